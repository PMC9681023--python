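"""Data model, I/O, preprocessing and windowing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import primflow as pf
from primflow import imu_data
from primflow.errors import ConfigError, DataError, ParseError, SchemaError


def _blank_samples(T):
    x = np.zeros((T, 77))
    return x


class TestRecordingValidation:
    def test_channel_count_is_77(self):
        assert len(imu_data.CHANNELS) == 77
        assert len(imu_data.ACC_CHANNELS) == 27
        assert len(imu_data.QUAT_CHANNELS) == 27
        assert len(imu_data.ANGLE_CHANNELS) == 22

    def test_wrong_width_rejected(self):
        with pytest.raises(SchemaError):
            pf.IMURecording(samples=np.zeros((5, 76)))

    def test_nonconstant_flag_rejected(self):
        x = _blank_samples(4)
        x[2, imu_data.FLAG_INDEX] = 1.0
        with pytest.raises(DataError):
            pf.IMURecording(samples=x)

    def test_overlong_quaternion_rejected(self):
        x = _blank_samples(3)
        x[1, imu_data.QUAT_SLICE.start] = 1.5
        with pytest.raises(DataError):
            pf.IMURecording(samples=x)


class TestIO:
    def test_roundtrip_identity_on_generated_trial(self, one_trial, tmp_path):
        rec = one_trial.recording
        pf.write_recording(rec, tmp_path / "c.csv", tmp_path / "m.yaml")
        back = pf.read_recording(tmp_path / "c.csv", tmp_path / "m.yaml")
        np.testing.assert_array_equal(back.samples, rec.samples)
        assert back.subject_id == rec.subject_id
        assert back.sample_rate == rec.sample_rate
        assert back.paretic_side == rec.paretic_side

    def test_three_row_table_roundtrip(self, tmp_path):
        rec = pf.IMURecording(samples=_blank_samples(3), subject_id="S01")
        pf.write_recording(rec, tmp_path / "c.csv", tmp_path / "m.yaml")
        back = pf.read_recording(tmp_path / "c.csv", tmp_path / "m.yaml")
        assert len(back) == 3

    def test_missing_channel_named_in_error(self, tmp_path, one_trial):
        import pandas as pd

        rec = one_trial.recording
        pf.write_recording(rec, tmp_path / "c.csv", tmp_path / "m.yaml")
        df = pd.read_csv(tmp_path / "c.csv")
        df = df.drop(columns=["hand_left_acc_x"])
        df.to_csv(tmp_path / "c76.csv", index=False)
        with pytest.raises(SchemaError, match="hand_left_acc_x"):
            pf.read_recording(tmp_path / "c76.csv", tmp_path / "m.yaml")

    def test_non_numeric_cell_reports_row(self, tmp_path, one_trial):
        import pandas as pd

        rec = one_trial.recording
        pf.write_recording(rec, tmp_path / "c.csv", tmp_path / "m.yaml")
        df = pd.read_csv(tmp_path / "c.csv")
        df["pelvis_acc_x"] = df["pelvis_acc_x"].astype(object)
        df.loc[2, "pelvis_acc_x"] = "oops"
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ParseError, match="row 2"):
            pf.read_recording(tmp_path / "bad.csv", tmp_path / "m.yaml")

    def test_segments_roundtrip(self, one_trial, tmp_path):
        segs = one_trial.segments
        pf.write_segments(segs, tmp_path / "s.csv")
        back = pf.read_segments(tmp_path / "s.csv")
        assert back == segs


class TestQuaternionTransform:
    def _recording_with_quats(self, vecs):
        # vecs: (T, 9, 3) vector parts
        x = _blank_samples(vecs.shape[0])
        x[:, imu_data.QUAT_SLICE] = vecs.reshape(len(vecs), 27)
        return pf.IMURecording(samples=x)

    def test_self_reference_gives_identity_rotation(self, rng):
        v = rng.normal(0, 0.2, size=(1, 9, 3))
        vecs = np.repeat(v, 5, axis=0)
        rec = self._recording_with_quats(vecs)
        out = pf.sensor_centric_transform(rec)
        # identity quaternion has zero vector part
        assert np.allclose(out.samples[:, imu_data.QUAT_SLICE], 0, atol=1e-12)

    def test_identity_reference_is_noop(self, rng):
        vecs = rng.normal(0, 0.2, size=(6, 9, 3))
        rec = self._recording_with_quats(vecs)
        out = pf.sensor_centric_transform(rec, reference=np.zeros((9, 3)))
        np.testing.assert_allclose(
            out.samples[:, imu_data.QUAT_SLICE],
            rec.samples[:, imu_data.QUAT_SLICE],
            atol=1e-12,
        )

    def test_matches_rotation_matrix_composition_oracle(self, rng):
        # relative rotation ref^-1 * q must match composing the inverse
        # reference rotation matrix with q's matrix (scipy as oracle)
        vecs = rng.normal(0, 0.25, size=(8, 9, 3))
        ref = rng.normal(0, 0.25, size=(9, 3))
        rec = self._recording_with_quats(vecs)
        out = pf.sensor_centric_transform(rec, reference=ref)

        def full(v):
            w = np.sqrt(1.0 - np.sum(v**2))
            return np.array([v[0], v[1], v[2], w])  # scipy xyzw order

        for t in range(8):
            for s in range(9):
                q = full(vecs[t, s])
                r = full(ref[s])
                R_rel = (
                    Rotation.from_quat(r).inv() * Rotation.from_quat(q)
                ).as_matrix()
                v_out = out.samples[t, imu_data.quat_block(s)]
                w_out = np.sqrt(max(0.0, 1.0 - np.sum(v_out**2)))
                R_ours = Rotation.from_quat(
                    [v_out[0], v_out[1], v_out[2], w_out]
                ).as_matrix()
                np.testing.assert_allclose(R_ours, R_rel, atol=1e-9)

    def test_norm_preserved(self, rng):
        vecs = rng.normal(0, 0.3, size=(10, 9, 3))
        norms = np.linalg.norm(vecs, axis=2, keepdims=True)
        vecs = vecs * np.minimum(1.0, 0.9 / norms)  # keep inside unit ball
        rec = self._recording_with_quats(vecs)
        out = pf.sensor_centric_transform(rec)
        v = out.samples[:, imu_data.QUAT_SLICE].reshape(-1, 9, 3)
        w = np.sqrt(np.clip(1 - np.sum(v**2, axis=2), 0, None))
        norms = np.sqrt(np.sum(v**2, axis=2) + w**2)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_acceleration_channels_untouched(self, one_trial):
        rec = one_trial.recording
        out = pf.sensor_centric_transform(rec)
        np.testing.assert_array_equal(
            out.samples[:, imu_data.ACC_SLICE],
            rec.samples[:, imu_data.ACC_SLICE],
        )
        np.testing.assert_array_equal(
            out.samples[:, imu_data.ANGLE_SLICE],
            rec.samples[:, imu_data.ANGLE_SLICE],
        )


class TestNormalization:
    def test_fit_apply_standardizes(self, small_dataset):
        recs = [t.recording for t in small_dataset.subset("train")]
        stats = pf.fit_channel_stats(recs)
        normed = np.concatenate(
            [pf.zscore_normalize(r, stats).samples for r in recs]
        )
        cont = normed[:, :76]
        np.testing.assert_allclose(cont.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(cont.std(axis=0), 1.0, atol=1e-6)

    def test_flag_passes_through(self, rng):
        x = _blank_samples(10)
        x[:, imu_data.FLAG_INDEX] = 1.0
        rec = pf.IMURecording(samples=x)
        stats = pf.fit_channel_stats([rec])
        out = pf.zscore_normalize(rec, stats)
        np.testing.assert_array_equal(out.samples[:, imu_data.FLAG_INDEX], 1.0)

    def test_constant_channel_maps_to_zero(self):
        x = _blank_samples(5)
        x[:, 0] = 3.14
        rec = pf.IMURecording(samples=x)
        stats = pf.fit_channel_stats([rec])
        out = pf.zscore_normalize(rec, stats)
        np.testing.assert_allclose(out.samples[:, 0], 0.0)

    def test_denormalize_inverts(self, one_trial):
        rec = one_trial.recording
        stats = pf.fit_channel_stats([rec])
        back = pf.zscore_denormalize(pf.zscore_normalize(rec, stats), stats)
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-9)


class TestLabels:
    def test_collapse_examples(self):
        labels = ["reach", "reach", "transport", "transport", "idle"]
        assert pf.collapse_to_sequence(labels) == (
            "reach",
            "transport",
            "idle",
        )
        assert pf.collapse_to_sequence(["idle"] * 7) == ("idle",)
        assert pf.collapse_to_sequence([], 0, 0) == ()

    def test_collapse_idempotent(self, rng):
        for _ in range(20):
            labels = list(rng.choice(pf.CLASSES, size=30))
            once = pf.collapse_to_sequence(labels)
            assert pf.collapse_to_sequence(list(once)) == once

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(pf.CLASSES), st.integers(1, 5)
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_segments_labels_roundtrip(self, runs):
        # build non-adjacent-duplicate segments from run-length pairs
        segs = []
        cursor = 0
        prev = None
        for klass, length in runs:
            if klass == prev:
                continue
            segs.append(pf.Segment(klass, cursor, cursor + length))
            cursor += length
            prev = klass
        labels = pf.segments_to_labels(segs, cursor)
        assert pf.labels_to_segments(labels) == segs


class TestWindowing:
    def test_test_slide_tiling_14s(self, rng):
        rec = pf.IMURecording(samples=_blank_samples(1400))
        wins = pf.make_windows(rec, slide_s=4.0)
        cores = [(w.core_start, w.core_end) for w in wins]
        assert cores == [(0, 400), (400, 800), (800, 1200), (1200, 1400)]
        for w in wins:
            assert w.data.shape == (600, 77)

    def test_single_tile_when_recording_equals_core(self):
        rec = pf.IMURecording(samples=_blank_samples(400))
        wins = pf.make_windows(rec, slide_s=4.0)
        assert len(wins) == 1
        assert (wins[0].core_start, wins[0].core_end) == (0, 400)

    def test_training_slide_produces_more_windows(self):
        rec = pf.IMURecording(samples=_blank_samples(1400))
        train = pf.make_windows(rec, slide_s=0.5)
        test = pf.make_windows(rec, slide_s=4.0)
        assert len(train) > len(test)

    @pytest.mark.parametrize("T", [150, 400, 640, 1000, 1399, 1401])
    def test_cores_partition_timeline(self, T):
        rec = pf.IMURecording(samples=_blank_samples(T))
        wins = pf.make_windows(rec, slide_s=4.0)
        covered = []
        for w in wins:
            covered.extend(range(w.core_start, w.core_end))
        assert covered == list(range(T))  # disjoint and exhaustive

    def test_flanks_are_zero_padded_at_edges(self):
        x = np.ones((500, 77))
        x[:, imu_data.FLAG_INDEX] = 0.0
        rec = pf.IMURecording(samples=np.zeros((500, 77)))
        rec.samples[:, 0] = 1.0
        wins = pf.make_windows(rec, slide_s=4.0)
        first = wins[0]
        # 1-s flank before sample 0 is zero-filled
        assert np.all(first.data[:100, 0] == 0.0)
        assert np.all(first.data[100:200, 0] == 1.0)

    def test_targets_attached_from_labels(self, one_trial):
        wins = pf.make_windows(
            one_trial.recording, one_trial.labels, slide_s=4.0
        )
        for w in wins:
            expected = pf.collapse_to_sequence(
                one_trial.labels, w.core_start, w.core_end
            )
            assert w.target == expected

    def test_bad_geometry_rejected(self):
        rec = pf.IMURecording(samples=_blank_samples(100))
        with pytest.raises(ConfigError):
            pf.make_windows(rec, window_s=4.0, core_s=6.0)
        with pytest.raises(ConfigError):
            pf.make_windows(rec, slide_s=0.0)
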