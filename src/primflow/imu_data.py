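"""Data model and preprocessing for upper-body IMU recordings.

A recording is a 77-channel time series sampled at 100 Hz: 27 linear
accelerations (9 sensors x 3 axes, in g), 27 orientation components
(9 sensors x the 3-vector part of a unit quaternion; the scalar part is
implied non-negative), 22 anatomical joint angles (degrees), and one
constant flag encoding the side of the paretic upper extremity
(0 = left, 1 = right).

Ground-truth annotation attaches one of five functional-primitive classes
to every 10-ms time step: ``reach``, ``reposition`` and ``transport`` are
motion primitives; ``stabilization`` and ``idle`` are minimal-motion
primitives distinguished by grasp.  Labels are handled both as a
per-timestep track and as ordered ``(class, start, end)`` segments with
0-based, half-open sample intervals.

This module also implements the preprocessing applied before modeling
(sensor-centric quaternion transformation and per-channel z-scoring with
statistics fit on training data only) and the window/core/flank scheme
used to feed fixed-length slices to the sequence model.
"""

from __future__ import annotations

import dataclasses

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, ParseError, SchemaError

# ---------------------------------------------------------------------------
# Channel layout
# ---------------------------------------------------------------------------

#: The five substantive primitive classes, in canonical order.  This order is
#: also the deterministic tie-break order used by the sequence decoder.
CLASSES: tuple[str, ...] = (
    "reach",
    "reposition",
    "transport",
    "stabilization",
    "idle",
)

#: Sensor placement of the nine IMUs (pelvis, spine at T10 and C7, and
#: arm / forearm / hand on each side).
SENSORS: tuple[str, ...] = (
    "pelvis",
    "t10",
    "c7",
    "arm_left",
    "forearm_left",
    "hand_left",
    "arm_right",
    "forearm_right",
    "hand_right",
)

_AXES = ("x", "y", "z")

ACC_CHANNELS: tuple[str, ...] = tuple(
    f"{s}_acc_{a}" for s in SENSORS for a in _AXES
)
QUAT_CHANNELS: tuple[str, ...] = tuple(
    f"{s}_quat_{a}" for s in SENSORS for a in _AXES
)

# 22 anatomical angles: 8 per side plus 6 trunk angles.
_SIDE_ANGLES = (
    "shoulder_flexion",
    "shoulder_abduction",
    "shoulder_rotation",
    "shoulder_total_flexion",
    "elbow_flexion",
    "forearm_pronation",
    "wrist_flexion",
    "wrist_deviation",
)
_TRUNK_ANGLES = (
    "thoracic_flexion",
    "thoracic_lateral",
    "thoracic_rotation",
    "lumbar_flexion",
    "lumbar_lateral",
    "lumbar_rotation",
)
ANGLE_CHANNELS: tuple[str, ...] = tuple(
    f"{name}_{side}" for side in ("left", "right") for name in _SIDE_ANGLES
) + _TRUNK_ANGLES

FLAG_CHANNEL = "paretic_side"

#: Canonical 77-channel order of every channel table.
CHANNELS: tuple[str, ...] = (
    ACC_CHANNELS + QUAT_CHANNELS + ANGLE_CHANNELS + (FLAG_CHANNEL,)
)

N_CHANNELS = len(CHANNELS)
assert N_CHANNELS == 77

ACC_SLICE = slice(0, 27)
QUAT_SLICE = slice(27, 54)
ANGLE_SLICE = slice(54, 76)
FLAG_INDEX = 76

_QUAT_NORM_TOL = 1e-3


def quat_block(sensor: int) -> slice:
    """Column slice of the 3 quaternion components of sensor ``sensor``."""
    return slice(27 + 3 * sensor, 27 + 3 * sensor + 3)


def acc_block(sensor: int) -> slice:
    return slice(3 * sensor, 3 * sensor + 3)


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class IMURecording:
    """A validated 77-channel recording plus its session metadata."""

    samples: np.ndarray  # (T, 77) float
    sample_rate: float = 100.0
    subject_id: str = ""
    activity_id: str = ""
    trial_id: str = ""
    ue_fma: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise SchemaError(
                f"expected (T, {N_CHANNELS}) samples, got {self.samples.shape}"
            )
        flag = self.samples[:, FLAG_INDEX]
        if len(flag) and (
            not np.all((flag == flag[0]))
            or flag[0] not in (0.0, 1.0)
        ):
            raise DataError("paretic-side flag must be constant and in {0, 1}")
        vec = self.samples[:, QUAT_SLICE].reshape(-1, 9, 3)
        norms = np.linalg.norm(vec, axis=2)
        if norms.size and norms.max() > 1.0 + _QUAT_NORM_TOL:
            raise DataError(
                "quaternion vector part exceeds unit norm "
                f"(max {norms.max():.4f})"
            )

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate

    @property
    def paretic_side(self) -> str:
        if len(self) == 0:
            return "left"
        return "right" if self.samples[0, FLAG_INDEX] == 1.0 else "left"

    def replace_samples(self, samples: np.ndarray) -> "IMURecording":
        return dataclasses.replace(self, samples=samples)


@dataclasses.dataclass(frozen=True)
class Segment:
    """One labeled primitive occupying the half-open interval [start, end)."""

    klass: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise DataError(f"unknown primitive class {self.klass!r}")
        if not 0 <= self.start < self.end:
            raise DataError(
                f"segment must satisfy 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class ChannelStats:
    """Per-channel moments estimated on the training split only.

    The paretic-side flag is excluded from normalization: its entries are
    fixed at mean 0, sd 1 so it passes through unchanged.
    """

    mean: np.ndarray  # (77,)
    sd: np.ndarray  # (77,)

    SD_FLOOR = 1e-8

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (N_CHANNELS,) or self.sd.shape != (N_CHANNELS,):
            raise ConfigError("channel stats must have one entry per channel")
        if np.any(self.sd < 0):
            raise ConfigError("channel standard deviations must be >= 0")
        self.sd = np.maximum(self.sd, self.SD_FLOOR)


@dataclasses.dataclass
class Window:
    """A fixed-length model input slice.

    ``data`` has ``window_s * sample_rate`` rows; the core -- the region
    whose primitives are predicted -- occupies rows
    ``[core_offset, core_offset + (core_end - core_start))`` and maps to the
    recording interval ``[core_start, core_end)``.  Flanks (and any part of
    the window outside the recording) are context only and are zero-filled
    where they extend past the recording boundary.
    """

    data: np.ndarray  # (window_len, 77)
    core_start: int  # absolute sample index, inclusive
    core_end: int  # absolute sample index, exclusive
    core_offset: int  # row of the core start within the window
    target: tuple[str, ...] | None = None  # primitive sequence for the core


# ---------------------------------------------------------------------------
# Labels: segments <-> per-timestep track <-> timing-free sequence
# ---------------------------------------------------------------------------


def validate_segments(segments: Sequence[Segment], length: int | None = None) -> None:
    """Check that segments are ordered and non-overlapping."""
    prev_end = 0
    for seg in segments:
        if seg.start < prev_end:
            raise DataError(
                f"segments overlap or are unordered near sample {seg.start}"
            )
        prev_end = seg.end
    if length is not None and segments and segments[-1].end > length:
        raise DataError("segments extend past the recording")


def segments_to_labels(segments: Sequence[Segment], length: int) -> np.ndarray:
    """Expand segments to a per-timestep label track of ``length`` steps.

    Gaps between segments are not allowed: ground truth tiles the recording.
    """
    validate_segments(segments, length)
    labels = np.empty(length, dtype=object)
    cursor = 0
    for seg in segments:
        if seg.start != cursor:
            raise DataError(f"gap in segment cover at sample {cursor}")
        labels[seg.start : seg.end] = seg.klass
        cursor = seg.end
    if cursor != length:
        raise DataError("segments do not cover the recording")
    return labels


def labels_to_segments(labels: Sequence[str]) -> list[Segment]:
    """Run-length encode a label track into ordered segments."""
    segments: list[Segment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append(Segment(str(labels[start]), start, i))
            start = i
    return segments


def collapse_to_sequence(
    labels: Sequence[str], start: int = 0, end: int | None = None
) -> tuple[str, ...]:
    """Run-length collapse of ``labels[start:end]`` into a timing-free
    primitive sequence; consecutive identical classes yield one element."""
    if end is None:
        end = len(labels)
    if not 0 <= start <= end <= len(labels):
        raise DataError(f"bad collapse region [{start}, {end})")
    out: list[str] = []
    for i in range(start, end):
        k = str(labels[i])
        if not out or out[-1] != k:
            out.append(k)
    return tuple(out)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_recording(channel_table_path, metadata_path) -> IMURecording:
    """Read a delimited channel table plus its metadata sidecar.

    The table must contain exactly the 77 canonical channels (extra or
    missing columns raise :class:`SchemaError`); non-numeric cells raise
    :class:`ParseError` naming the row.
    """
    df = pd.read_csv(channel_table_path, float_precision="round_trip")
    missing = [c for c in CHANNELS if c not in df.columns]
    extra = [c for c in df.columns if c not in CHANNELS]
    if missing or extra:
        raise SchemaError(
            f"channel table schema mismatch: missing={missing} extra={extra}"
        )
    df = df[list(CHANNELS)]
    arr = np.empty(df.shape, dtype=float)
    for j, col in enumerate(CHANNELS):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value in channel {col!r} at row {row}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ParseError(f"missing value in channel {col!r} at row {row}")
        arr[:, j] = converted.to_numpy()

    with open(metadata_path) as fh:
        meta = yaml.safe_load(fh) or {}
    side = meta.get("paretic_side", "left")
    if side not in ("left", "right"):
        raise DataError(f"paretic_side must be 'left' or 'right', got {side!r}")
    rec = IMURecording(
        samples=arr,
        sample_rate=float(meta.get("sample_rate_hz", 100.0)),
        subject_id=str(meta.get("subject", "")),
        activity_id=str(meta.get("activity", "")),
        trial_id=str(meta.get("trial", "")),
        ue_fma=(None if meta.get("ue_fma") is None else int(meta["ue_fma"])),
    )
    if len(rec) and rec.paretic_side != side:
        raise DataError(
            "paretic-side flag channel disagrees with metadata sidecar"
        )
    return rec


def write_recording(
    rec: IMURecording, channel_table_path, metadata_path
) -> None:
    df = pd.DataFrame(rec.samples, columns=list(CHANNELS))
    # 17 significant digits: write -> read recovers float64 exactly
    df.to_csv(channel_table_path, index=False, float_format="%.17g")
    meta = {
        "subject": rec.subject_id,
        "activity": rec.activity_id,
        "trial": rec.trial_id,
        "paretic_side": rec.paretic_side,
        "sample_rate_hz": float(rec.sample_rate),
        "ue_fma": rec.ue_fma,
    }
    with open(metadata_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_segments(path, sample_rate: float = 100.0) -> list[Segment]:
    """Read a ``klass,start_ms,end_ms`` table (end exclusive) into segments."""
    df = pd.read_csv(path)
    expected = {"klass", "start_ms", "end_ms"}
    if set(df.columns) != expected:
        raise SchemaError(
            f"segment table must have columns {sorted(expected)}, "
            f"got {list(df.columns)}"
        )
    segs = [
        Segment(
            str(row.klass),
            int(round(row.start_ms * sample_rate / 1000.0)),
            int(round(row.end_ms * sample_rate / 1000.0)),
        )
        for row in df.itertuples()
    ]
    validate_segments(segs)
    return segs


def write_segments(
    segments: Sequence[Segment], path, sample_rate: float = 100.0
) -> None:
    rows = [
        {
            "klass": s.klass,
            "start_ms": s.start * 1000.0 / sample_rate,
            "end_ms": s.end * 1000.0 / sample_rate,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=["klass", "start_ms", "end_ms"]).to_csv(
        path, index=False, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# Quaternion preprocessing
# ---------------------------------------------------------------------------


def _vec_to_quat(vec: np.ndarray) -> np.ndarray:
    """Lift (..., 3) vector parts to (..., 4) unit quaternions [w, x, y, z].

    The scalar part is reconstructed as the non-negative root
    ``w = sqrt(1 - |v|^2)``, the storage convention of the channel tables.
    """
    sq = np.sum(vec * vec, axis=-1)
    if np.any(sq > (1.0 + _QUAT_NORM_TOL) ** 2):
        raise DataError("quaternion vector part exceeds unit norm")
    w = np.sqrt(np.clip(1.0 - sq, 0.0, None))
    return np.concatenate([w[..., None], vec], axis=-1)


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product of quaternions stored as (..., 4) [w, x, y, z]."""
    w1, x1, y1, z1 = (q1[..., i] for i in range(4))
    w2, x2, y2, z2 = (q2[..., i] for i in range(4))
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def sensor_centric_transform(
    rec: IMURecording, reference: np.ndarray | None = None
) -> IMURecording:
    """Re-express each sensor's orientation relative to a reference pose.

    Each output quaternion is the relative rotation ``ref^-1 (x) q(t)``,
    which represents the rotation of the sensor around its own axes since
    calibration.  By default the reference is the first sample of each
    sensor, so a motionless recording maps to the identity rotation.

    ``reference`` may be an array of shape (9, 3) holding the vector parts
    of per-sensor calibration quaternions (scalar parts implied
    non-negative).  Acceleration, angle and flag channels are unchanged.
    """
    if len(rec) == 0:
        return rec.replace_samples(rec.samples.copy())
    vec = rec.samples[:, QUAT_SLICE].reshape(len(rec), 9, 3)
    q = _vec_to_quat(vec)  # (T, 9, 4)
    norms = np.linalg.norm(q, axis=-1)
    if np.any(norms < 1e-6):
        raise DataError("zero-norm quaternion")
    if reference is None:
        ref = q[0]
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.shape != (9, 3):
            raise ConfigError("reference must have shape (9, 3)")
        ref = _vec_to_quat(reference)
    rel = quat_multiply(quat_conjugate(ref)[None, :, :], q)
    # Canonicalize the double cover: keep the scalar part non-negative so the
    # stored 3-vector determines the rotation uniquely.
    flip = rel[..., 0] < 0.0
    rel[flip] *= -1.0
    out = rec.samples.copy()
    out[:, QUAT_SLICE] = rel[..., 1:].reshape(len(rec), 27)
    return rec.replace_samples(out)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def fit_channel_stats(recordings: Iterable[IMURecording]) -> ChannelStats:
    """Estimate per-channel mean/sd over training recordings.

    Must only ever be fed the training split; applying the resulting stats
    to validation or test data is the supported (and only correct) use.
    """
    chunks = [r.samples for r in recordings]
    if not chunks:
        raise ConfigError("cannot fit channel stats on zero recordings")
    data = np.concatenate(chunks, axis=0)
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    mean[FLAG_INDEX] = 0.0
    sd[FLAG_INDEX] = 1.0
    return ChannelStats(mean=mean, sd=sd)


def _clone_with_samples(rec: IMURecording, samples: np.ndarray) -> IMURecording:
    """Shallow copy skipping validation (normalized data is off-scale)."""
    import copy

    new = copy.copy(rec)
    new.samples = samples
    return new


def zscore_normalize(rec: IMURecording, stats: ChannelStats) -> IMURecording:
    """Z-score the 76 continuous channels; the paretic flag passes through."""
    out = (rec.samples - stats.mean) / stats.sd
    out[:, FLAG_INDEX] = rec.samples[:, FLAG_INDEX]
    return _clone_with_samples(rec, out)


def zscore_denormalize(rec: IMURecording, stats: ChannelStats) -> IMURecording:
    out = rec.samples * stats.sd + stats.mean
    out[:, FLAG_INDEX] = rec.samples[:, FLAG_INDEX]
    return _clone_with_samples(rec, out)


def normalize_array(samples: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Array-level z-scoring used on window batches (flag passes through)."""
    out = (samples - stats.mean) / stats.sd
    out[..., FLAG_INDEX] = samples[..., FLAG_INDEX]
    return out


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


def make_windows(
    rec: IMURecording,
    labels: Sequence[str] | None = None,
    window_s: float = 6.0,
    core_s: float = 4.0,
    slide_s: float = 4.0,
    min_overlap_s: float = 0.0,
) -> list[Window]:
    """Cut a recording into fixed-length windows with predicted cores.

    The middle ``core_s`` of each ``window_s`` window is the prediction
    region; the flanks only give the model temporal context.  At the test
    slide (``slide_s == core_s``) the cores partition ``[0, T)``: the signal
    is zero-padded one flank at each end so edge cores reach the recording
    boundaries, and a trailing core shorter than ``core_s`` covers any
    remainder.  At smaller (training) slides, only fully contained cores are
    produced, yielding overlapping windows.

    ``min_overlap_s`` controls target construction at core edges: a
    primitive cut by an *internal* core boundary enters the core's target
    sequence only if at least this much of it lies inside the core.
    Sub-perceptual edge fragments otherwise make targets noisy; as long as
    the threshold stays below half the shortest primitive duration, every
    primitive still appears in at least one core, so deduplicating
    counting remains exact.  Fragments at the recording's outer edges are
    always kept (there is no neighboring core to carry them).
    """
    if core_s > window_s:
        raise ConfigError("core_s must not exceed window_s")
    if slide_s <= 0:
        raise ConfigError("slide_s must be positive")
    rate = rec.sample_rate
    nw = int(round(window_s * rate))
    nc = int(round(core_s * rate))
    ns = int(round(slide_s * rate))
    flank = (nw - nc) // 2
    T = len(rec)
    if T == 0:
        return []
    if labels is not None and len(labels) != T:
        raise DataError("label track length must match the recording")

    starts: list[int] = []
    s = 0
    while s + nc <= T:
        starts.append(s)
        s += ns
    if ns >= nc:
        covered = (starts[-1] + nc) if starts else 0
        if covered < T:
            starts.append(s)  # trailing short core [s, T)
    if not starts:
        starts = [0]

    windows: list[Window] = []
    for cs in starts:
        ce = min(cs + nc, T)
        ws = cs - flank
        data = np.zeros((nw, rec.samples.shape[1]), dtype=rec.samples.dtype)
        lo = max(ws, 0)
        hi = min(ws + nw, T)
        if hi > lo:
            data[lo - ws : hi - ws] = rec.samples[lo:hi]
        target = None
        if labels is not None:
            target = _core_target(
                labels, cs, ce, int(round(min_overlap_s * rate)), T
            )
        windows.append(
            Window(
                data=data,
                core_start=cs,
                core_end=ce,
                core_offset=flank,
                target=target,
            )
        )
    return windows


def _core_target(
    labels: Sequence[str], start: int, end: int, min_overlap: int, T: int
) -> tuple[str, ...]:
    """Collapse core labels, dropping short fragments at internal edges."""
    if min_overlap <= 1:
        return collapse_to_sequence(labels, start, end)
    runs: list[tuple[str, int]] = []  # (class, run length)
    for i in range(start, end):
        k = str(labels[i])
        if runs and runs[-1][0] == k:
            runs[-1] = (k, runs[-1][1] + 1)
        else:
            runs.append((k, 1))
    if runs and start > 0 and runs[0][1] < min_overlap:
        runs = runs[1:]
    if runs and end < T and runs[-1][1] < min_overlap:
        runs = runs[:-1]
    out = [k for k, _ in runs]
    # dropping an edge run can expose adjacent duplicates; re-collapse
    return collapse_to_sequence(out)


def core_sequences(
    labels: Sequence[str], rec: IMURecording, core_s: float = 4.0
) -> list[tuple[str, ...]]:
    """Ground-truth primitive sequence of each test-slide core, in order."""
    wins = make_windows(rec, labels, slide_s=core_s, core_s=core_s)
    return [w.target for w in wins if w.target is not None]
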