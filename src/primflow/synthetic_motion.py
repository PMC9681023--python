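"""Synthetic labeled IMU sessions with class-distinct kinematic phenotypes.

The generator emulates the structure of wearable-sensor recordings of
upper-extremity rehabilitation: a first-order Markov grammar strings the
five functional primitives together into an "activity", each motion
primitive (reach / reposition / transport) renders a minimum-jerk velocity
bell on its own signature channels of the paretic arm, and the
minimal-motion primitives (stabilization / idle) render only sensor noise.
Because the sensor array carries no finger information, grasp -- the real
phenotypic difference between stabilization and idle -- is stood in for by
a small constant orientation offset of the paretic hand sensor whose
magnitude is configurable (shrinking it toward 0 reproduces the
stabilization/idle confusion seen with real data).

Everything is driven by a single integer seed: a fixed seed reproduces the
dataset bit for bit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import imu_data
from .errors import ConfigError, DataError
from .imu_data import (
    ANGLE_CHANNELS,
    CHANNELS,
    CLASSES,
    FLAG_INDEX,
    IMURecording,
    Segment,
    SENSORS,
)

# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PhenotypeSpec:
    """Kinematic phenotype of one primitive class.

    ``acc_weights`` / ``quat_weights`` map a sensor role on the paretic side
    ("hand", "forearm", "arm", "c7") to a 3-axis direction scaled by
    ``amplitude`` (g) resp. ``quat_amplitude`` (unit-quaternion vector
    components).  ``angle_weights`` maps angle-channel templates (with the
    ``{side}`` placeholder) to excursions in degrees.  Durations are drawn
    log-normal with the given median and log-sd, truncated to
    ``[0.3, 5] s``.
    """

    kind: str  # "burst" | "quiescent"
    amplitude: float  # peak acceleration of the bell, g
    quat_amplitude: float
    angle_amplitude: float  # scales angle_weights, degrees
    duration_median_s: float
    duration_log_sd: float
    acc_weights: Mapping[str, tuple[float, float, float]]
    quat_weights: Mapping[str, tuple[float, float, float]]
    angle_weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.kind not in ("burst", "quiescent"):
            raise ConfigError(f"unknown phenotype kind {self.kind!r}")
        if self.duration_median_s <= 0:
            raise ConfigError("durations must be positive")


DURATION_BOUNDS_S = (0.3, 5.0)

#: Default per-class phenotypes.  Each motion primitive recruits a
#: distinct part of the paretic upper extremity -- reaching is
#: distal-dominant (hand sensor), repositioning is forearm-dominant, and
#: transporting an object engages the whole arm plus trunk -- and the
#: three differ in duration (transports longest, repositions shortest).
#: This is a deliberate stylization: it keeps the class-conditional
#: signatures well separated so the desk-scale sequence model has a
#: learnable task, which is the module's purpose.  Amplitudes sit far
#: above the noise floor.  Quiescent classes render noise only;
#: stabilization additionally carries the grasp surrogate (a constant
#: hand-orientation offset plus a small wrist-flexion posture).
DEFAULT_PHENOTYPES: dict[str, PhenotypeSpec] = {
    "reach": PhenotypeSpec(
        kind="burst",
        amplitude=1.0,
        quat_amplitude=0.20,
        angle_amplitude=1.0,
        duration_median_s=1.1,
        duration_log_sd=0.30,
        acc_weights={
            "hand": (1.0, 0.4, 0.2),
            "forearm": (0.25, 0.1, 0.05),
        },
        quat_weights={"hand": (1.0, 0.2, 0.0)},
        angle_weights={"elbow_flexion_{side}": -35.0},
    ),
    "reposition": PhenotypeSpec(
        kind="burst",
        amplitude=0.8,
        quat_amplitude=0.15,
        angle_amplitude=1.0,
        duration_median_s=0.9,
        duration_log_sd=0.30,
        acc_weights={
            "forearm": (0.2, 1.0, 0.4),
            "hand": (0.05, 0.25, 0.1),
        },
        quat_weights={"forearm": (0.0, 1.0, 0.3)},
        angle_weights={"shoulder_abduction_{side}": 20.0},
    ),
    "transport": PhenotypeSpec(
        kind="burst",
        amplitude=0.9,
        quat_amplitude=0.18,
        angle_amplitude=1.0,
        duration_median_s=1.8,
        duration_log_sd=0.30,
        acc_weights={
            "arm": (1.0, 0.6, 0.8),
            "c7": (0.3, 0.3, 0.3),
            "hand": (0.2, 0.2, 0.2),
        },
        quat_weights={"arm": (0.3, 0.3, 1.0)},
        angle_weights={
            "shoulder_flexion_{side}": 30.0,
            "thoracic_flexion": 6.0,
        },
    ),
    "stabilization": PhenotypeSpec(
        kind="quiescent",
        amplitude=0.0,
        quat_amplitude=0.0,
        angle_amplitude=1.0,
        duration_median_s=1.4,
        duration_log_sd=0.40,
        acc_weights={},
        quat_weights={},
        angle_weights={"wrist_flexion_{side}": 10.0},  # grasp posture
    ),
    "idle": PhenotypeSpec(
        kind="quiescent",
        amplitude=0.0,
        quat_amplitude=0.0,
        angle_amplitude=0.0,
        duration_median_s=1.2,
        duration_log_sd=0.40,
        acc_weights={},
        quat_weights={},
        angle_weights={},
    ),
}


# ---------------------------------------------------------------------------
# Grammar
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GrammarSpec:
    """First-order transition structure of one synthetic activity."""

    transition: np.ndarray  # (5, 5), rows sum to 1
    initial: np.ndarray  # (5,)

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        p0 = np.asarray(self.initial, dtype=float)
        object.__setattr__(self, "transition", t)
        object.__setattr__(self, "initial", p0)
        if t.shape != (5, 5) or p0.shape != (5,):
            raise ConfigError("grammar must be 5x5 transitions + 5 initial")
        if np.any(t < 0) or np.any(p0 < 0):
            raise ConfigError("grammar probabilities must be non-negative")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("grammar rows must sum to 1")
        if not np.isclose(p0.sum(), 1.0, atol=1e-9):
            raise ConfigError("initial distribution must sum to 1")


def _grammar(rows: Sequence[Sequence[float]], p0: Sequence[float]) -> GrammarSpec:
    return GrammarSpec(np.asarray(rows, float), np.asarray(p0, float))


#: Default activity grammars.  Self-transitions are 0 so the sampled ground
#: truth never contains back-to-back same-class primitives; a typical cycle
#: is reposition -> reach -> transport -> stabilization -> transport -> idle.
#: Order of classes: reach, reposition, transport, stabilization, idle.
DEFAULT_GRAMMARS: dict[str, GrammarSpec] = {
    "tabletop": _grammar(
        [
            [0.00, 0.00, 0.55, 0.25, 0.20],  # after reach
            [0.70, 0.00, 0.00, 0.00, 0.30],  # after reposition
            [0.00, 0.35, 0.00, 0.40, 0.25],  # after transport
            [0.00, 0.30, 0.45, 0.00, 0.25],  # after stabilization
            [0.50, 0.50, 0.00, 0.00, 0.00],  # after idle
        ],
        [0.30, 0.30, 0.00, 0.00, 0.40],
    ),
    "shelf": _grammar(
        [
            [0.00, 0.00, 0.70, 0.15, 0.15],
            [0.60, 0.00, 0.00, 0.00, 0.40],
            [0.00, 0.45, 0.00, 0.30, 0.25],
            [0.00, 0.35, 0.50, 0.00, 0.15],
            [0.45, 0.55, 0.00, 0.00, 0.00],
        ],
        [0.25, 0.35, 0.00, 0.00, 0.40],
    ),
}


# ---------------------------------------------------------------------------
# Config and dataset containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions of a synthetic data run (fully seeded)."""

    n_subjects: int = 11
    trials_per_subject: int = 7
    activities: tuple[str, ...] = ("tabletop", "shelf")
    trial_duration_s: float = 30.0
    noise_acc_g: float = 0.05
    noise_quat: float = 0.01
    noise_angle_deg: float = 0.5
    grasp_quat_offset: float = 0.25
    drift_deg_per_min: float = 0.0
    sample_rate: float = 100.0
    split: tuple[int, int, int] = (6, 1, 4)  # train/val/test subjects
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ConfigError("need at least 3 subjects (one per split)")
        if sum(self.split) != self.n_subjects:
            raise ConfigError(
                f"split {self.split} must sum to n_subjects={self.n_subjects}"
            )
        if min(self.split) < 0 or self.split[0] == 0:
            raise ConfigError("train split must be non-empty")
        for name in self.activities:
            if name not in DEFAULT_GRAMMARS:
                raise ConfigError(f"unknown activity {name!r}")


@dataclasses.dataclass
class Trial:
    recording: IMURecording
    labels: np.ndarray  # per-timestep classes
    segments: list[Segment]
    split: str  # "train" | "val" | "test"


@dataclasses.dataclass
class SyntheticDataset:
    trials: list[Trial]
    config: SyntheticConfig
    manifest: dict

    def subset(self, split: str) -> list[Trial]:
        return [t for t in self.trials if t.split == split]

    @property
    def subjects(self) -> dict[str, str]:
        """subject_id -> split"""
        return {
            t.recording.subject_id: t.split for t in self.trials
        }


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _sample_duration(
    spec: PhenotypeSpec, rng: np.random.Generator, rate: float
) -> int:
    lo, hi = DURATION_BOUNDS_S
    for _ in range(1000):
        d = float(
            np.exp(np.log(spec.duration_median_s)
                   + spec.duration_log_sd * rng.standard_normal())
        )
        if lo <= d <= hi:
            return max(1, int(round(d * rate)))
    return max(1, int(round(spec.duration_median_s * rate)))


def sample_segments(
    grammar: GrammarSpec,
    total_duration_s: float,
    phenotypes: Mapping[str, PhenotypeSpec] = DEFAULT_PHENOTYPES,
    rng: np.random.Generator | None = None,
    sample_rate: float = 100.0,
) -> list[Segment]:
    """Sample a grammar realization whose segments tile [0, total_duration).

    The final segment is truncated so the tiling is exact.
    """
    rng = np.random.default_rng() if rng is None else rng
    total = int(round(total_duration_s * sample_rate))
    if total <= 0:
        return []
    segments: list[Segment] = []
    cursor = 0
    state = int(rng.choice(5, p=grammar.initial))
    while cursor < total:
        klass = CLASSES[state]
        n = _sample_duration(phenotypes[klass], rng, sample_rate)
        end = min(cursor + n, total)
        segments.append(Segment(klass, cursor, end))
        cursor = end
        state = int(rng.choice(5, p=grammar.transition[state]))
    return segments


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def minimum_jerk_bell(n: int) -> np.ndarray:
    """Minimum-jerk velocity profile over n samples, normalized to peak 1.

    v(tau) = 16 tau^2 (1 - tau)^2 for tau in [0, 1] (the 30 tau^2(1-tau)^2
    minimum-jerk speed rescaled so its midpoint peak equals 1).
    """
    tau = (np.arange(n) + 0.5) / n
    return 16.0 * tau**2 * (1.0 - tau) ** 2


def _role_sensor(role: str, side: str) -> int:
    if role == "c7":
        return SENSORS.index("c7")
    return SENSORS.index(f"{role}_{side}")


def _angle_index(template: str, side: str) -> int:
    return ANGLE_CHANNELS.index(template.format(side=side))


def render_recording(
    segments: Sequence[Segment],
    phenotypes: Mapping[str, PhenotypeSpec] = DEFAULT_PHENOTYPES,
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "S01",
    activity_id: str = "tabletop",
    trial_id: str = "T01",
    paretic_side: str = "left",
    ue_fma: int | None = None,
) -> tuple[IMURecording, np.ndarray]:
    """Render a segment tiling into a 77-channel recording + label track."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng() if rng is None else rng
    imu_data.validate_segments(segments)
    if not segments:
        raise DataError("cannot render an empty segment list")
    T = segments[-1].end
    rate = config.sample_rate
    X = np.zeros((T, len(CHANNELS)))

    # Constant per-trial baselines: calibration orientation of each sensor
    # and a resting posture for the joint angles.
    quat_base = rng.normal(0.0, 0.03, size=(9, 3))
    angle_base = rng.uniform(-10.0, 10.0, size=len(ANGLE_CHANNELS))
    X[:, imu_data.QUAT_SLICE] = np.tile(quat_base.reshape(27), (T, 1))
    X[:, imu_data.ANGLE_SLICE] = angle_base

    hand = _role_sensor("hand", paretic_side)

    for seg in segments:
        spec = phenotypes[seg.klass]
        n = seg.length
        rows = slice(seg.start, seg.end)
        if spec.kind == "burst":
            bell = minimum_jerk_bell(n)
            for role, direction in spec.acc_weights.items():
                cols = imu_data.acc_block(_role_sensor(role, paretic_side))
                X[rows, cols] += (
                    spec.amplitude * np.outer(bell, np.asarray(direction))
                )
            for role, direction in spec.quat_weights.items():
                cols = imu_data.quat_block(_role_sensor(role, paretic_side))
                X[rows, cols] += (
                    spec.quat_amplitude * np.outer(bell, np.asarray(direction))
                )
            for template, excursion in spec.angle_weights.items():
                col = imu_data.ANGLE_SLICE.start + _angle_index(
                    template, paretic_side
                )
                X[rows, col] += spec.angle_amplitude * excursion * bell
        else:  # quiescent
            # constant postural offsets (e.g. the grasp wrist posture)
            for template, excursion in spec.angle_weights.items():
                col = imu_data.ANGLE_SLICE.start + _angle_index(
                    template, paretic_side
                )
                X[rows, col] += spec.angle_amplitude * excursion
            if seg.klass == "stabilization":
                # Grasp surrogate: constant hand-sensor orientation offset
                # while an object is held (no finger channels exist to
                # encode grasp).
                X[rows, imu_data.quat_block(hand).start] += (
                    config.grasp_quat_offset
                )

    # Sensor noise.
    X[:, imu_data.ACC_SLICE] += rng.normal(
        0.0, config.noise_acc_g, size=(T, 27)
    )
    X[:, imu_data.QUAT_SLICE] += rng.normal(
        0.0, config.noise_quat, size=(T, 27)
    )
    X[:, imu_data.ANGLE_SLICE] += rng.normal(
        0.0, config.noise_angle_deg, size=(T, 22)
    )
    if config.drift_deg_per_min > 0:
        t_min = np.arange(T) / rate / 60.0
        X[:, imu_data.ANGLE_SLICE] += (
            config.drift_deg_per_min * t_min[:, None]
        )

    # Keep orientation vector parts inside the unit ball.
    vec = X[:, imu_data.QUAT_SLICE].reshape(T, 9, 3)
    norms = np.linalg.norm(vec, axis=2, keepdims=True)
    over = norms > 0.999
    if np.any(over):
        scale = np.where(over, 0.999 / norms, 1.0)
        X[:, imu_data.QUAT_SLICE] = (vec * scale).reshape(T, 27)

    X[:, FLAG_INDEX] = 1.0 if paretic_side == "right" else 0.0

    rec = IMURecording(
        samples=X,
        sample_rate=rate,
        subject_id=subject_id,
        activity_id=activity_id,
        trial_id=trial_id,
        ue_fma=ue_fma,
    )
    labels = imu_data.segments_to_labels(segments, T)
    return rec, labels


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(
    config: SyntheticConfig | None = None,
    phenotypes: Mapping[str, PhenotypeSpec] = DEFAULT_PHENOTYPES,
    grammars: Mapping[str, GrammarSpec] | None = None,
) -> SyntheticDataset:
    """Generate a full labeled dataset with subject-level splits.

    Subjects are disjoint across train/validation/test; paretic side
    alternates across subjects; activities cycle across trials.  The
    manifest records the config, the seed, and one row per trial.
    """
    config = config or SyntheticConfig()
    grammars = dict(grammars or DEFAULT_GRAMMARS)
    rng = np.random.default_rng(config.seed)

    n_train, n_val, n_test = config.split
    split_of: dict[int, str] = {}
    order = rng.permutation(config.n_subjects)
    for rank, subj in enumerate(order):
        if rank < n_train:
            split_of[subj] = "train"
        elif rank < n_train + n_val:
            split_of[subj] = "val"
        else:
            split_of[subj] = "test"

    trials: list[Trial] = []
    manifest_rows = []
    for subj in range(config.n_subjects):
        subject_id = f"S{subj + 1:02d}"
        side = "left" if subj % 2 == 0 else "right"
        ue_fma = int(rng.integers(26, 66))
        for t in range(config.trials_per_subject):
            activity = config.activities[t % len(config.activities)]
            trial_id = f"T{t + 1:02d}"
            segs = sample_segments(
                grammars[activity],
                config.trial_duration_s,
                phenotypes,
                rng,
                config.sample_rate,
            )
            rec, labels = render_recording(
                segs,
                phenotypes,
                config,
                rng,
                subject_id=subject_id,
                activity_id=activity,
                trial_id=trial_id,
                paretic_side=side,
                ue_fma=ue_fma,
            )
            trial = Trial(rec, labels, segs, split_of[subj])
            trials.append(trial)
            manifest_rows.append(
                {
                    "subject": subject_id,
                    "activity": activity,
                    "trial": trial_id,
                    "split": split_of[subj],
                    "paretic_side": side,
                    "n_samples": len(rec),
                    "n_primitives": len(segs),
                }
            )
    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "trials": manifest_rows,
    }
    return SyntheticDataset(trials=trials, config=config, manifest=manifest)


def save_dataset(dataset: SyntheticDataset, outdir) -> Path:
    """Write channel tables, segment tables, metadata sidecars + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for trial in dataset.trials:
        rec = trial.recording
        stem = f"{rec.subject_id}_{rec.activity_id}_{rec.trial_id}"
        imu_data.write_recording(
            rec, outdir / f"{stem}_channels.csv", outdir / f"{stem}_meta.yaml"
        )
        imu_data.write_segments(
            trial.segments, outdir / f"{stem}_segments.csv", rec.sample_rate
        )
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(_clean_for_yaml(dataset.manifest), fh, sort_keys=True)
    return outdir


def load_dataset(indir) -> SyntheticDataset:
    indir = Path(indir)
    with open(indir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    cfg_dict = dict(manifest["config"])
    cfg_dict["activities"] = tuple(cfg_dict["activities"])
    cfg_dict["split"] = tuple(cfg_dict["split"])
    config = SyntheticConfig(**cfg_dict)
    trials = []
    for row in manifest["trials"]:
        stem = f"{row['subject']}_{row['activity']}_{row['trial']}"
        rec = imu_data.read_recording(
            indir / f"{stem}_channels.csv", indir / f"{stem}_meta.yaml"
        )
        segs = imu_data.read_segments(
            indir / f"{stem}_segments.csv", rec.sample_rate
        )
        labels = imu_data.segments_to_labels(segs, len(rec))
        trials.append(Trial(rec, labels, segs, row["split"]))
    return SyntheticDataset(trials=trials, config=config, manifest=manifest)


def _clean_for_yaml(obj):
    if isinstance(obj, dict):
        return {k: _clean_for_yaml(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean_for_yaml(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
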