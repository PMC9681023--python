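"""Pointwise benchmark models and smoothing-to-sequence conversion.

The reference point for the sequence model is a conventional pointwise
pipeline: a classifier emits a class-probability vector at every 10-ms
time step, the probability tracks are smoothed with a Kaiser window
(parameterized by window size and relative sidelobe attenuation, both
selected on validation data), and per-step argmax followed by run-length
collapse turns the smoothed track into primitive sequences that feed the
same counting and evaluation machinery as the sequence model.

The bundled classifier is a random forest over per-channel statistical
features (mean, maximum, minimum, standard deviation, root mean square;
population convention for sd/RMS) computed on a sliding sub-window
centered on each prediction step.  Any other pointwise classifier can be
plugged in through the same predict-probabilities interface.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import kaiser_beta
from scipy.signal.windows import kaiser as kaiser_window
from sklearn.ensemble import RandomForestClassifier

from . import evaluation, imu_data
from .errors import ConfigError, DataError
from .imu_data import CLASSES, IMURecording, collapse_to_sequence


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def extract_features(window_per_channel: np.ndarray) -> np.ndarray:
    """Five statistics per channel of an (n, C) window, channel-major.

    Order within each channel block: mean, max, min, sd, RMS, with
    sd and RMS using the population (divide-by-n) convention, so that
    RMS^2 = mean^2 + sd^2.
    """
    w = np.asarray(window_per_channel, dtype=float)
    if w.ndim != 2 or w.shape[0] == 0:
        raise DataError("feature window must be a non-empty (n, C) array")
    stats = np.stack(
        [
            w.mean(axis=0),
            w.max(axis=0),
            w.min(axis=0),
            w.std(axis=0),
            np.sqrt(np.mean(w * w, axis=0)),
        ],
        axis=1,
    )  # (C, 5)
    return stats.ravel()


def sliding_features(
    samples: np.ndarray, win: int = 100, stride: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Features on sliding sub-windows centered on a stride grid.

    Computed with O(T) separable rolling filters (reflected edges), so
    whole recordings featurize in milliseconds.  Returns (features,
    centers).  Defaults: 1-s window, 0.1-s stride at 100 Hz.
    """
    from scipy.ndimage import (
        maximum_filter1d,
        minimum_filter1d,
        uniform_filter1d,
    )

    x = np.asarray(samples, dtype=float)
    T, C = x.shape
    size = win if win % 2 == 1 else win + 1
    mean = uniform_filter1d(x, size, axis=0, mode="reflect")
    msq = uniform_filter1d(x * x, size, axis=0, mode="reflect")
    sd = np.sqrt(np.clip(msq - mean * mean, 0.0, None))
    rms = np.sqrt(msq)
    mx = maximum_filter1d(x, size, axis=0, mode="reflect")
    mn = minimum_filter1d(x, size, axis=0, mode="reflect")
    centers = np.arange(0, T, stride)
    # (n_centers, C, 5) -> channel-major flat layout as extract_features
    stacked = np.stack(
        [mean[centers], mx[centers], mn[centers], sd[centers], rms[centers]],
        axis=2,
    )
    return stacked.reshape(len(centers), C * 5), centers


# ---------------------------------------------------------------------------
# Random-forest pointwise classifier
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PointwiseClassifier:
    """A fitted classifier emitting per-class probabilities per time step."""

    estimator: RandomForestClassifier
    win: int
    stride: int
    #: preprocessing applied at fit time: "none" or "sensor_centric"
    preprocess: str = "none"

    def predict_recording(self, rec: IMURecording) -> np.ndarray:
        """(T, 5) probability track, applying the fit-time preprocessing."""
        if self.preprocess == "sensor_centric":
            rec = imu_data.sensor_centric_transform(rec)
        return self.predict_pointwise(rec.samples)

    def predict_pointwise(self, samples: np.ndarray) -> np.ndarray:
        """(T, 5) probability track for a (T, 77) sample array.

        Probabilities are predicted on the stride grid and propagated to
        every 10-ms step by nearest-center assignment.
        """
        feats, centers = sliding_features(samples, self.win, self.stride)
        proba = self.estimator.predict_proba(feats)
        full = np.zeros((len(feats), len(CLASSES)))
        for j, klass in enumerate(self.estimator.classes_):
            full[:, CLASSES.index(klass)] = proba[:, j]
        T = samples.shape[0]
        idx = np.clip(
            np.round(np.arange(T) / self.stride).astype(int),
            0,
            len(centers) - 1,
        )
        return full[idx]


def train_pointwise_rf(
    features: np.ndarray,
    labels: Sequence[str],
    n_trees: int = 100,
    rng: int | np.random.Generator | None = 0,
    win: int = 100,
    stride: int = 10,
) -> PointwiseClassifier:
    """Fit the statistical-feature random forest.

    ``features`` rows are per-step feature vectors, ``labels`` the class
    at each corresponding step.  Seeded for reproducibility.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DataError("need at least two classes to train a classifier")
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(0, 2**31 - 1))
    else:
        seed = rng
    est = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    est.fit(features, labels)
    return PointwiseClassifier(estimator=est, win=win, stride=stride)


def fit_rf_on_trials(
    trials: Iterable,
    n_trees: int = 100,
    seed: int = 0,
    win: int = 100,
    stride: int = 10,
) -> PointwiseClassifier:
    """Convenience: fit the RF on (recording, labels) training trials.

    Recordings get the same sensor-centric quaternion transform as the
    sequence pipeline (z-scoring is irrelevant for trees).
    """
    feat_blocks = []
    label_blocks = []
    for t in trials:
        rec = imu_data.sensor_centric_transform(t.recording)
        feats, centers = sliding_features(rec.samples, win, stride)
        feat_blocks.append(feats)
        label_blocks.append(np.asarray(t.labels)[centers])
    clf = train_pointwise_rf(
        np.concatenate(feat_blocks),
        np.concatenate(label_blocks),
        n_trees=n_trees,
        rng=seed,
        win=win,
        stride=stride,
    )
    clf.preprocess = "sensor_centric"
    return clf


# ---------------------------------------------------------------------------
# Kaiser smoothing and sequence conversion
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SmootherConfig:
    """Kaiser smoothing window: odd size in samples + sidelobe attenuation
    (dB), which sets the window's shape parameter beta."""

    size: int = 51
    attenuation_db: float = 30.0

    def __post_init__(self) -> None:
        if self.size < 1 or self.size % 2 == 0:
            raise ConfigError("smoother window size must be odd and >= 1")


def kaiser_smooth(
    pointwise: np.ndarray, config: SmootherConfig
) -> np.ndarray:
    """Convolve each class-probability channel with a normalized Kaiser
    window (reflection padding at the edges), then renormalize rows."""
    probs = np.asarray(pointwise, dtype=float)
    if config.size == 1:
        return probs.copy()
    kernel = kaiser_window(config.size, kaiser_beta(config.attenuation_db))
    kernel = kernel / kernel.sum()
    half = config.size // 2
    padded = np.pad(probs, ((half, half), (0, 0)), mode="reflect")
    out = np.empty_like(probs)
    for c in range(probs.shape[1]):
        out[:, c] = np.convolve(padded[:, c], kernel, mode="valid")
    sums = out.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return out / sums


def pointwise_to_sequence(
    smoothed: np.ndarray, core: tuple[int, int] | None = None
) -> tuple[str, ...]:
    """Per-step argmax then run-length collapse over the core region."""
    lo, hi = (0, smoothed.shape[0]) if core is None else core
    idx = np.argmax(smoothed[lo:hi], axis=1)
    return collapse_to_sequence([CLASSES[i] for i in idx])


def sequences_for_recording(
    clf: PointwiseClassifier,
    rec: IMURecording,
    smoother: SmootherConfig,
    core_s: float = 4.0,
) -> list[tuple[str, ...]]:
    """Pointwise predict -> smooth -> one sequence per test core."""
    smoothed = kaiser_smooth(clf.predict_recording(rec), smoother)
    wins = imu_data.make_windows(rec, core_s=core_s, slide_s=core_s)
    return [
        pointwise_to_sequence(smoothed, (w.core_start, w.core_end))
        for w in wins
    ]


DEFAULT_SMOOTHER_GRID: tuple[SmootherConfig, ...] = tuple(
    SmootherConfig(size=s, attenuation_db=a)
    for s in (1, 31, 61, 101, 151)
    for a in (30.0, 60.0)
)


def select_smoother(
    validation: Sequence[tuple[np.ndarray, Sequence[str]]],
    grid: Sequence[SmootherConfig] = DEFAULT_SMOOTHER_GRID,
    core_s: float = 4.0,
    sample_rate: float = 100.0,
) -> SmootherConfig:
    """Grid-search the smoother maximizing sequence-level validation F1.

    ``validation`` holds (pointwise probability track, label track) pairs.
    Ties prefer the smallest window (then the grid order).
    """
    if not grid:
        raise ConfigError("smoother grid must be non-empty")
    nc = int(round(core_s * sample_rate))
    best_cfg = None
    best_key = None
    for cfg in grid:
        pairs = []
        for probs, labels in validation:
            T = len(labels)
            smoothed = kaiser_smooth(probs, cfg)
            starts = list(range(0, T, nc)) or [0]
            for s in starts:
                e = min(s + nc, T)
                if e <= s:
                    continue
                gt = collapse_to_sequence(labels, s, e)
                pred = pointwise_to_sequence(smoothed, (s, e))
                pairs.append((gt, pred))
        report = evaluation.evaluate_sequences(pairs)
        score = -1.0 if report.f1 is None else report.f1
        key = (-score, cfg.size)
        if best_key is None or key < best_key:
            best_key = key
            best_cfg = cfg
    return best_cfg
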