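"""Sequence-level evaluation of primitive predictions.

Predicted and ground-truth primitive sequences are compared with a
unit-cost Levenshtein alignment whose operations carry the four-way error
taxonomy used throughout the package:

* a *match* is a true positive for its class;
* a *deletion* (ground-truth item unmatched) is a false-negative mode in
  which the primitive was missed entirely;
* an *insertion* (predicted item unmatched) is a false-positive mode in
  which a primitive was invented;
* a *substitution* counts twice: a *swap-out* (false negative) for the
  ground-truth class and a *swap-in* (false positive) for the predicted
  class.

Hence FN = deletions + swap-outs and FP = insertions + swap-ins, and the
summary metrics are sensitivity TP/(TP+FN), false discovery rate
FP/(TP+FP), F1 = 2*s*(1-f)/(s+(1-f)) (equal to 2TP/(2TP+FN+FP)), and the
Action Error Rate AER = edit_distance / |ground truth|.

Among equal-cost alignments the operation tallies can differ, so the
alignment is made deterministic: walking forward from the sequence starts
over a suffix-distance table, ties are broken preferring
match > substitution > deletion > insertion.

Model comparison mirrors a trial-level bootstrap: per-trial (TP, FN, FP)
tallies are resampled with replacement, metrics are computed per
replicate, and models are compared with unpaired two-tailed t-tests
(df = 2*n_replicates - 2) under Bonferroni correction.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from .errors import ConfigError
from .imu_data import CLASSES

Sequence_ = tuple[str, ...]


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class AlignOp:
    op: str  # "match" | "substitution" | "deletion" | "insertion"
    gt: str | None  # ground-truth class consumed, if any
    pred: str | None  # predicted class consumed, if any


@dataclasses.dataclass
class SequenceAlignment:
    gt: Sequence_
    pred: Sequence_
    ops: list[AlignOp]
    distance: int

    def counts(self) -> dict[str, int]:
        c = {"match": 0, "substitution": 0, "deletion": 0, "insertion": 0}
        for op in self.ops:
            c[op.op] += 1
        return c


def edit_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Unit-cost Levenshtein distance (two-row dynamic program)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(
                    prev[j] + 1,  # delete ca
                    cur[j - 1] + 1,  # insert cb
                    prev[j - 1] + (ca != cb),
                )
            )
        prev = cur
    return prev[-1]


def _suffix_distance_table(gt: Sequence[str], pred: Sequence[str]) -> np.ndarray:
    n, m = len(gt), len(pred)
    D = np.zeros((n + 1, m + 1), dtype=np.int64)
    D[n, :] = m - np.arange(m + 1)
    D[:, m] = n - np.arange(n + 1)
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            D[i, j] = min(
                D[i + 1, j + 1] + (gt[i] != pred[j]),
                D[i + 1, j] + 1,
                D[i, j + 1] + 1,
            )
    return D


def align(gt: Sequence[str], pred: Sequence[str]) -> SequenceAlignment:
    """Minimal-cost alignment with a deterministic operation script.

    The script is recovered by walking forward from the sequence starts
    over the suffix-distance table, breaking cost ties in the order
    match > substitution > deletion > insertion.
    """
    gt = tuple(gt)
    pred = tuple(pred)
    D = _suffix_distance_table(gt, pred)
    ops: list[AlignOp] = []
    i = j = 0
    n, m = len(gt), len(pred)
    while i < n or j < m:
        here = D[i, j]
        if i < n and j < m and gt[i] == pred[j] and D[i + 1, j + 1] == here:
            ops.append(AlignOp("match", gt[i], pred[j]))
            i += 1
            j += 1
        elif i < n and j < m and D[i + 1, j + 1] + 1 == here:
            ops.append(AlignOp("substitution", gt[i], pred[j]))
            i += 1
            j += 1
        elif i < n and D[i + 1, j] + 1 == here:
            ops.append(AlignOp("deletion", gt[i], None))
            i += 1
        else:
            ops.append(AlignOp("insertion", None, pred[j]))
            j += 1
    return SequenceAlignment(gt=gt, pred=pred, ops=ops, distance=int(D[0, 0]))


def aer(gt: Sequence[str], pred: Sequence[str]) -> float | None:
    """Action Error Rate: edit distance normalized by ground-truth length.

    May exceed 1; undefined (None) for empty ground truth.
    """
    if len(gt) == 0:
        return None
    return edit_distance(gt, pred) / len(gt)


# ---------------------------------------------------------------------------
# Outcome taxonomy
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class OutcomeTally:
    """Per-class true-positive and error-mode tallies."""

    tp: dict[str, int]
    deletions: dict[str, int]
    swap_out: dict[str, int]
    insertions: dict[str, int]
    swap_in: dict[str, int]
    gt_count: dict[str, int]
    pred_count: dict[str, int]

    @classmethod
    def empty(cls) -> "OutcomeTally":
        z = lambda: {c: 0 for c in CLASSES}  # noqa: E731
        return cls(z(), z(), z(), z(), z(), z(), z())

    def fn(self, klass: str | None = None) -> int:
        if klass is None:
            return sum(self.fn(c) for c in CLASSES)
        return self.deletions[klass] + self.swap_out[klass]

    def fp(self, klass: str | None = None) -> int:
        if klass is None:
            return sum(self.fp(c) for c in CLASSES)
        return self.insertions[klass] + self.swap_in[klass]

    def tp_total(self) -> int:
        return sum(self.tp.values())

    def add(self, other: "OutcomeTally") -> None:
        for field in (
            "tp",
            "deletions",
            "swap_out",
            "insertions",
            "swap_in",
            "gt_count",
            "pred_count",
        ):
            mine = getattr(self, field)
            for c in CLASSES:
                mine[c] += getattr(other, field)[c]


def classify_outcomes(
    alignments: SequenceAlignment | Iterable[SequenceAlignment],
) -> OutcomeTally:
    """Tally matches and the four error modes over one or many alignments."""
    if isinstance(alignments, SequenceAlignment):
        alignments = [alignments]
    tally = OutcomeTally.empty()
    for al in alignments:
        for c in al.gt:
            tally.gt_count[c] += 1
        for c in al.pred:
            tally.pred_count[c] += 1
        for op in al.ops:
            if op.op == "match":
                tally.tp[op.gt] += 1
            elif op.op == "deletion":
                tally.deletions[op.gt] += 1
            elif op.op == "insertion":
                tally.insertions[op.pred] += 1
            else:  # substitution: swap-out for gt class, swap-in for pred
                tally.swap_out[op.gt] += 1
                tally.swap_in[op.pred] += 1
    return tally


# ---------------------------------------------------------------------------
# Scalar metrics
# ---------------------------------------------------------------------------


def sensitivity(tp: float, fn: float) -> float | None:
    """TP / (TP + FN); None when no ground-truth positives exist."""
    if tp + fn <= 0:
        return None
    return tp / (tp + fn)


def fdr(tp: float, fp: float) -> float | None:
    """FP / (TP + FP); None when nothing was predicted."""
    if tp + fp <= 0:
        return None
    return fp / (tp + fp)


def f1(sens: float, fdr_value: float) -> float | None:
    """F1 from sensitivity and FDR: 2*s*(1-f) / (s + (1-f)).

    Equals 2TP/(2TP + FN + FP) when s and f come from the same tallies.
    """
    precision = 1.0 - fdr_value
    denom = sens + precision
    if denom <= 0:
        return None
    return 2.0 * sens * precision / denom


def f1_from_counts(tp: float, fn: float, fp: float) -> float | None:
    denom = 2.0 * tp + fn + fp
    if denom <= 0:
        return None
    return 2.0 * tp / denom


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MetricsReport:
    """Aggregate classification metrics over a set of trial alignments."""

    tally: OutcomeTally
    sensitivity: float | None
    fdr: float | None
    f1: float | None
    aer: float | None
    per_class: pd.DataFrame  # tallies + normalized error frequencies
    confusion: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["sensitivity", "fdr", "f1", "aer"],
                "value": [self.sensitivity, self.fdr, self.f1, self.aer],
            }
        )


def confusion_matrix(
    alignments: Iterable[SequenceAlignment],
) -> pd.DataFrame:
    """5x5 confusion matrix normalized to ground-truth counts.

    Rows are ground-truth classes, columns predicted classes; the diagonal
    is per-class sensitivity and the ``deletion`` margin column completes
    each row to 1.  The ``insertion`` margin row holds insertion
    frequencies of each predicted class, also normalized by that class's
    ground-truth count.  Rows for classes absent from the ground truth are
    NaN.
    """
    alignments = list(alignments)
    if not alignments:
        raise ConfigError("need at least one alignment")
    tally = classify_outcomes(alignments)
    sub = {(r, c): 0 for r in CLASSES for c in CLASSES}
    for al in alignments:
        for op in al.ops:
            if op.op == "substitution":
                sub[(op.gt, op.pred)] += 1
    cols = list(CLASSES) + ["deletion"]
    rows = list(CLASSES) + ["insertion"]
    M = pd.DataFrame(np.nan, index=rows, columns=cols, dtype=float)
    for r in CLASSES:
        n = tally.gt_count[r]
        if n == 0:
            continue
        for c in CLASSES:
            M.loc[r, c] = (tally.tp[r] if r == c else sub[(r, c)]) / n
        M.loc[r, "deletion"] = tally.deletions[r] / n
    for c in CLASSES:
        n = tally.gt_count[c]
        if n > 0:
            M.loc["insertion", c] = tally.insertions[c] / n
    return M


def evaluate_sequences(
    pairs: Iterable[tuple[Sequence[str], Sequence[str]]],
) -> MetricsReport:
    """Align (ground truth, prediction) pairs and aggregate all metrics.

    AER is aggregated as total edit distance over total ground-truth
    length; pairs with empty ground truth contribute only their edits.
    """
    alignments = [align(gt, pred) for gt, pred in pairs]
    tally = classify_outcomes(alignments)
    tp, fn, fp = tally.tp_total(), tally.fn(), tally.fp()
    total_edits = sum(a.distance for a in alignments)
    total_gt = sum(len(a.gt) for a in alignments)
    rows = []
    for c in CLASSES:
        n = tally.gt_count[c]
        rows.append(
            {
                "class": c,
                "gt_count": n,
                "pred_count": tally.pred_count[c],
                "tp": tally.tp[c],
                "deletion": tally.deletions[c],
                "swap_out": tally.swap_out[c],
                "insertion": tally.insertions[c],
                "swap_in": tally.swap_in[c],
                "sensitivity": sensitivity(tally.tp[c], tally.fn(c)),
                "fdr": fdr(tally.tp[c], tally.fp(c)),
                "deletion_freq": tally.deletions[c] / n if n else np.nan,
                "swap_out_freq": tally.swap_out[c] / n if n else np.nan,
                "insertion_freq": tally.insertions[c] / n if n else np.nan,
                "swap_in_freq": tally.swap_in[c] / n if n else np.nan,
            }
        )
    s = sensitivity(tp, fn)
    f = fdr(tp, fp)
    return MetricsReport(
        tally=tally,
        sensitivity=s,
        fdr=f,
        f1=(f1(s, f) if s is not None and f is not None else None),
        aer=(total_edits / total_gt if total_gt else None),
        per_class=pd.DataFrame(rows).set_index("class"),
        confusion=confusion_matrix(alignments),
    )


# ---------------------------------------------------------------------------
# Bootstrap model comparison
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BootstrapResult:
    metrics: pd.DataFrame  # columns: model, replicate, sensitivity, fdr, f1
    comparisons: pd.DataFrame  # model, metric, t, df, p, p_bonferroni
    df: int
    n_replicates: int


def bootstrap_compare(
    per_trial_outcomes_by_model: Mapping[str, Sequence[tuple[int, int, int]]],
    n_replicates: int = 250,
    subsample: int = 81,
    rng: np.random.Generator | None = None,
    reference: str | None = None,
) -> BootstrapResult:
    """Bootstrap trial-level (TP, FN, FP) tallies and compare models.

    Every model must supply tallies for the same ordered set of trials.
    Each replicate draws ``subsample`` trial indices with replacement (the
    same draw for all models), aggregates tallies, and computes
    sensitivity/FDR/F1.  Each rival model is compared to the reference
    (first key by default) with an unpaired two-tailed t-test over
    replicates, df = 2*n_replicates - 2, Bonferroni-corrected by the
    number of rivals.
    """
    models = list(per_trial_outcomes_by_model)
    if len(models) < 2:
        raise ConfigError("need at least two models to compare")
    n_trials = len(per_trial_outcomes_by_model[models[0]])
    arrays = {}
    for m in models:
        arr = np.asarray(per_trial_outcomes_by_model[m], dtype=float)
        if arr.shape != (n_trials, 3):
            raise ConfigError(
                "all models must supply (TP, FN, FP) for the same trials"
            )
        arrays[m] = arr
    reference = models[0] if reference is None else reference
    if reference not in models:
        raise ConfigError(f"reference model {reference!r} not supplied")
    rng = np.random.default_rng() if rng is None else rng

    rows = []
    for rep in range(n_replicates):
        idx = rng.integers(0, n_trials, size=subsample)
        for m in models:
            tp, fn, fp = arrays[m][idx].sum(axis=0)
            s = sensitivity(tp, fn)
            f = fdr(tp, fp)
            rows.append(
                {
                    "model": m,
                    "replicate": rep,
                    "sensitivity": s,
                    "fdr": f,
                    "f1": f1(s, f) if s is not None and f is not None else None,
                }
            )
    metrics = pd.DataFrame(rows)

    dof = 2 * n_replicates - 2
    rivals = [m for m in models if m != reference]
    comps = []
    ref_vals = metrics[metrics["model"] == reference]
    for m in rivals:
        riv_vals = metrics[metrics["model"] == m]
        for metric in ("sensitivity", "fdr", "f1"):
            a = ref_vals[metric].to_numpy(dtype=float)
            b = riv_vals[metric].to_numpy(dtype=float)
            if np.allclose(a, b):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = scipy_stats.ttest_ind(a, b)
            comps.append(
                {
                    "model": m,
                    "metric": metric,
                    "mean_reference": float(np.mean(a)),
                    "mean_model": float(np.mean(b)),
                    "t": float(t_stat),
                    "df": dof,
                    "p": float(p),
                    "p_bonferroni": float(min(1.0, p * len(rivals))),
                }
            )
    return BootstrapResult(
        metrics=metrics,
        comparisons=pd.DataFrame(comps),
        df=dof,
        n_replicates=n_replicates,
    )
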