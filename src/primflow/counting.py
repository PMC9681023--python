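"""Boundary-deduplicating primitive counting and counting-error summaries.

Per-window predicted sequences are timing-free, so a primitive that
straddles the boundary between two adjacent 4-s prediction cores appears
at the end of one window's sequence and again at the start of the next.
The tally therefore merges the boundary pair whenever the last element of
window k equals the first element of window k+1 (a primitive spanning
three cores merges pairwise across both boundaries and is counted once).
Within-window repeats are never merged.  The rule is class-equality only;
two genuinely distinct same-class primitives meeting exactly at a core
boundary are (incorrectly) merged -- an inherent limitation of timing-free
sequences.

Counting accuracy is summarized per class / activity / subject as
``percent error = 100 * (predicted - true) / true`` (negative =
undercount) and ``percent of true = 100 * predicted / true``; cells with
zero true count are flagged and excluded rather than divided by zero.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .imu_data import CLASSES


def merge_window_sequences(
    window_sequences: Iterable[Sequence[str]],
) -> list[str]:
    """Concatenate per-window sequences, merging duplicates at boundaries.

    Window sequences must be supplied in temporal core order.
    """
    merged: list[str] = []
    for seq in window_sequences:
        for pos, klass in enumerate(seq):
            if pos == 0 and merged and merged[-1] == klass:
                continue  # boundary duplicate: same primitive continues
            merged.append(klass)
    return merged


def dedup_and_count(
    window_sequences: Iterable[Sequence[str]],
) -> dict[str, int]:
    """Per-class tallies of the boundary-merged prediction stream."""
    counts = {c: 0 for c in CLASSES}
    for klass in merge_window_sequences(window_sequences):
        counts[klass] += 1
    return counts


@dataclasses.dataclass
class CountReport:
    """Predicted-vs-true tallies at class, activity and subject granularity.

    ``per_class`` and ``per_activity`` aggregate over all trials;
    ``per_subject`` holds the per-subject percent counting errors whose
    mean/sd mirror single-subject counting-error summaries.  ``excluded``
    lists (table, cell) pairs dropped because their true count was zero.
    """

    per_class: pd.DataFrame
    per_activity: pd.DataFrame
    per_subject: pd.DataFrame
    excluded: list[tuple[str, str]]

    def total_predicted(self) -> int:
        return int(self.per_class["predicted"].sum())


def counting_error(
    predicted: Mapping[str, int], true: Mapping[str, int]
) -> pd.DataFrame:
    """Percent error and percent-of-true per key; zero-truth keys excluded.

    percent_error = 100 * (predicted - true) / true
    percent_of_true = 100 * predicted / true
    """
    rows = []
    for key in true:
        t = true[key]
        p = predicted.get(key, 0)
        if t <= 0:
            warnings.warn(
                f"true count for {key!r} is zero; cell excluded from "
                "normalized counting errors",
                stacklevel=2,
            )
            rows.append(
                {
                    "key": key,
                    "predicted": p,
                    "true": t,
                    "percent_error": np.nan,
                    "percent_of_true": np.nan,
                }
            )
            continue
        rows.append(
            {
                "key": key,
                "predicted": p,
                "true": t,
                "percent_error": 100.0 * (p - t) / t,
                "percent_of_true": 100.0 * p / t,
            }
        )
    return pd.DataFrame(rows).set_index("key")


def build_count_report(
    trials: Iterable[Mapping],
) -> CountReport:
    """Assemble a CountReport from per-trial counted predictions.

    Each trial mapping needs keys ``subject``, ``activity``,
    ``predicted`` (class -> count) and ``true`` (class -> count).
    """
    trials = list(trials)
    excluded: list[tuple[str, str]] = []

    def _sum(field: str, group=None, value=None):
        out = {c: 0 for c in CLASSES}
        for tr in trials:
            if group is not None and tr[group] != value:
                continue
            for c in CLASSES:
                out[c] += int(tr[field].get(c, 0))
        return out

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_class = counting_error(_sum("predicted"), _sum("true"))
    per_class.index.name = "class"
    for c in CLASSES:
        if per_class.loc[c, "true"] == 0:
            excluded.append(("per_class", c))

    activities = sorted({tr["activity"] for tr in trials})
    act_rows = {}
    for a in activities:
        pred = _sum("predicted", "activity", a)
        true = _sum("true", "activity", a)
        act_rows[a] = (sum(pred.values()), sum(true.values()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_activity = counting_error(
            {a: v[0] for a, v in act_rows.items()},
            {a: v[1] for a, v in act_rows.items()},
        )
    per_activity.index.name = "activity"
    for a in activities:
        if per_activity.loc[a, "true"] == 0:
            excluded.append(("per_activity", a))

    subjects = sorted({tr["subject"] for tr in trials})
    subj_rows = []
    for s in subjects:
        pred = _sum("predicted", "subject", s)
        true = _sum("true", "subject", s)
        p_tot, t_tot = sum(pred.values()), sum(true.values())
        if t_tot == 0:
            excluded.append(("per_subject", s))
            err = of_true = np.nan
        else:
            err = 100.0 * (p_tot - t_tot) / t_tot
            of_true = 100.0 * p_tot / t_tot
        subj_rows.append(
            {
                "subject": s,
                "predicted": p_tot,
                "true": t_tot,
                "percent_error": err,
                "percent_of_true": of_true,
            }
        )
    per_subject = pd.DataFrame(subj_rows).set_index("subject")
    return CountReport(
        per_class=per_class,
        per_activity=per_activity,
        per_subject=per_subject,
        excluded=excluded,
    )


def save_count_report(report: CountReport, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.per_class.to_csv(outdir / "counts_per_class.csv")
    report.per_activity.to_csv(outdir / "counts_per_activity.csv")
    report.per_subject.to_csv(outdir / "counts_per_subject.csv")
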