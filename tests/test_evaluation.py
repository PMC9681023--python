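"""Levenshtein alignment, error taxonomy, metrics, bootstrap."""

import itertools

import edlib
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import primflow as pf
from primflow import evaluation as ev
from primflow.errors import ConfigError

_LETTER = {c: chr(ord("A") + i) for i, c in enumerate(pf.CLASSES)}


def edlib_distance(a, b):
    """Independent edit-distance oracle (C implementation)."""
    sa = "".join(_LETTER[c] for c in a)
    sb = "".join(_LETTER[c] for c in b)
    if not sa and not sb:
        return 0
    if not sa or not sb:
        return max(len(sa), len(sb))
    return edlib.align(sa, sb)["editDistance"]


def brute_force_distance(a, b):
    """Plain recursive minimal-edit search (tiny sequences only)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        brute_force_distance(a[1:], b[1:]) + (a[0] != b[0]),
        brute_force_distance(a[1:], b) + 1,
        brute_force_distance(a, b[1:]) + 1,
    )


seq_strategy = st.lists(st.sampled_from(pf.CLASSES), max_size=6).map(tuple)


class TestAlignment:
    def test_identity_alignment(self):
        al = pf.align(("reach", "transport"), ("reach", "transport"))
        assert al.distance == 0
        assert [o.op for o in al.ops] == ["match", "match"]

    def test_substitution_plus_insertion_script(self):
        # analogue of the schematic error taxonomy: stabilization swapped
        # out for idle, plus a spurious trailing reach
        gt = ("transport", "stabilization", "reach")
        pred = ("transport", "idle", "reach", "reach")
        al = pf.align(gt, pred)
        assert al.distance == 2
        ops = [(o.op, o.gt, o.pred) for o in al.ops]
        assert ops == [
            ("match", "transport", "transport"),
            ("substitution", "stabilization", "idle"),
            ("match", "reach", "reach"),
            ("insertion", None, "reach"),
        ]

    def test_empty_gt_all_insertions(self):
        al = pf.align((), ("idle",))
        assert al.distance == 1
        assert [o.op for o in al.ops] == ["insertion"]

    def test_distance_matches_brute_force_small(self, rng):
        for _ in range(200):
            a = tuple(rng.choice(pf.CLASSES, size=rng.integers(0, 4)))
            b = tuple(rng.choice(pf.CLASSES, size=rng.integers(0, 4)))
            assert pf.edit_distance(a, b) == brute_force_distance(a, b)

    @given(seq_strategy, seq_strategy)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_distance_matches_edlib_and_ops_consistent(self, a, b):
        al = pf.align(a, b)
        assert al.distance == edlib_distance(a, b)
        c = al.counts()
        # conservation of sequence lengths through the op script
        assert c["match"] + c["substitution"] + c["deletion"] == len(a)
        assert c["match"] + c["substitution"] + c["insertion"] == len(b)
        assert al.distance == c["substitution"] + c["deletion"] + c["insertion"]

    @given(seq_strategy, seq_strategy, seq_strategy)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_metric_properties(self, a, b, c):
        assert pf.edit_distance(a, b) == pf.edit_distance(b, a)
        assert pf.edit_distance(a, c) <= (
            pf.edit_distance(a, b) + pf.edit_distance(b, c)
        )
        assert pf.edit_distance(a, a) == 0


class TestOutcomeTaxonomy:
    def test_all_match_no_errors(self):
        al = pf.align(("reach", "idle"), ("reach", "idle"))
        tally = pf.classify_outcomes(al)
        assert tally.tp_total() == 2
        assert tally.fn() == 0 and tally.fp() == 0

    def test_substitution_is_swap_out_and_swap_in(self):
        al = pf.align(("reach",), ("idle",))
        tally = pf.classify_outcomes(al)
        assert tally.swap_out["reach"] == 1
        assert tally.swap_in["idle"] == 1
        assert tally.fn() == 1 and tally.fp() == 1

    def test_tallies_match_direct_enumeration(self, rng):
        pairs = [
            (
                tuple(rng.choice(pf.CLASSES, size=rng.integers(0, 7))),
                tuple(rng.choice(pf.CLASSES, size=rng.integers(0, 7))),
            )
            for _ in range(100)
        ]
        alignments = [pf.align(g, p) for g, p in pairs]
        tally = pf.classify_outcomes(alignments)
        # independent pass over the op lists
        tp = dele = sout = ins = sin_ = 0
        for al in alignments:
            for op in al.ops:
                tp += op.op == "match"
                dele += op.op == "deletion"
                ins += op.op == "insertion"
                sout += op.op == "substitution"
                sin_ += op.op == "substitution"
        assert tally.tp_total() == tp
        assert sum(tally.deletions.values()) == dele
        assert sum(tally.insertions.values()) == ins
        assert sum(tally.swap_out.values()) == sout
        assert sum(tally.swap_in.values()) == sin_
        assert tally.fn() == dele + sout
        assert tally.fp() == ins + sin_


class TestScalarMetrics:
    @pytest.mark.parametrize(
        "tp,fn,expected", [(8, 2, 0.8), (5, 0, 1.0), (0, 3, 0.0)]
    )
    def test_sensitivity(self, tp, fn, expected):
        assert pf.sensitivity(tp, fn) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "tp,fp,expected", [(8, 2, 0.2), (4, 0, 0.0), (0, 5, 1.0)]
    )
    def test_fdr(self, tp, fp, expected):
        assert pf.fdr(tp, fp) == pytest.approx(expected)

    def test_undefined_metrics_are_none(self):
        assert pf.sensitivity(0, 0) is None
        assert pf.fdr(0, 0) is None

    @pytest.mark.parametrize(
        "sens,f,expected",
        [(0.767, 0.166, 0.799), (0.720, 0.160, 0.775),
         (0.497, 0.213, 0.609), (1.0, 0.0, 1.0)],
    )
    def test_f1_reference_values(self, sens, f, expected):
        assert round(pf.f1(sens, f), 3) == pytest.approx(expected)

    def test_f1_forms_agree_on_integer_tallies(self, rng):
        for _ in range(100):
            tp = int(rng.integers(1, 50))
            fn = int(rng.integers(0, 50))
            fp = int(rng.integers(0, 50))
            s = pf.sensitivity(tp, fn)
            f = pf.fdr(tp, fp)
            assert pf.f1(s, f) == pytest.approx(
                pf.f1_from_counts(tp, fn, fp), abs=1e-12
            )

    def test_aer_examples_and_oracle(self, rng):
        assert pf.aer(("reach",) * 4, ("reach",) * 4) == 0.0
        assert pf.aer(
            ("reach", "idle", "reach", "idle"),
            ("reach", "idle", "transport", "idle"),
        ) == pytest.approx(0.25)
        assert pf.aer((), ("idle",)) is None
        for _ in range(50):
            a = tuple(rng.choice(pf.CLASSES, size=rng.integers(1, 7)))
            b = tuple(rng.choice(pf.CLASSES, size=rng.integers(0, 7)))
            assert pf.aer(a, b) == pytest.approx(
                brute_force_distance(a, b) / len(a)
            )


class TestConfusionMatrix:
    def test_perfect_predictions_identity_diagonal(self, rng):
        pairs = []
        for _ in range(30):
            s = tuple(rng.choice(pf.CLASSES, size=5))
            pairs.append((s, s))
        M = pf.confusion_matrix([pf.align(g, p) for g, p in pairs])
        for c in pf.CLASSES:
            assert M.loc[c, c] == pytest.approx(1.0)
            assert M.loc[c, "deletion"] == pytest.approx(0.0)

    def test_rows_sum_to_one(self, rng):
        alignments = []
        for _ in range(200):
            g = tuple(rng.choice(pf.CLASSES, size=rng.integers(1, 7)))
            p = tuple(rng.choice(pf.CLASSES, size=rng.integers(0, 7)))
            alignments.append(pf.align(g, p))
        M = pf.confusion_matrix(alignments)
        for c in pf.CLASSES:
            row = M.loc[c, list(pf.CLASSES) + ["deletion"]]
            assert row.sum() == pytest.approx(1.0)

    def test_matches_brute_force_recount(self, rng):
        alignments = [
            pf.align(
                tuple(rng.choice(pf.CLASSES, size=rng.integers(1, 6))),
                tuple(rng.choice(pf.CLASSES, size=rng.integers(0, 6))),
            )
            for _ in range(150)
        ]
        M = pf.confusion_matrix(alignments)
        gt_count = {c: 0 for c in pf.CLASSES}
        cell = {(r, c): 0 for r in pf.CLASSES for c in pf.CLASSES}
        for al in alignments:
            for c in al.gt:
                gt_count[c] += 1
            for op in al.ops:
                if op.op == "match":
                    cell[(op.gt, op.gt)] += 1
                elif op.op == "substitution":
                    cell[(op.gt, op.pred)] += 1
        for r in pf.CLASSES:
            for c in pf.CLASSES:
                assert M.loc[r, c] == pytest.approx(
                    cell[(r, c)] / gt_count[r]
                )


class TestBootstrap:
    def _outcomes(self, rng, n_trials=40, quality=0.8):
        out = []
        for _ in range(n_trials):
            n = int(rng.integers(5, 15))
            tp = int(rng.binomial(n, quality))
            out.append((tp, n - tp, int(rng.integers(0, 4))))
        return out

    def test_identical_models_null_comparison(self, rng):
        a = self._outcomes(rng)
        res = pf.bootstrap_compare(
            {"ref": a, "twin": list(a)},
            n_replicates=100,
            subsample=20,
            rng=np.random.default_rng(0),
        )
        assert (res.comparisons["p_bonferroni"] > 0.9).all()
        assert (res.comparisons["t"].abs() < 1e-12).all()

    def test_df_matches_replicate_count(self, rng):
        a = self._outcomes(rng)
        b = self._outcomes(rng, quality=0.6)
        res = pf.bootstrap_compare(
            {"ref": a, "rival": b},
            n_replicates=250,
            subsample=20,
            rng=np.random.default_rng(1),
        )
        assert res.df == 498
        assert (res.comparisons["df"] == 498).all()

    def test_detects_clearly_worse_model(self, rng):
        a = self._outcomes(rng, quality=0.9)
        b = self._outcomes(rng, quality=0.5)
        res = pf.bootstrap_compare(
            {"ref": a, "rival": b},
            n_replicates=100,
            subsample=30,
            rng=np.random.default_rng(2),
        )
        sens = res.comparisons.set_index("metric").loc["sensitivity"]
        assert sens["p_bonferroni"] < 1e-6
        assert sens["mean_reference"] > sens["mean_model"]

    def test_fixed_rng_reproducible(self, rng):
        a = self._outcomes(rng)
        b = self._outcomes(rng, quality=0.7)
        r1 = pf.bootstrap_compare(
            {"x": a, "y": b}, n_replicates=50, subsample=10,
            rng=np.random.default_rng(5),
        )
        r2 = pf.bootstrap_compare(
            {"x": a, "y": b}, n_replicates=50, subsample=10,
            rng=np.random.default_rng(5),
        )
        assert r1.metrics.equals(r2.metrics)

    def test_mismatched_trials_rejected(self, rng):
        a = self._outcomes(rng, n_trials=10)
        b = self._outcomes(rng, n_trials=12)
        with pytest.raises(ConfigError):
            pf.bootstrap_compare({"a": a, "b": b}, n_replicates=5,
                                 subsample=5)


class TestEvaluateSequences:
    def test_perfect_prediction_metrics(self, rng):
        pairs = [
            (s, s)
            for s in (
                tuple(rng.choice(pf.CLASSES, size=4)) for _ in range(20)
            )
        ]
        rep = pf.evaluate_sequences(pairs)
        assert rep.sensitivity == 1.0
        assert rep.fdr == 0.0
        assert rep.f1 == 1.0
        assert rep.aer == 0.0

    def test_per_class_error_frequencies_normalized(self, rng):
        pairs = [
            (
                tuple(rng.choice(pf.CLASSES, size=5)),
                tuple(rng.choice(pf.CLASSES, size=5)),
            )
            for _ in range(50)
        ]
        rep = pf.evaluate_sequences(pairs)
        for c in pf.CLASSES:
            row = rep.per_class.loc[c]
            if row["gt_count"]:
                assert row["deletion_freq"] == pytest.approx(
                    row["deletion"] / row["gt_count"]
                )
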