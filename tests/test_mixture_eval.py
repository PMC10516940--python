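"""ROC/PR evaluation and rare-mixture reweighting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from iacsim import (
    CellRecord,
    MixtureSpec,
    confusion,
    empirical_mixture_pr_curve,
    filter_evaluable,
    mixture_pr_curve,
    operating_point,
    roc_curve,
    sample_cohort,
    selection_scores,
)
from iacsim.synth import circulating_cell_mixture

from conftest import brute_force_auc


def _record(cid, label, scores, names):
    return CellRecord(cell_id=cid, true_label=label,
                      scores=np.asarray(scores, float), class_names=names)


NAMES3 = ("background", "debris", "target")


class TestFilterEvaluable:
    def test_removes_quality_labelled_cells_preserving_order(self):
        recs = [
            _record(f"c{i}", "debris" if i % 3 == 0 else "target",
                    [0.2, 0.3, 0.5], NAMES3)
            for i in range(10)
        ]
        kept = filter_evaluable(recs, {"debris"})
        assert len(kept) == 6
        assert [r.cell_id for r in kept] == [f"c{i}" for i in range(10) if i % 3]

    def test_identity_when_no_quality_cells_present(self):
        recs = [_record("a", "target", [0.2, 0.3, 0.5], NAMES3)]
        assert filter_evaluable(recs, {"debris"}) == recs

    def test_retained_fraction_matches_training_composition_preset(self, quality_model):
        """The 39.01% out-of-focus / 6.57% debris preset retains ~54.42%."""
        mix = circulating_cell_mixture(pi=0.1, background_class="background")
        cohort = sample_cohort(quality_model, mix, 10_000, seed=13)
        kept = filter_evaluable(cohort, {"debris", "out_of_focus"})
        frac = len(kept) / len(cohort)
        assert abs(frac - 0.5442) < 3 * np.sqrt(0.5442 * (1 - 0.5442) / 10_000)

    def test_unknown_quality_class_is_an_error(self):
        recs = [_record("a", "target", [0.2, 0.3, 0.5], NAMES3)]
        with pytest.raises(KeyError):
            filter_evaluable(recs, {"smudge"})


class TestSelectionScores:
    def test_positive_mode_returns_target_score(self):
        recs = [_record("a", "target", [0.2, 0.0, 0.8], NAMES3)]
        out = selection_scores(recs, "positive", "target", ["background"])
        assert out[0] == pytest.approx(0.8)

    def test_negative_mode_is_one_minus_max_background(self):
        names = ("b1", "b2", "target")
        recs = [_record("a", "target", [0.6, 0.3, 0.1], names)]
        out = selection_scores(recs, "negative", "target", ["b1", "b2"])
        assert out[0] == pytest.approx(0.4)

    def test_modes_rank_identically_under_perfect_separation(self):
        """With disjoint score supports both gates order cells the same way."""
        names = ("background", "target")
        recs = [
            _record(f"t{i}", "target", [0.1 - 0.01 * i, 0.9 + 0.01 * i], names)
            for i in range(3)
        ] + [
            _record(f"b{i}", "background", [0.8 + 0.05 * i, 0.2 - 0.05 * i], names)
            for i in range(3)
        ]
        pos = selection_scores(recs, "positive", "target", ["background"])
        neg = selection_scores(recs, "negative", "target", ["background"])
        assert np.array_equal(np.argsort(pos), np.argsort(neg))

    def test_overlapping_target_background_rejected(self):
        recs = [_record("a", "target", [0.2, 0.3, 0.5], NAMES3)]
        with pytest.raises(ValueError, match="overlaps"):
            selection_scores(recs, "positive", "target", ["target"])


class TestROC:
    def test_three_of_four_pairs_ordered(self):
        roc = roc_curve(np.array([0.9, 0.4]), np.array([0.6, 0.1]))
        assert roc.auc == pytest.approx(0.75)

    def test_identical_multisets_give_half(self):
        roc = roc_curve(np.array([0.3, 0.7]), np.array([0.3, 0.7]))
        assert roc.auc == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        roc = roc_curve(np.array([0.8, 0.9]), np.array([0.1, 0.2]))
        assert roc.auc == pytest.approx(1.0)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        roc = roc_curve(rng.normal(1, 1, 50), rng.normal(0, 1, 80))
        assert (roc.tpr[0], roc.fpr[0]) == (0.0, 0.0)
        assert (roc.tpr[-1], roc.fpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)
        assert roc.auc == pytest.approx(np.trapezoid(roc.tpr, roc.fpr), abs=1e-12)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([]), np.array([0.1]))

    @given(
        st.lists(st.integers(0, 10), min_size=1, max_size=200),
        st.lists(st.integers(0, 10), min_size=1, max_size=200),
    )
    def test_auc_equals_mann_whitney_statistic(self, t, b):
        """Trapezoid AUC on the tie-grouped curve is the pair statistic."""
        t = np.array(t) / 10.0
        b = np.array(b) / 10.0
        assert roc_curve(t, b).auc == pytest.approx(brute_force_auc(t, b), abs=1e-12)

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(21)
        t = rng.normal(1, 1, 300)
        b = rng.normal(0, 1, 400)
        y = np.r_[np.ones(300), np.zeros(400)]
        assert roc_curve(t, b).auc == pytest.approx(
            roc_auc_score(y, np.r_[t, b]), abs=1e-12
        )


class TestMixturePR:
    def test_perfect_point_maps_to_perfect_precision_recall(self):
        rng = np.random.default_rng(2)
        roc = roc_curve(rng.uniform(0.6, 1.0, 50), rng.uniform(0.0, 0.4, 50))
        pr = mixture_pr_curve(roc, 1e-4)
        i = np.flatnonzero((roc.tpr == 1.0) & (roc.fpr == 0.0))
        assert i.size and pr.precision[i[0]] == 1.0 and pr.recall[i[0]] == 1.0

    def test_reweighting_arithmetic_at_extreme_pi(self):
        # TPR=1, FPR=0.001 at pi=1e-5 -> precision 1e-5 / (1e-5 + 0.99999e-3)
        pi, tpr, fpr = 1e-5, 1.0, 1e-3
        expected = pi * tpr / (pi * tpr + (1 - pi) * fpr)
        roc = roc_curve(np.full(10, 0.9), np.r_[np.full(1, 0.9), np.full(999, 0.1)])
        pr = mixture_pr_curve(roc, pi)
        j = np.flatnonzero(np.isclose(pr.recall, 1.0) & np.isclose(roc.fpr, 1e-3))
        assert j.size and pr.precision[j[0]] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.009901, abs=5e-7)

    def test_precision_degrades_as_target_gets_rarer(self):
        rng = np.random.default_rng(3)
        roc = roc_curve(rng.normal(1, 1, 400), rng.normal(0, 1, 400))
        p_hi = mixture_pr_curve(roc, 1e-2).precision
        p_lo = mixture_pr_curve(roc, 1e-3).precision
        mask = roc.fpr > 0
        assert np.all(p_lo[mask] <= p_hi[mask] + 1e-15)

    def test_invalid_pi_rejected(self):
        roc = roc_curve(np.array([0.9]), np.array([0.1]))
        for pi in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError, match="pi"):
                mixture_pr_curve(roc, pi)

    @pytest.mark.parametrize("pi", [1e-2, 1e-3])
    def test_reweighting_agrees_with_explicit_mixture(self, pi):
        """Analytic reweighting vs a physically constructed mixture."""
        rng = np.random.default_rng(17)
        t_scores = rng.beta(5, 2, 4000)
        b_scores = rng.beta(2, 5, 4000)
        pr = mixture_pr_curve(roc_curve(t_scores, b_scores), pi)
        emp = empirical_mixture_pr_curve(t_scores, b_scores, pi, n=100_000, seed=29)
        for recall_target in (0.3, 0.5, 0.7, 0.9):
            j = int(np.argmin(np.abs(emp.recall - recall_target)))
            r_j, p_emp = emp.recall[j], emp.precision[j]
            n_t = round(100_000 * pi)
            tp = r_j * n_t
            n_called = tp / p_emp if p_emp > 0 else np.inf
            p_expected = np.interp(r_j, pr.recall, pr.precision)
            se = np.sqrt(max(p_expected * (1 - p_expected), 1e-6) / max(n_called, 1))
            assert abs(p_emp - p_expected) < 3 * se + 0.02


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        recs = [
            _record("a", "target", [0.1, 0.0, 0.9], NAMES3),
            _record("b", "background", [0.9, 0.0, 0.1], NAMES3),
        ]
        cm = confusion(recs, {"debris"})
        assert np.array_equal(np.diag(np.diag(cm.counts)), cm.counts)

    def test_hand_built_two_class_counts(self):
        names = ("A", "B")
        recs = [
            _record("1", "A", [0.9, 0.1], names),
            _record("2", "A", [0.8, 0.2], names),
            _record("3", "A", [0.3, 0.7], names),  # off-diagonal
            _record("4", "B", [0.2, 0.8], names),
        ]
        cm = confusion(recs, set())
        assert np.array_equal(cm.counts, [[2, 1], [0, 1]])
        np.testing.assert_allclose(cm.fractions[0], [2 / 3, 1 / 3])

    def test_shuffling_records_leaves_matrix_unchanged(self, quality_model):
        mix = circulating_cell_mixture(pi=0.2)
        cohort = sample_cohort(quality_model, mix, 500, seed=23)
        cm1 = confusion(cohort)
        rng = np.random.default_rng(0)
        shuffled = [cohort[i] for i in rng.permutation(len(cohort))]
        assert np.array_equal(confusion(shuffled).counts, cm1.counts)

    def test_total_count_equals_filtered_records(self, quality_model):
        mix = circulating_cell_mixture(pi=0.2)
        cohort = sample_cohort(quality_model, mix, 800, seed=5)
        cm = confusion(cohort)
        assert cm.counts.sum() == len(filter_evaluable(cohort))

    def test_all_quality_cohort_is_an_error(self):
        recs = [_record("a", "debris", [0.1, 0.8, 0.1], NAMES3)]
        with pytest.raises(ValueError, match="no evaluable"):
            confusion(recs, {"debris"})

    def test_argmax_tie_breaks_by_name_order(self):
        recs = [_record("a", "target", [0.5, 0.0, 0.5], NAMES3)]
        cm = confusion(recs, set())
        # "background" sorts before "target": the tie goes there
        assert cm.counts[NAMES3.index("target"), NAMES3.index("background")] == 1


class TestOperatingPoint:
    def _pr(self, seed=31, pi=1e-2):
        rng = np.random.default_rng(seed)
        roc = roc_curve(rng.normal(2, 1, 500), rng.normal(0, 1, 500))
        return mixture_pr_curve(roc, pi)

    def test_perfect_classifier_keeps_full_recall(self):
        roc = roc_curve(np.array([0.9, 0.95]), np.array([0.05, 0.1]))
        op = operating_point(mixture_pr_curve(roc, 1e-3), 0.7)
        assert op.attainable and op.recall == 1.0 and op.precision == 1.0

    def test_unattainable_precision_is_flagged_not_raised(self):
        from iacsim.mixture_eval import PRCurve

        pr = PRCurve(thresholds=np.array([0.5]), precision=np.array([0.5]),
                     recall=np.array([1.0]), mixture_pi=0.1)
        op = operating_point(pr, 0.7)
        assert not op.attainable and np.isnan(op.recall)

    def test_raising_min_precision_never_increases_recall(self):
        for seed in range(5):
            pr = self._pr(seed=seed)
            recalls = []
            for mp in (0.1, 0.3, 0.5, 0.7, 0.9):
                op = operating_point(pr, mp)
                recalls.append(op.recall if op.attainable else 0.0)
            assert np.all(np.diff(recalls) <= 0)

    def test_returned_point_is_consistent_with_curve(self):
        pr = self._pr()
        op = operating_point(pr, 0.5)
        j = int(np.argmin(np.abs(pr.thresholds - op.threshold)))
        assert pr.precision[j] == op.precision and pr.recall[j] == op.recall
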