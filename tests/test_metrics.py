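"""Evaluation statistics: confusion counting, proportions with exact CIs,
F-measure, kappa, agreement, and the five-row patient-level report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfquality.metrics import (
    ConfusionCounts,
    UndefinedMetricError,
    clopper_pearson_ci,
    cohens_kappa,
    concordance,
    confusion_counts,
    evaluate_run,
    f_measure,
    percent_agreement,
    ppv,
    sensitivity,
    specificity,
    wilson_ci,
)
from hfquality.simulate import CorpusSpec, generate_corpus
from hfquality.classify import run_pipeline


class TestConfusionCounts:
    def test_hand_counted_example(self):
        c = confusion_counts(["+", "+", "-"], ["+", "-", "-"], positive="+")
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 0)

    def test_identical_vectors(self):
        c = confusion_counts([1, 0, 1], [1, 0, 1], positive=1)
        assert c.fp == c.fn == 0

    def test_disjoint_vectors(self):
        c = confusion_counts([1, 1], [0, 0], positive=1)
        assert c.tp == c.tn == 0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts([1], [1, 0], positive=1)

    @given(
        st.lists(st.booleans(), min_size=1, max_size=60),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_brute_force_tally(self, gold, rnd):
        pred = [rnd.random() < 0.5 for _ in gold]
        c = confusion_counts(pred, gold, positive=True)
        # oracle: raw pairwise tally
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for p, g in zip(pred, gold):
            tally[("t" if p == g else "f") + ("p" if p else "n")] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (
            tally["tp"],
            tally["fp"],
            tally["tn"],
            tally["fn"],
        )
        assert c.total == len(gold)


class TestProportions:
    def test_sensitivity_from_counts(self):
        c = ConfusionCounts(tp=469, fp=0, tn=0, fn=5)
        r = sensitivity(c)
        assert round(r.estimate, 2) == 98.95

    def test_zero_denominator_is_a_signal(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionCounts(tp=0, fp=3, tn=2, fn=0))
        with pytest.raises(UndefinedMetricError):
            ppv(ConfusionCounts(tp=0, fp=0, tn=2, fn=1))
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionCounts(tp=2, fp=0, tn=0, fn=1))

    def test_specificity(self):
        c = ConfusionCounts(tp=0, fp=10, tn=90, fn=0)
        assert specificity(c).estimate == 90.0


class TestClopperPearson:
    def test_boundary_zero_successes(self):
        low, high = clopper_pearson_ci(0, 10)
        assert low == 0.0 and 0 < high < 100

    def test_boundary_all_successes(self):
        low, high = clopper_pearson_ci(474, 474)
        assert high == 100.0 and 0 < low < 100

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(5, 0)
        with pytest.raises(ValueError):
            clopper_pearson_ci(11, 10)

    @pytest.mark.parametrize("successes,n", [(469, 474), (3, 7), (50, 100), (1, 1000)])
    def test_matches_independent_implementation(self, successes, n):
        """Cross-check the beta-quantile form against statsmodels' exact
        binomial interval."""
        from statsmodels.stats.proportion import proportion_confint

        low, high = clopper_pearson_ci(successes, n)
        sm_low, sm_high = proportion_confint(successes, n, method="beta")
        assert low == pytest.approx(sm_low * 100, abs=1e-9)
        assert high == pytest.approx(sm_high * 100, abs=1e-9)

    def test_wilson_differs_but_brackets_estimate(self):
        low, high = wilson_ci(469, 474)
        assert low < 469 / 474 * 100 < high

    def test_coverage_of_true_proportion(self):
        """The exact interval covers the true p in at least 95% of
        replicates (with Monte-Carlo slack on the coverage estimate)."""
        rng = np.random.default_rng(20080115)
        p, n, reps = 0.3, 50, 400
        covered = 0
        for x in rng.binomial(n, p, size=reps):
            low, high = clopper_pearson_ci(int(x), n)
            covered += low <= p * 100 <= high
        # Clopper-Pearson is conservative: coverage >= nominal up to MC error
        mc_low, _ = clopper_pearson_ci(covered, reps)
        assert mc_low >= 93.0


class TestFMeasure:
    def test_harmonic_mean_identity(self):
        assert f_measure(100.0, 100.0) == 100.0

    def test_zero_convention(self):
        assert f_measure(0.0, 0.0) == 0.0

    @given(
        st.floats(0.1, 100.0, allow_nan=False),
        st.floats(0.1, 100.0, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_min_and_max(self, sn, pv):
        f = f_measure(sn, pv)
        assert min(sn, pv) - 1e-9 <= f <= max(sn, pv) + 1e-9


class TestKappa:
    def test_perfect_agreement_with_two_categories(self):
        assert cohens_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == pytest.approx(1.0)

    def test_worked_2x2_table(self):
        # table [[20, 5], [10, 65]]: p_o = 0.85, p_e = 0.60, kappa = 0.625
        a = [1] * 25 + [0] * 75
        b = [1] * 20 + [0] * 5 + [1] * 10 + [0] * 65
        assert cohens_kappa(a, b) == pytest.approx(0.625)

    def test_constant_raters_undefined(self):
        with pytest.raises(UndefinedMetricError):
            cohens_kappa([1, 1, 1], [1, 1, 1])

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(42)
        a = rng.integers(0, 2, size=4000)
        b = rng.integers(0, 2, size=4000)
        assert abs(cohens_kappa(list(a), list(b))) < 0.05

    @given(
        st.lists(st.sampled_from(["x", "y", "z"]), min_size=5, max_size=40),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_sklearn(self, a, rnd):
        from sklearn.metrics import cohen_kappa_score

        b = [rnd.choice(["x", "y", "z"]) for _ in a]
        try:
            ours = cohens_kappa(a, b)
        except UndefinedMetricError:
            return  # degenerate marginals: sklearn returns nan here
        theirs = cohen_kappa_score(a, b)
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_kappa_one_iff_perfect_with_two_categories(self):
        assert cohens_kappa(["a", "b"], ["a", "b"]) == pytest.approx(1.0)
        assert cohens_kappa(["a", "b", "a"], ["a", "b", "b"]) < 1.0


class TestPercentAgreement:
    def test_91_of_100(self):
        a = [1] * 91 + [0] * 9
        b = [1] * 91 + [1] * 9
        assert percent_agreement(a, b) == pytest.approx(91.0)

    def test_all_and_none(self):
        assert percent_agreement([1, 2], [1, 2]) == 100.0
        assert percent_agreement([1, 2], [3, 4]) == 0.0

    def test_empty_undefined(self):
        with pytest.raises(UndefinedMetricError):
            percent_agreement([], [])


class TestEvaluateRun:
    def _run(self, n=30, seed=4):
        corpus, gold = generate_corpus(CorpusSpec(n_patients=n, seed=seed))
        return run_pipeline(corpus), gold

    def test_identical_predictions_are_all_100(self):
        _, gold = self._run()
        dets = [g.determination for g in gold]
        report = evaluate_run(dets, gold)
        for row in report.rows:
            if row.sn is not None:
                assert row.sn.estimate == 100.0
            if row.ppv is not None:
                assert row.ppv.estimate == 100.0

    def test_report_always_has_five_rows(self):
        pred, gold = self._run()
        report = evaluate_run(pred, gold)
        assert [r.key for r in report.rows] == [
            "measure_met",
            "lvsf_assessed",
            "ef_lt_40",
            "on_acei_arb",
            "rnm_present",
        ]

    def test_one_flipped_patient_moves_one_count(self):
        _, gold = self._run()
        dets = [g.determination for g in gold]
        baseline = evaluate_run(dets, gold).rows[0].counts
        flipped = [d for d in dets]
        from hfquality.types import Classification, PatientDeterminations

        victim = flipped[0]
        flipped[0] = PatientDeterminations(
            patient_id=victim.patient_id,
            lvsf_assessed=victim.lvsf_assessed,
            ef=victim.ef,
            ef_lt_40=victim.ef_lt_40,
            on_acei_arb=victim.on_acei_arb,
            rnm_present=victim.rnm_present,
            classification=Classification.NOT_MET
            if victim.classification is Classification.MET
            else Classification.MET,
        )
        after = evaluate_run(flipped, gold).rows[0].counts
        deltas = [
            abs(after.tp - baseline.tp),
            abs(after.fp - baseline.fp),
            abs(after.tn - baseline.tn),
            abs(after.fn - baseline.fn),
        ]
        assert sorted(deltas) == [0, 0, 1, 1]

    def test_missing_gold_patient_excluded_and_listed(self):
        pred, gold = self._run()
        report = evaluate_run(pred, gold[1:])
        assert report.missing_from_gold == [gold[0].patient_id]
        assert report.n_patients == len(pred) - 1


class TestConcordance:
    def test_crosstab_and_kappa(self):
        a = ["on", "on", "off", "off"]
        b = ["on", "off", "off", "off"]
        result = concordance(a, b)
        assert result["n"] == 4
        assert result["percent_agreement"] == 75.0
        assert -1 <= result["kappa"] <= 1
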