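"""Four-field-table metrics, exact binomial CIs, and ROC/AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from castquotient.accuracy import (
    ContingencyTable,
    accuracy_metrics,
    build_contingency,
    roc_curve,
    stratified_accuracy,
)
from castquotient.cohort import Cohort, LightChainType
from castquotient.rule import apply_rule
from conftest import make_patient


def auc_by_pair_counting(scores, truths):
    """Independent oracle: Mann-Whitney concordance over all diseased/healthy
    pairs, ties credited one half."""
    pos = [s for s, t in zip(scores, truths) if t]
    neg = [s for s, t in zip(scores, truths) if not t]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestContingency:
    def test_observed_cohort_counts(self):
        pred = [True] * 18 + [True] * 7 + [False] * 42
        truth = [True] * 18 + [False] * 7 + [False] * 42
        assert build_contingency(pred, truth) == ContingencyTable(18, 7, 0, 42)

    def test_all_negative(self):
        assert build_contingency([False] * 5, [False] * 5) == ContingencyTable(0, 0, 0, 5)

    def test_prediction_flip_swaps_cells(self):
        pred = [True, True, False, False, True]
        truth = [True, False, True, False, False]
        t = build_contingency(pred, truth)
        flipped = build_contingency([not p for p in pred], truth)
        assert (flipped.tp, flipped.fp, flipped.fn, flipped.tn) == (t.fn, t.tn, t.tp, t.fp)

    def test_misaligned_inputs(self):
        with pytest.raises(ValueError):
            build_contingency([True], [True, False])

    def test_rejects_negative_or_empty(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 2)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


class TestAccuracyMetrics:
    @pytest.mark.parametrize(
        "table, sens, spec, ppv, npv",
        [
            (ContingencyTable(18, 7, 0, 42), 1.0, 0.857, 0.720, 1.0),
            (ContingencyTable(7, 2, 0, 20), 1.0, 0.909, 0.778, 1.0),
            (ContingencyTable(11, 5, 0, 22), 1.0, 0.815, 0.688, 1.0),
        ],
    )
    def test_observed_strata_metrics(self, table, sens, spec, ppv, npv):
        r = accuracy_metrics(table)
        assert round(r.sensitivity.value, 3) == sens
        assert round(r.specificity.value, 3) == spec
        assert round(r.ppv.value, 3) == ppv
        assert round(r.npv.value, 3) == npv

    def test_perfect_classifier(self):
        r = accuracy_metrics(ContingencyTable(4, 0, 0, 9))
        assert (r.sensitivity.value, r.specificity.value, r.ppv.value, r.npv.value) == \
            (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_reported_undefined(self):
        r = accuracy_metrics(ContingencyTable(0, 0, 3, 5))  # nothing called positive
        assert not r.ppv.defined
        assert r.npv.defined

    @given(
        tp=st.integers(0, 40), fp=st.integers(0, 40),
        fn=st.integers(0, 40), tn=st.integers(1, 40),
    )
    @settings(max_examples=100, derandomize=True)
    def test_ci_contains_point_estimate(self, tp, fp, fn, tn):
        r = accuracy_metrics(ContingencyTable(tp, fp, fn, tn))
        for m in (r.sensitivity, r.specificity, r.ppv, r.npv):
            if m.defined:
                assert m.ci_low - 1e-12 <= m.value <= m.ci_high + 1e-12

    def test_ci_width_shrinks_with_denominator(self):
        narrowing = []
        for scale in (1, 4, 16):
            r = accuracy_metrics(ContingencyTable(6 * scale, 0, 2 * scale, 1))
            narrowing.append(r.sensitivity.ci_high - r.sensitivity.ci_low)
        assert narrowing[0] > narrowing[1] > narrowing[2]


class TestRoc:
    def test_perfect_separation(self):
        curve = roc_curve([10, 9, 8, 1, 2, 3], [True, True, True, False, False, False])
        assert curve.auc == 1.0

    def test_all_tied_scores(self):
        curve = roc_curve([4.0] * 6, [True, False, True, False, True, False])
        assert curve.auc == pytest.approx(0.5)

    def test_small_instance_matches_pair_counting(self):
        # diseased {3, 5} vs non-diseased {1, 4}: 3 of 4 pairs concordant
        scores, truths = [3, 5, 1, 4], [True, True, False, False]
        curve = roc_curve(scores, truths)
        assert curve.auc == pytest.approx(0.75)
        assert auc_by_pair_counting(scores, truths) == 0.75

    def test_curve_shape_invariants(self):
        rng = np.random.default_rng(5)
        scores = np.round(rng.normal(size=40), 1)  # rounding forces ties
        truths = rng.random(40) < 0.4
        curve = roc_curve(scores, truths)
        assert (np.diff(curve.tpr) <= 1e-12).all()  # non-increasing with threshold
        assert (np.diff(curve.fpr) <= 1e-12).all()
        assert curve.tpr[0] == curve.fpr[0] == 1.0  # threshold -inf anchor
        assert curve.tpr[-1] == curve.fpr[-1] == 0.0  # threshold +inf anchor

    @given(st.data())
    @settings(max_examples=100, derandomize=True)
    def test_trapezoid_equals_pair_counting(self, data):
        n = data.draw(st.integers(4, 30))
        scores = data.draw(
            st.lists(st.integers(0, 8), min_size=n, max_size=n)  # many ties
        )
        truths = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda t: any(t) and not all(t)
            )
        )
        curve = roc_curve([float(s) for s in scores], truths)
        assert curve.auc == pytest.approx(auc_by_pair_counting(scores, truths), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [True, True])


class TestStratified:
    def test_all_equals_sum_of_strata(self, study_cohort):
        application = apply_rule(study_cohort)
        predictions = {pid: p.positive for pid, p in application.predictions.items()}
        strat = stratified_accuracy(study_cohort, predictions)
        combined = strat.reports["kappa"].table + strat.reports["lambda"].table
        assert combined == strat.reports["all"].table

    def test_single_stratum_cohort(self):
        patients = [
            make_patient(f"p{i}", lc_type=LightChainType.KAPPA,
                         involved_lc_urine=float(10 * i), egfr=20.0)
            for i in range(1, 6)
        ]
        cohort = Cohort(patients)
        predictions = {p.id: p.involved_lc_urine / p.egfr > 1 for p in patients}
        strat = stratified_accuracy(cohort, predictions)
        assert "lambda" not in strat.reports
        assert strat.reports["all"].table == strat.reports["kappa"].table

    def test_permutation_invariance(self, study_cohort):
        application = apply_rule(study_cohort)
        predictions = {pid: p.positive for pid, p in application.predictions.items()}
        a = stratified_accuracy(study_cohort, predictions)
        shuffled = Cohort(list(reversed(study_cohort.patients)), provenance="synthetic")
        b = stratified_accuracy(shuffled, predictions)
        assert a.reports["all"].table == b.reports["all"].table
        assert a.rocs["all"].auc == b.rocs["all"].auc
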