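"""Rank-based group comparisons, FDR adjustment, and group summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from castquotient.cohort import Cohort, HistologyLabel
from castquotient.groupstats import (
    benjamini_hochberg,
    dunn_posthoc,
    histology_group,
    kruskal_wallis,
    one_way_anova,
    summarize_groups,
    two_sample_t,
)
from conftest import make_patient


def kruskal_h_by_hand(groups):
    """Brute-force oracle: mid-ranks and the defining H formula with tie
    correction, independent of scipy."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty_like(pooled)
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank, 1-based
        i = j
    n = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def bh_by_hand(pvals):
    """Step-up definition with cumulative-minimum enforcement."""
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, pvals[idx] * m / rank)
        adjusted[idx] = running
    return adjusted.tolist()


class TestKruskalWallis:
    def test_matches_hand_rank_arithmetic(self):
        groups = ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        result = kruskal_wallis(*groups)
        assert result.statistic == pytest.approx(kruskal_h_by_hand(groups), rel=1e-12)
        assert result.df == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [np.round(rng.normal(size=rng.integers(4, 12)), 1) for _ in range(3)]
        result = kruskal_wallis(*groups)
        assert result.statistic == pytest.approx(kruskal_h_by_hand(groups), rel=1e-10)

    def test_degenerate_all_identical(self):
        result = kruskal_wallis([2.0, 2.0], [2.0, 2.0, 2.0])
        assert result.degenerate
        assert result.statistic == 0.0 and result.pvalue == 1.0

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20) + 100.0
        assert kruskal_wallis(a, b).pvalue < 1e-3

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        groups = [rng.gamma(2.0, size=12) for _ in range(3)]
        h1 = kruskal_wallis(*groups).statistic
        h2 = kruskal_wallis(*[np.log(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0])
        with pytest.raises(ValueError):
            kruskal_wallis([1.0], [])


class TestDunn:
    @pytest.mark.parametrize("seed", range(10))
    def test_two_group_z_squared_equals_h(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = np.round(rng.normal(size=11), 1)
        b = np.round(rng.normal(0.5, size=14), 1)
        h = kruskal_wallis(a, b).statistic
        (pair,) = dunn_posthoc([a, b], adjust=False)
        assert pair.z**2 == pytest.approx(h, rel=1e-10)

    def test_identical_groups_null(self):
        (pair,) = dunn_posthoc([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], adjust=False)
        assert pair.z == 0.0 and pair.pvalue == 1.0

    def test_pair_count_and_adjustment_dominance(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(loc, 1, 15) for loc in (0.0, 0.2, 1.5, 3.0)]
        results = dunn_posthoc(groups, labels=list("abcd"))
        assert len(results) == 6
        for r in results:
            assert r.pvalue_adjusted >= r.pvalue - 1e-15
            assert r.pvalue_adjusted <= 1.0

    def test_clearly_shifted_pair_significant(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(8, 1, 20)]
        results = dunn_posthoc(groups, labels=["x", "y", "z"])
        by_pair = {r.pair: r for r in results}
        assert by_pair[("x", "z")].pvalue_adjusted < 0.05
        assert by_pair[("x", "y")].pvalue_adjusted > 0.05


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.037]) == [0.037]

    def test_worked_example(self):
        assert benjamini_hochberg([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=200, derandomize=True)
    def test_matches_stepup_definition_and_dominates(self, pvals):
        adjusted = benjamini_hochberg(pvals)
        assert adjusted == pytest.approx(bh_by_hand(pvals), abs=1e-12)
        for raw, adj in zip(pvals, adjusted):
            assert raw - 1e-15 <= adj <= 1.0
        # order preservation
        order_raw = np.argsort(pvals, kind="mergesort")
        assert (np.diff(np.asarray(adjusted)[order_raw]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestTAndAnova:
    def test_equal_samples_null(self):
        a = [1.0, 2.0, 3.0, 4.0]
        result = two_sample_t(a, list(a))
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.pvalue == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_pooled_t_squared_equals_anova_f(self, seed):
        rng = np.random.default_rng(200 + seed)
        a, b = rng.normal(size=12), rng.normal(0.7, 1.2, size=9)
        t = two_sample_t(a, b, equal_var=True)
        f = one_way_anova(a, b)
        assert t.statistic**2 == pytest.approx(f.statistic, rel=1e-10)
        assert t.pvalue == pytest.approx(f.pvalue, rel=1e-10)

    def test_welch_df_smaller_under_unequal_variance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.1, 30)
        b = rng.normal(3.0, 5.0, 8)
        welch = two_sample_t(a, b)
        pooled = two_sample_t(a, b, equal_var=True)
        assert welch.df < pooled.df == len(a) + len(b) - 2

    def test_preconditions(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])


class TestGroupSummary:
    def test_histology_grouping(self):
        assert histology_group(HistologyLabel.CAST_NEPHROPATHY) == "CN"
        assert histology_group(HistologyLabel.MIDD) == "MIDD"
        assert histology_group(HistologyLabel.LIGHT_CHAIN_PROXIMAL_TUBULOPATHY) == "Others"
        assert histology_group(HistologyLabel.NEPHROANGIOSCLEROSIS) == "Others"

    def test_single_value_group(self):
        cohort = Cohort([make_patient(histology=HistologyLabel.MIDD, egfr=23.7)])
        summary = summarize_groups(cohort)
        row = summary.loc[("MIDD", "egfr")]
        assert row["median"] == 23.7 and row["iqr"] == 0.0 and row["n"] == 1

    def test_duplication_invariance_of_median(self, study_cohort):
        base = summarize_groups(study_cohort)
        doubled = Cohort(
            [make_patient(f"d{i}", **{
                k: getattr(p, k) for k in (
                    "age", "sex", "lc_type", "egfr", "involved_flc_serum",
                    "involved_lc_urine", "proteinuria", "histology")
            }) for i, p in enumerate(list(study_cohort) * 2)],
            provenance="synthetic",
        )
        dup = summarize_groups(doubled)
        for idx in base.index:
            assert dup.loc[idx, "median"] == pytest.approx(base.loc[idx, "median"])
            assert dup.loc[idx, "n"] == 2 * base.loc[idx, "n"]

    def test_n_sums_to_cohort_size(self, study_cohort):
        summary = summarize_groups(study_cohort)
        per_group = summary.xs("egfr", level="variable")["n"]
        assert per_group.sum() == len(study_cohort)
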