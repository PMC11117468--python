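"""Group comparisons across the four histology strata: CN, ALA, MIDD, Others.

Continuous lab variables (eGFR, involved serum FLC, involved urine LC, and
the quotient) are summarized as median (IQR) per group and compared with a
Kruskal-Wallis omnibus test; pairwise differences use Dunn's rank-based post
hoc test with Benjamini-Hochberg adjustment across the pairs of one variable.
Welch's t-test and one-way ANOVA are provided for two-group mean comparisons
(e.g. CN vs all other kidney disease).

Kruskal-Wallis, t-test and ANOVA are delegated to scipy.stats and the BH
step-up to statsmodels; Dunn's z statistics (pooled mid-ranks with tie
correction) are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort, HistologyLabel

__all__ = [
    "GROUP_LABELS",
    "histology_group",
    "summarize_groups",
    "OmnibusResult",
    "PairwiseResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "benjamini_hochberg",
    "two_sample_t",
    "one_way_anova",
]

GROUP_LABELS = ("CN", "ALA", "MIDD", "Others")

_GROUP_OF_HISTOLOGY = {
    HistologyLabel.CAST_NEPHROPATHY: "CN",
    HistologyLabel.AL_AMYLOIDOSIS: "ALA",
    HistologyLabel.MIDD: "MIDD",
}


def histology_group(label: HistologyLabel) -> str:
    """Collapse a biopsy label to CN / ALA / MIDD / Others."""
    return _GROUP_OF_HISTOLOGY.get(HistologyLabel(label), "Others")


# Variables summarized per group; quotient is derived per patient.
SUMMARY_VARIABLES = ("egfr", "involved_flc_serum", "involved_lc_urine", "quotient")


def cohort_groups_frame(cohort: Cohort) -> pd.DataFrame:
    """Long frame: one row per patient with group label and the four variables."""
    rows = []
    for p in cohort:
        rows.append(
            {
                "id": p.id,
                "group": histology_group(p.histology),
                "egfr": p.egfr,
                "involved_flc_serum": p.involved_flc_serum,
                "involved_lc_urine": p.involved_lc_urine,
                "quotient": p.involved_lc_urine / p.egfr,
            }
        )
    return pd.DataFrame(rows)


def summarize_groups(cohort: Cohort) -> pd.DataFrame:
    """Median and IQR of each variable by histology group.

    Quartiles use linear interpolation between order statistics (the numpy
    default), the convention also used to calibrate the cohort simulator.
    Returns a frame indexed by (group, variable) with columns n/median/iqr.
    """
    df = cohort_groups_frame(cohort)
    records = []
    for group in GROUP_LABELS:
        values = df[df["group"] == group]
        if values.empty:
            continue
        for var in SUMMARY_VARIABLES:
            x = values[var].to_numpy(dtype=float)
            q25, q50, q75 = np.percentile(x, [25, 50, 75])
            records.append(
                {"group": group, "variable": var, "n": len(x),
                 "median": q50, "iqr": q75 - q25}
            )
    return pd.DataFrame(records).set_index(["group", "variable"])


@dataclass(frozen=True)
class OmnibusResult:
    statistic: float  # H (Kruskal-Wallis) or F (ANOVA)
    df: float
    pvalue: float
    tie_correction: float | None = None
    degenerate: bool = False  # all values identical across groups


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    z: float
    pvalue: float  # raw, two-sided
    pvalue_adjusted: float | None = None


def _tie_correction(values: np.ndarray) -> float:
    """1 - sum(t^3 - t) / (N^3 - N) over tie groups; 1.0 when untied."""
    n = values.size
    if n < 2:
        return 1.0
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)


def kruskal_wallis(*samples: Sequence[float]) -> OmnibusResult:
    """Kruskal-Wallis H on mid-ranks with tie correction, chi-square p-value."""
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need at least three observations in total")
    if np.all(pooled == pooled[0]):
        return OmnibusResult(0.0, len(groups) - 1, 1.0,
                             tie_correction=0.0, degenerate=True)
    h, p = stats.kruskal(*groups)
    return OmnibusResult(float(h), len(groups) - 1, float(p),
                         tie_correction=_tie_correction(pooled))


def dunn_posthoc(
    samples: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: bool = True,
) -> list[PairwiseResult]:
    """Dunn's rank-based post hoc test for all group pairs.

    z for pair (i, j) compares mean pooled mid-ranks with standard error
    sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)), T = sum(t^3 - t)/(12(N-1)) over
    tie groups; two-sided normal p-values, BH-adjusted across the pairs
    unless ``adjust`` is False.
    """
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("labels must match samples")

    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)  # mid-ranks
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term

    results = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(variance_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
        if se == 0:  # every pooled value identical
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        results.append(PairwiseResult((labels[i], labels[j]), float(z), min(float(p), 1.0)))

    if adjust:
        adjusted = benjamini_hochberg([r.pvalue for r in results])
        results = [
            PairwiseResult(r.pair, r.z, r.pvalue, adj)
            for r, adj in zip(results, adjusted)
        ]
    return results


def benjamini_hochberg(pvals: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def two_sample_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> OmnibusResult:
    """Two-sample t-test, Welch form by default (pooled with equal_var=True)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return OmnibusResult(float(res.statistic), float(res.df), float(res.pvalue))


def one_way_anova(*samples: Sequence[float]) -> OmnibusResult:
    """Classical one-way fixed-effects ANOVA F-test."""
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need at least two groups with two observations each")
    f, p = stats.f_oneway(*groups)
    df_between = len(groups) - 1
    return OmnibusResult(float(f), float(df_between), float(p))
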