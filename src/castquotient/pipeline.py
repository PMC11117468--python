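"""End-to-end analysis driver: classify, tabulate, stratify, compare, report.

``run_analysis`` reproduces the full validation analysis on any cohort file
or in-memory cohort: rule predictions, 2x2 tables and accuracy metrics
overall and per LC type, ROC curves on the raw quotient, per-group lab
summaries, and the Kruskal-Wallis / Dunn / Benjamini-Hochberg battery.
``replicate_table3`` re-derives the published stratified accuracy metrics
from the 2x2 counts observed in the original two-centre cohort.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .accuracy import (
    AccuracyReport,
    ContingencyTable,
    RocCurve,
    StratifiedAccuracy,
    accuracy_metrics,
    stratified_accuracy,
)
from .cohort import Cohort, cohort_summary_counts, read_cohort
from .groupstats import (
    OmnibusResult,
    PairwiseResult,
    SUMMARY_VARIABLES,
    cohort_groups_frame,
    dunn_posthoc,
    kruskal_wallis,
    summarize_groups,
)
from .rule import RuleApplication, RuleThresholds, apply_rule

__all__ = [
    "OBSERVED_CONTINGENCY",
    "AnalysisReport",
    "run_analysis",
    "replicate_table3",
]

# 2x2 counts (tp, fp, fn, tn) of rule vs biopsy observed in the original
# two-centre validation cohort (n = 67), overall and by involved LC type.
OBSERVED_CONTINGENCY: dict[str, ContingencyTable] = {
    "all": ContingencyTable(tp=18, fp=7, fn=0, tn=42),
    "lambda": ContingencyTable(tp=7, fp=2, fn=0, tn=20),
    "kappa": ContingencyTable(tp=11, fp=5, fn=0, tn=22),
}

# Accuracy metrics reported for those counts (sens, spec, ppv, npv), at the
# precision they were reported with.
OBSERVED_METRICS: dict[str, tuple[float, float, float, float]] = {
    "all": (1.0, 0.857, 0.72, 1.0),
    "lambda": (1.0, 0.909, 0.778, 1.0),
    "kappa": (1.0, 0.815, 0.688, 1.0),
}


@dataclass
class VariableComparison:
    variable: str
    omnibus: OmnibusResult
    pairwise: list[PairwiseResult]


@dataclass
class AnalysisReport:
    """Everything the validation analysis produces, fully recomputable."""

    counts: dict
    thresholds: RuleThresholds
    rule: RuleApplication
    accuracy: StratifiedAccuracy
    group_summary: pd.DataFrame
    comparisons: list[VariableComparison]
    ci_level: float
    ckdepi_version: str
    software_version: str = __version__

    def to_dict(self) -> dict:
        """JSON-serializable structured report (full precision)."""
        def metric(m):
            return {
                "value": m.value, "ci_low": m.ci_low, "ci_high": m.ci_high,
                "numerator": m.numerator, "denominator": m.denominator,
            }

        def acc(r: AccuracyReport):
            return {
                "stratum": r.stratum,
                "table": asdict(r.table),
                "sensitivity": metric(r.sensitivity),
                "specificity": metric(r.specificity),
                "ppv": metric(r.ppv),
                "npv": metric(r.npv),
                "ci_level": r.ci_level,
            }

        def roc(c: RocCurve):
            return {
                "thresholds": [float(t) for t in c.thresholds],
                "tpr": c.tpr.tolist(),
                "fpr": c.fpr.tolist(),
                "auc": c.auc,
            }

        return {
            "software_version": self.software_version,
            "config": {
                "thresholds": asdict(self.thresholds),
                "ci_level": self.ci_level,
                "ckdepi_version": self.ckdepi_version,
            },
            "counts": self.counts,
            "exclusions": self.rule.exclusions,
            "predictions": {
                pid: {
                    "quotient": pred.quotient,
                    "positive": pred.positive,
                    "branch": pred.branch.value,
                }
                for pid, pred in self.rule.predictions.items()
            },
            "accuracy": {name: acc(r) for name, r in self.accuracy.reports.items()},
            "roc": {name: roc(c) for name, c in self.accuracy.rocs.items()},
            "group_summary": [
                {"group": g, "variable": v, **row}
                for (g, v), row in self.group_summary.to_dict("index").items()
            ],
            "comparisons": [
                {
                    "variable": c.variable,
                    "omnibus": asdict(c.omnibus),
                    "pairwise": [
                        {"pair": list(p.pair), "z": p.z, "p": p.pvalue,
                         "p_adjusted": p.pvalue_adjusted}
                        for p in c.pairwise
                    ],
                }
                for c in self.comparisons
            ],
        }

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def run_analysis(
    cohort: Cohort | str | Path,
    thresholds: RuleThresholds = RuleThresholds(),
    ci_level: float = 0.95,
    ckdepi_version: str = "2009",
    posthoc_gate: float | None = 0.05,
) -> AnalysisReport:
    """Run the full validation analysis on a cohort (path or object).

    Deterministic given the cohort and configuration.  Dunn's post hoc test
    is run per variable only when the Kruskal-Wallis omnibus p-value passes
    ``posthoc_gate`` (set None to always run it).
    """
    if not isinstance(cohort, Cohort):
        cohort = read_cohort(cohort)
    cohort.validate(check_consistency=False)

    rule = apply_rule(cohort, thresholds)
    predictions = {pid: pred.positive for pid, pred in rule.predictions.items()}
    accuracy = stratified_accuracy(cohort, predictions, ci_level=ci_level)

    frame = cohort_groups_frame(cohort)
    comparisons = []
    for variable in SUMMARY_VARIABLES:
        groups, labels = [], []
        for label, sub in frame.groupby("group"):
            groups.append(sub[variable].to_numpy())
            labels.append(label)
        if len(groups) < 2:
            continue
        omnibus = kruskal_wallis(*groups)
        pairwise = []
        if posthoc_gate is None or omnibus.pvalue < posthoc_gate:
            pairwise = dunn_posthoc(groups, labels)
        comparisons.append(VariableComparison(variable, omnibus, pairwise))

    return AnalysisReport(
        counts=cohort_summary_counts(cohort),
        thresholds=thresholds,
        rule=rule,
        accuracy=accuracy,
        group_summary=summarize_groups(cohort),
        comparisons=comparisons,
        ci_level=ci_level,
        ckdepi_version=ckdepi_version,
    )


def replicate_table3(
    counts: Mapping[str, ContingencyTable] | None = None,
    reference: Mapping[str, tuple[float, float, float, float]] | None = None,
) -> str:
    """Recompute stratified accuracy metrics from 2x2 counts and format them
    beside the originally reported values (rounded to reporting precision).

    Stored metric values stay full precision; rounding here is presentation
    only (3 decimals, matching how the study reported them).
    """
    counts = dict(OBSERVED_CONTINGENCY if counts is None else counts)
    reference = dict(OBSERVED_METRICS if reference is None else reference)
    lines = [
        f"{'stratum':<8} {'metric':<12} {'computed':>9} {'reported':>9}",
        "-" * 42,
    ]
    for stratum, table in counts.items():
        report = accuracy_metrics(table)
        ref = reference.get(stratum)
        for k, name in enumerate(("sensitivity", "specificity", "ppv", "npv")):
            estimate = getattr(report, name)
            computed = "n/a" if estimate.value is None else f"{round(estimate.value, 3):g}"
            reported = f"{ref[k]:g}" if ref is not None else "-"
            lines.append(f"{stratum:<8} {name:<12} {computed:>9} {reported:>9}")
    return "\n".join(lines)
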