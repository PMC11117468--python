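"""Four-field-table diagnostic accuracy and ROC analysis, overall and by LC type.

Sensitivity, specificity, PPV and NPV are the defining ratios of the 2x2
table of rule prediction against biopsy-proven cast nephropathy, each with an
exact (Clopper-Pearson) binomial confidence interval.  The ROC curve treats
the raw quotient as a score with higher values indicating disease; its AUC is
the normalized Mann-Whitney concordance (ties credited one half).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort, LightChainType

__all__ = [
    "ContingencyTable",
    "MetricEstimate",
    "AccuracyReport",
    "RocCurve",
    "build_contingency",
    "accuracy_metrics",
    "roc_curve",
    "stratified_accuracy",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN counts of rule prediction vs biopsy diagnosis."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if any(c < 0 or c != int(c) for c in (self.tp, self.fp, self.fn, self.tn)):
            raise ValueError("cell counts must be non-negative integers")
        if self.total < 1:
            raise ValueError("contingency table must contain at least one subject")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def build_contingency(
    predictions: Sequence[bool], truths: Sequence[bool]
) -> ContingencyTable:
    """Cross-tabulate aligned prediction/truth booleans into a 2x2 table."""
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must be aligned and equal length")
    pred = np.asarray(predictions, dtype=bool)
    truth = np.asarray(truths, dtype=bool)
    return ContingencyTable(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its exact binomial CI; None when the denominator is 0."""

    value: float | None
    ci_low: float | None
    ci_high: float | None
    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.value is not None


def _proportion(numerator: int, denominator: int, ci_level: float) -> MetricEstimate:
    if denominator == 0:
        return MetricEstimate(None, None, None, numerator, denominator)
    low, high = proportion_confint(numerator, denominator, alpha=1 - ci_level, method="beta")
    return MetricEstimate(numerator / denominator, float(low), float(high), numerator, denominator)


@dataclass(frozen=True)
class AccuracyReport:
    """Sensitivity/specificity/PPV/NPV for one stratum with exact CIs."""

    table: ContingencyTable
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    stratum: str = "all"
    ci_level: float = 0.95


def accuracy_metrics(
    table: ContingencyTable, ci_level: float = 0.95, stratum: str = "all"
) -> AccuracyReport:
    """The four standard metrics with Clopper-Pearson intervals.

    A metric whose denominator is zero (e.g. PPV with no positive calls) is
    reported as undefined, never coerced to 0 or 1.
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    return AccuracyReport(
        table=table,
        sensitivity=_proportion(table.tp, table.tp + table.fn, ci_level),
        specificity=_proportion(table.tn, table.tn + table.fp, ci_level),
        ppv=_proportion(table.tp, table.tp + table.fp, ci_level),
        npv=_proportion(table.tn, table.tn + table.fn, ci_level),
        stratum=stratum,
        ci_level=ci_level,
    )


@dataclass(frozen=True)
class RocCurve:
    """Operating points sorted by increasing threshold, with trapezoidal AUC.

    ``thresholds[0]`` is -inf (everything called positive, the (1,1) anchor);
    the last threshold is +inf-like (nothing positive, the (0,0) anchor).
    TPR and FPR are non-increasing in the threshold.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def operating_points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds.tolist(), self.tpr.tolist(), self.fpr.tolist()))


def roc_curve(scores: Sequence[float], truths: Sequence[bool]) -> RocCurve:
    """ROC over quotient scores (higher score = more likely diseased).

    Ties are grouped at a single operating point; the AUC by trapezoidal
    integration then equals the Mann-Whitney pair-counting statistic with
    ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=bool)
    if scores.shape != truths.shape or scores.ndim != 1:
        raise ValueError("scores and truths must be aligned 1-d sequences")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if truths.all() or not truths.any():
        raise ValueError("ROC needs at least one diseased and one non-diseased subject")
    fpr, tpr, thresh = _sk_roc_curve(truths, scores)
    # sklearn orders by decreasing threshold (first point is the (0,0) anchor
    # with threshold +inf); reverse to increasing-threshold convention and
    # replace the synthetic top threshold with +inf explicitly.
    thresh = thresh.astype(float)
    thresh[0] = np.inf
    order = slice(None, None, -1)
    curve_thresh = np.concatenate(([-np.inf], thresh[order]))
    curve_tpr = np.concatenate(([1.0], tpr[order]))
    curve_fpr = np.concatenate(([1.0], fpr[order]))
    return RocCurve(
        thresholds=curve_thresh,
        tpr=curve_tpr,
        fpr=curve_fpr,
        auc=float(_trapezoid_auc(fpr, tpr)),
    )


@dataclass(frozen=True)
class StratifiedAccuracy:
    reports: dict[str, AccuracyReport]
    rocs: dict[str, RocCurve]


def stratified_accuracy(
    cohort: Cohort,
    predictions: Mapping[str, bool],
    ci_level: float = 0.95,
) -> StratifiedAccuracy:
    """Accuracy report and ROC for all patients and per LC-type stratum.

    ``predictions`` maps patient id to the rule call; patients without a
    prediction (excluded as unclassifiable) are omitted.  A stratum whose
    classified patients are single-class gets no ROC (logged and skipped).
    The all-patients contingency table is by construction the cell-wise sum
    of the two LC-type strata.
    """
    strata: dict[str, list] = {"all": [], "kappa": [], "lambda": []}
    for patient in cohort:
        if patient.id not in predictions:
            continue
        entry = (
            bool(predictions[patient.id]),
            patient.is_cn,
            patient.involved_lc_urine / patient.egfr,
        )
        strata["all"].append(entry)
        strata[LightChainType(patient.lc_type).value].append(entry)

    reports: dict[str, AccuracyReport] = {}
    rocs: dict[str, RocCurve] = {}
    for name, rows in strata.items():
        if not rows:
            logger.warning("stratum %s empty; skipped", name)
            continue
        preds, truths, scores = (list(t) for t in zip(*rows))
        reports[name] = accuracy_metrics(build_contingency(preds, truths), ci_level, stratum=name)
        try:
            rocs[name] = roc_curve(scores, truths)
        except ValueError as err:
            logger.warning("stratum %s: no ROC (%s)", name, err)
    return StratifiedAccuracy(reports=reports, rocs=rocs)
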