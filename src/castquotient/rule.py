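"""The urine light-chain/eGFR quotient and the LC-type-specific decision rule.

Cast nephropathy (CN) combines severe loss of filtration with massive urinary
excretion of the involved monoclonal light chain, so the quotient

    Q = involved LC in urine (mg/dL) / eGFR (mL/min/1.73 m²)

is high in CN and low in the other paraprotein-associated kidney diseases.
The decision rule is light-chain-type specific:

* lambda LC: positive iff Q > 2;
* kappa LC: positive iff Q > 5, or 1 < Q <= 5 and proteinuria < 8 g/24 h.

All comparisons are strict at the cut points.  Under this convention the
published "Q in 1–5" interval phrasing and the "Q > 1 and proteinuria
< 8 g/24 h or Q > 5" phrasing are logically identical (the region with
Q > 5 is positive regardless of proteinuria).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .cohort import Cohort, LightChainType, Patient

__all__ = [
    "RuleThresholds",
    "RuleBranch",
    "RulePrediction",
    "UnclassifiableError",
    "lc_egfr_quotient",
    "classify_cn",
    "apply_rule",
]


class UnclassifiableError(ValueError):
    """The deciding rule branch needs a value that is missing (or undefined)."""


@dataclass(frozen=True)
class RuleThresholds:
    """Cut points of the decision rule; defaults are the published limits."""

    lambda_cut: float = 2.0
    kappa_high_cut: float = 5.0
    kappa_low_cut: float = 1.0
    proteinuria_cut: float = 8000.0  # mg/24 h

    def __post_init__(self) -> None:
        if not 0 < self.kappa_low_cut < self.kappa_high_cut:
            raise ValueError("require 0 < kappa_low_cut < kappa_high_cut")
        if not self.lambda_cut > 0:
            raise ValueError("lambda_cut must be > 0")
        if not self.proteinuria_cut > 0:
            raise ValueError("proteinuria_cut must be > 0")


class RuleBranch(str, Enum):
    LAMBDA_MAIN = "lambda_main"
    KAPPA_HIGH = "kappa_high"
    KAPPA_LOW_WITH_PROTEINURIA = "kappa_low_with_proteinuria"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class RulePrediction:
    quotient: float
    positive: bool
    branch: RuleBranch
    lc_type: LightChainType
    proteinuria: float | None = None

    def __post_init__(self) -> None:
        assert self.positive == (self.branch is not RuleBranch.NEGATIVE)


def lc_egfr_quotient(involved_lc_urine: float, egfr: float) -> float:
    """Urine involved-LC concentration divided by eGFR (dimensionless scale).

    Undefined for eGFR <= 0: with anuria the quotient cannot be determined
    and biopsy remains the only option.
    """
    if not egfr > 0:
        raise ValueError(
            "quotient undefined for eGFR <= 0 (anuric/undefined kidney function)"
        )
    if involved_lc_urine < 0:
        raise ValueError("involved_lc_urine must be >= 0")
    return involved_lc_urine / egfr


def classify_cn(
    lc_type: LightChainType | str,
    quotient: float,
    proteinuria: float | None = None,
    thresholds: RuleThresholds = RuleThresholds(),
) -> RulePrediction:
    """Apply the LC-type-specific rule to one patient's quotient.

    ``proteinuria`` (mg/24 h) is only consulted for kappa LC with quotient in
    the branch-sensitive interval (kappa_low_cut, kappa_high_cut]; if missing
    there, the patient is unclassifiable.
    """
    lc_type = LightChainType(lc_type)
    if quotient < 0:
        raise ValueError("quotient must be >= 0")
    if proteinuria is not None and proteinuria < 0:
        raise ValueError("proteinuria must be >= 0")

    if lc_type is LightChainType.LAMBDA:
        branch = RuleBranch.LAMBDA_MAIN if quotient > thresholds.lambda_cut else RuleBranch.NEGATIVE
    elif quotient > thresholds.kappa_high_cut:
        branch = RuleBranch.KAPPA_HIGH
    elif quotient > thresholds.kappa_low_cut:
        if proteinuria is None:
            raise UnclassifiableError(
                "kappa patient with quotient in the proteinuria-dependent range "
                f"({thresholds.kappa_low_cut:g}, {thresholds.kappa_high_cut:g}] "
                "but no 24-h proteinuria"
            )
        branch = (
            RuleBranch.KAPPA_LOW_WITH_PROTEINURIA
            if proteinuria < thresholds.proteinuria_cut
            else RuleBranch.NEGATIVE
        )
    else:
        branch = RuleBranch.NEGATIVE

    return RulePrediction(
        quotient=quotient,
        positive=branch is not RuleBranch.NEGATIVE,
        branch=branch,
        lc_type=lc_type,
        proteinuria=proteinuria,
    )


@dataclass
class RuleApplication:
    """Per-patient predictions plus logged exclusions."""

    predictions: dict[str, RulePrediction]
    exclusions: dict[str, str] = field(default_factory=dict)


def apply_rule(
    cohort: Cohort | Iterable[Patient],
    thresholds: RuleThresholds = RuleThresholds(),
) -> RuleApplication:
    """Classify every classifiable patient in the cohort; log the rest.

    A kappa patient whose quotient falls in the proteinuria-dependent range
    without a recorded 24-h proteinuria is excluded with a reason, never
    silently coerced.  Raises if no patient is classifiable.
    """
    predictions: dict[str, RulePrediction] = {}
    exclusions: dict[str, str] = {}
    for patient in cohort:
        try:
            q = lc_egfr_quotient(patient.involved_lc_urine, patient.egfr)
            predictions[patient.id] = classify_cn(
                patient.lc_type, q, patient.proteinuria, thresholds
            )
        except (UnclassifiableError, ValueError) as err:
            exclusions[patient.id] = str(err)
    if not predictions:
        raise UnclassifiableError("no classifiable patients in cohort")
    return RuleApplication(predictions=predictions, exclusions=exclusions)
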