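"""CKD-EPI creatinine-based estimation of the glomerular filtration rate.

The estimated GFR (eGFR, mL/min/1.73 m²) is a piecewise power law of serum
creatinine with sex-specific knot ``kappa`` and low-range exponent ``alpha``::

    eGFR = scale * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^high_exponent
           * age_base^age * female_factor[if female] * race_factor

Both the 2009 equation (default, race factor 1.0 as customary in European
laboratories) and the 2021 race-free refit are provided.  Because the map is
a strictly monotone piecewise power law it has a closed-form inverse, which
the synthetic-cohort generator uses to attach a serum creatinine consistent
with a sampled eGFR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "CkdEpiParams",
    "CKDEPI_2009",
    "CKDEPI_2021",
    "get_params",
    "egfr_ckdepi",
    "creatinine_from_egfr",
]

Sex = Literal["female", "male"]

ADULT_AGE_MIN = 18.0
ADULT_AGE_MAX = 110.0


@dataclass(frozen=True)
class CkdEpiParams:
    """Constants of one CKD-EPI creatinine equation version."""

    kappa_female: float = 0.7  # mg/dL, sex-specific creatinine knot
    kappa_male: float = 0.9
    alpha_female: float = -0.329  # low-range exponent
    alpha_male: float = -0.411
    high_exponent: float = -1.209
    age_base: float = 0.993  # per-year decline factor
    scale: float = 141.0
    female_factor: float = 1.018
    race_factor: float = 1.0
    version: str = "2009"

    def __post_init__(self) -> None:
        for name in ("kappa_female", "kappa_male", "age_base", "scale",
                     "female_factor", "race_factor"):
            if not getattr(self, name) > 0:
                raise ValueError(f"CkdEpiParams.{name} must be > 0")
        for name in ("alpha_female", "alpha_male", "high_exponent"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"CkdEpiParams.{name} must be finite")

    def knot(self, sex: Sex) -> float:
        return self.kappa_female if sex == "female" else self.kappa_male

    def alpha(self, sex: Sex) -> float:
        return self.alpha_female if sex == "female" else self.alpha_male

    def sex_factor(self, sex: Sex) -> float:
        return self.female_factor if sex == "female" else 1.0


CKDEPI_2009 = CkdEpiParams()
CKDEPI_2021 = CkdEpiParams(
    alpha_female=-0.241,
    alpha_male=-0.302,
    high_exponent=-1.200,
    age_base=0.9938,
    scale=142.0,
    female_factor=1.012,
    version="2021",
)

_VERSIONS = {"2009": CKDEPI_2009, "2021": CKDEPI_2021}


def get_params(version: str = "2009", race_factor: float | None = None) -> CkdEpiParams:
    """Look up an equation version, optionally overriding the race factor."""
    try:
        params = _VERSIONS[str(version)]
    except KeyError:
        raise ValueError(f"unknown CKD-EPI version {version!r}; choose 2009 or 2021")
    if race_factor is not None:
        params = replace(params, race_factor=race_factor)
    return params


def _check_age(age) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    if np.any(age < ADULT_AGE_MIN) or np.any(age > ADULT_AGE_MAX):
        raise ValueError(
            f"age must lie in the adult range [{ADULT_AGE_MIN:g}, {ADULT_AGE_MAX:g}]"
        )
    return age


def _base_factor(age, sex: Sex, params: CkdEpiParams) -> np.ndarray:
    """eGFR at the knot creatinine: scale * age_base^age * sex and race factors."""
    age = _check_age(age)
    return params.scale * params.age_base ** age * params.sex_factor(sex) * params.race_factor


def egfr_ckdepi(creatinine, age, sex: Sex, params: CkdEpiParams = CKDEPI_2009):
    """eGFR (mL/min/1.73 m²) from serum creatinine (mg/dL), age (years), sex.

    Accepts scalars or arrays (broadcast).  Strictly decreasing in both
    creatinine and age; the two power-law branches meet continuously at the
    sex-specific knot.
    """
    creatinine = np.asarray(creatinine, dtype=float)
    if np.any(creatinine <= 0):
        raise ValueError("serum creatinine must be > 0 mg/dL")
    ratio = creatinine / params.knot(sex)
    egfr = (
        _base_factor(age, sex, params)
        * np.minimum(ratio, 1.0) ** params.alpha(sex)
        * np.maximum(ratio, 1.0) ** params.high_exponent
    )
    return egfr if egfr.ndim else float(egfr)


def creatinine_from_egfr(egfr, age, sex: Sex, params: CkdEpiParams = CKDEPI_2009):
    """Serum creatinine (mg/dL) whose CKD-EPI eGFR equals ``egfr`` — exact inverse.

    The branch is chosen by comparing ``egfr`` with the knot-point eGFR for the
    given age/sex; each branch is a pure power law and inverts in closed form.
    """
    egfr = np.asarray(egfr, dtype=float)
    if np.any(egfr <= 0):
        raise ValueError("egfr must be > 0")
    base = _base_factor(age, sex, params)
    r = egfr / base
    # egfr >= knot eGFR  <=>  creatinine <= kappa  (low branch, exponent alpha)
    exponent = np.where(r >= 1.0, 1.0 / params.alpha(sex), 1.0 / params.high_exponent)
    creatinine = params.knot(sex) * r ** exponent
    return creatinine if creatinine.ndim else float(creatinine)
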