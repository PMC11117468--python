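"""Patient-level data model, validation, and delimited-text cohort I/O.

One row per patient at the time of kidney biopsy: demographics, involved
light-chain type, serum creatinine, eGFR, involved free light chain in serum,
involved light chain in urine, 24-h proteinuria, and the histological
diagnosis.  Units are fixed: creatinine mg/dL, eGFR mL/min/1.73 m², serum FLC
and urine LC mg/dL, proteinuria mg/24 h.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .renal import CkdEpiParams, CKDEPI_2009, egfr_ckdepi

__all__ = [
    "LightChainType",
    "Sex",
    "HistologyLabel",
    "Patient",
    "Cohort",
    "CohortSchemaError",
    "PatientValidationError",
    "normalize_histology",
    "read_cohort",
    "write_cohort",
    "cohort_summary_counts",
]

logger = logging.getLogger(__name__)


class CohortSchemaError(ValueError):
    """File-level problem: missing column, duplicate id, empty cohort."""


class PatientValidationError(ValueError):
    """Row-level invariant violation; carries the offending patient id."""

    def __init__(self, patient_id: str, message: str):
        self.patient_id = patient_id
        super().__init__(f"patient {patient_id!r}: {message}")


class LightChainType(str, Enum):
    KAPPA = "kappa"
    LAMBDA = "lambda"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class HistologyLabel(str, Enum):
    CAST_NEPHROPATHY = "cast_nephropathy"
    LIGHT_CHAIN_PROXIMAL_TUBULOPATHY = "light_chain_proximal_tubulopathy"
    AL_AMYLOIDOSIS = "al_amyloidosis"
    MIDD = "midd"
    NEPHROANGIOSCLEROSIS = "nephroangiosclerosis"
    THROMBOTIC_MICROANGIOPATHY = "thrombotic_microangiopathy"
    OTHER = "other"


# Free-text biopsy diagnoses are normalized case-insensitively; anything not
# matched maps to OTHER with the original subtype retained on the patient.
_HISTOLOGY_SYNONYMS = {
    "cast nephropathy": HistologyLabel.CAST_NEPHROPATHY,
    "cn": HistologyLabel.CAST_NEPHROPATHY,
    "myeloma cast nephropathy": HistologyLabel.CAST_NEPHROPATHY,
    "light chain proximal tubulopathy": HistologyLabel.LIGHT_CHAIN_PROXIMAL_TUBULOPATHY,
    "lcpt": HistologyLabel.LIGHT_CHAIN_PROXIMAL_TUBULOPATHY,
    "al amyloidosis": HistologyLabel.AL_AMYLOIDOSIS,
    "ala": HistologyLabel.AL_AMYLOIDOSIS,
    "amyloidosis": HistologyLabel.AL_AMYLOIDOSIS,
    "midd": HistologyLabel.MIDD,
    "lcdd": HistologyLabel.MIDD,
    "light chain deposition disease": HistologyLabel.MIDD,
    "monoclonal immunoglobulin deposition disease": HistologyLabel.MIDD,
    "nephroangiosclerosis": HistologyLabel.NEPHROANGIOSCLEROSIS,
    "thrombotic microangiopathy": HistologyLabel.THROMBOTIC_MICROANGIOPATHY,
    "tma": HistologyLabel.THROMBOTIC_MICROANGIOPATHY,
}


def normalize_histology(text: str) -> tuple[HistologyLabel, str | None]:
    """Map a free-text biopsy diagnosis to a closed label.

    Returns ``(label, subtype)`` where ``subtype`` keeps the original text for
    diagnoses folded into OTHER.
    """
    key = re.sub(r"[\s_\-]+", " ", str(text).strip().lower())
    key_enum = key.replace(" ", "_")
    for label in HistologyLabel:
        if key_enum == label.value:
            return label, None
    if key in _HISTOLOGY_SYNONYMS:
        return _HISTOLOGY_SYNONYMS[key], None
    return HistologyLabel.OTHER, str(text).strip() or None


@dataclass
class Patient:
    """One subject: demographics, labs, involved LC type, biopsy diagnosis."""

    id: str
    age: int  # years, adult
    sex: Sex
    lc_type: LightChainType
    egfr: float  # mL/min/1.73 m²
    involved_flc_serum: float  # mg/dL
    involved_lc_urine: float  # mg/dL
    proteinuria: float | None  # mg/24 h; may be missing
    histology: HistologyLabel
    serum_creatinine: float | None = None  # mg/dL
    histology_subtype: str | None = None  # free text kept for OTHER

    @property
    def is_cn(self) -> bool:
        """Biopsy-proven cast nephropathy — the ground truth for the rule."""
        return self.histology is HistologyLabel.CAST_NEPHROPATHY

    def validate(
        self,
        *,
        egfr_tolerance: float = 0.05,
        ckdepi_params: CkdEpiParams = CKDEPI_2009,
        check_consistency: bool = True,
    ) -> None:
        """Raise :class:`PatientValidationError` on any invariant violation.

        When both creatinine and eGFR are present they must agree under the
        CKD-EPI forward map within ``egfr_tolerance`` (relative).
        """
        def fail(msg: str) -> None:
            raise PatientValidationError(self.id, msg)

        if not self.id:
            raise PatientValidationError("<missing>", "empty id")
        if not (18 <= self.age <= 110):
            fail(f"age {self.age} outside adult range [18, 110]")
        if not (isinstance(self.egfr, (int, float)) and math.isfinite(self.egfr) and self.egfr > 0):
            fail(f"egfr must be a positive number, got {self.egfr!r}")
        if self.serum_creatinine is not None and not self.serum_creatinine > 0:
            fail(f"serum_creatinine must be > 0, got {self.serum_creatinine!r}")
        for name in ("involved_flc_serum", "involved_lc_urine"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                fail(f"{name} must be >= 0, got {value!r}")
        if self.proteinuria is not None and not (
            math.isfinite(self.proteinuria) and self.proteinuria >= 0
        ):
            fail(f"proteinuria must be >= 0, got {self.proteinuria!r}")
        if check_consistency and self.serum_creatinine is not None:
            implied = egfr_ckdepi(self.serum_creatinine, self.age, self.sex.value, ckdepi_params)
            if abs(implied - self.egfr) / self.egfr > egfr_tolerance:
                fail(
                    f"egfr {self.egfr:.4g} inconsistent with creatinine "
                    f"{self.serum_creatinine:.4g} (CKD-EPI {ckdepi_params.version} "
                    f"implies {implied:.4g}) beyond {egfr_tolerance:.0%} tolerance"
                )


@dataclass
class Cohort:
    """Ordered patient collection with provenance (observed or synthetic)."""

    patients: list[Patient]
    provenance: str = "observed"  # observed | synthetic
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("observed", "synthetic"):
            raise ValueError("provenance must be 'observed' or 'synthetic'")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[Patient]:
        return iter(self.patients)

    def validate(self, **patient_kwargs) -> None:
        if not self.patients:
            raise CohortSchemaError("cohort is empty")
        ids = [p.id for p in self.patients]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise CohortSchemaError(f"duplicate patient ids: {sorted(dupes)}")
        for p in self.patients:
            p.validate(**patient_kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.id for p in self],
                "age": [p.age for p in self],
                "sex": [p.sex.value for p in self],
                "lc_type": [p.lc_type.value for p in self],
                "serum_creatinine": [p.serum_creatinine for p in self],
                "egfr": [p.egfr for p in self],
                "involved_flc_serum": [p.involved_flc_serum for p in self],
                "involved_lc_urine": [p.involved_lc_urine for p in self],
                "proteinuria": [p.proteinuria for p in self],
                "histology": [
                    p.histology_subtype if (p.histology is HistologyLabel.OTHER and p.histology_subtype)
                    else p.histology.value
                    for p in self
                ],
            }
        )


REQUIRED_COLUMNS = (
    "id", "age", "sex", "lc_type", "egfr",
    "involved_flc_serum", "involved_lc_urine", "proteinuria", "histology",
)
# serum_creatinine optional when egfr is given; egfr optional when creatinine is.


def _parse_row(row: pd.Series, ckdepi_params: CkdEpiParams) -> Patient:
    def number(name: str, *, optional: bool = False) -> float | None:
        raw = row.get(name)
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
            if optional:
                return None
            raise PatientValidationError(str(row["id"]), f"missing value for {name!r}")
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise PatientValidationError(
                str(row["id"]), f"non-numeric value {raw!r} for {name!r}"
            ) from None

    pid = str(row["id"]).strip()
    sex_raw = str(row["sex"]).strip().lower()
    sex = {"f": Sex.FEMALE, "female": Sex.FEMALE, "m": Sex.MALE, "male": Sex.MALE}.get(sex_raw)
    if sex is None:
        raise PatientValidationError(pid, f"unrecognized sex {row['sex']!r}")
    lc_raw = str(row["lc_type"]).strip().lower()
    try:
        lc_type = LightChainType(lc_raw)
    except ValueError:
        raise PatientValidationError(pid, f"unrecognized lc_type {row['lc_type']!r}") from None
    age_f = number("age")
    if age_f != int(age_f):
        raise PatientValidationError(pid, f"age must be an integer number of years, got {age_f}")
    creatinine = number("serum_creatinine", optional=True)
    egfr = number("egfr", optional=True)
    if egfr is None:
        if creatinine is None:
            raise PatientValidationError(pid, "either egfr or serum_creatinine is required")
        # completion rule: fill eGFR from creatinine via the CKD-EPI forward map
        egfr = egfr_ckdepi(creatinine, age_f, sex.value, ckdepi_params)
    histology, subtype = normalize_histology(row["histology"])
    return Patient(
        id=pid,
        age=int(age_f),
        sex=sex,
        lc_type=lc_type,
        egfr=egfr,
        involved_flc_serum=number("involved_flc_serum"),
        involved_lc_urine=number("involved_lc_urine"),
        proteinuria=number("proteinuria", optional=True),
        histology=histology,
        serum_creatinine=creatinine,
        histology_subtype=subtype,
    )


def _read_provenance(path: Path) -> tuple[str, int | None]:
    provenance, seed = "observed", None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = re.match(r"#\s*(provenance|seed)\s*[:=]\s*(\S+)", line)
            if m:
                if m.group(1) == "provenance":
                    provenance = m.group(2)
                else:
                    seed = int(m.group(2))
    return provenance, seed


def read_cohort(
    path: str | Path,
    strict: bool = True,
    *,
    ckdepi_params: CkdEpiParams = CKDEPI_2009,
    egfr_tolerance: float = 0.05,
) -> Cohort:
    """Read a delimited-text cohort file (comma default, tab accepted).

    In strict mode any invariant violation raises; in lenient mode offending
    rows are dropped with a logged reason, and a supplied eGFR inconsistent
    with creatinine is kept (eGFR is the analysis-bearing quantity) and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = next((line for line in fh if not line.startswith("#")), "")
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(
        path, comment="#", sep=sep, dtype={"id": str}, float_precision="round_trip"
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns and c != "egfr"]
    if "egfr" not in df.columns and "serum_creatinine" not in df.columns:
        missing.append("egfr")
    if missing:
        raise CohortSchemaError(f"missing required column(s): {missing}")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            df[col] = float("nan")

    patients: list[Patient] = []
    for _, row in df.iterrows():
        try:
            patient = _parse_row(row, ckdepi_params)
            patient.validate(
                egfr_tolerance=egfr_tolerance,
                ckdepi_params=ckdepi_params,
                check_consistency=strict,
            )
            if not strict and patient.serum_creatinine is not None:
                implied = egfr_ckdepi(
                    patient.serum_creatinine, patient.age, patient.sex.value, ckdepi_params
                )
                if abs(implied - patient.egfr) / patient.egfr > egfr_tolerance:
                    logger.warning(
                        "patient %s: keeping supplied egfr %.4g despite CKD-EPI-implied %.4g",
                        patient.id, patient.egfr, implied,
                    )
        except PatientValidationError as err:
            if strict:
                raise
            logger.warning("dropping row: %s", err)
            continue
        patients.append(patient)

    provenance, seed = _read_provenance(path)
    cohort = Cohort(patients, provenance=provenance, seed=seed)
    ids = [p.id for p in patients]
    dupes = sorted(i for i, c in Counter(ids).items() if c > 1)
    if dupes:
        raise CohortSchemaError(f"duplicate patient ids: {dupes}")
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort re-readable by :func:`read_cohort` at full precision."""
    if not cohort.patients:
        raise CohortSchemaError("refusing to write an empty cohort")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# provenance: {cohort.provenance}\n")
        if cohort.seed is not None:
            fh.write(f"# seed: {cohort.seed}\n")
        # repr round-trips floats exactly through read_cohort
        cohort.to_frame().to_csv(fh, index=False, float_format=lambda x: repr(float(x)))
    return path


def cohort_summary_counts(cohort: Cohort) -> dict[str, dict[str, int]]:
    """Counts by histology label, CN vs other kidney disease, LC type, and sex."""
    if not cohort.patients:
        raise CohortSchemaError("cohort is empty")
    return {
        "histology": dict(Counter(p.histology.value for p in cohort)),
        "cn_status": dict(Counter("cn" if p.is_cn else "okd" for p in cohort)),
        "lc_type": dict(Counter(p.lc_type.value for p in cohort)),
        "sex": dict(Counter(p.sex.value for p in cohort)),
    }
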