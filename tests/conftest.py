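import pytest

from castquotient import default_cohort_spec, generate_cohort
from castquotient.cohort import HistologyLabel, LightChainType, Patient, Sex


def make_patient(pid="p1", **overrides):
    """A valid single patient with overridable fields, for unit tests."""
    fields = dict(
        id=pid,
        age=70,
        sex=Sex.MALE,
        lc_type=LightChainType.KAPPA,
        egfr=25.0,
        involved_flc_serum=100.0,
        involved_lc_urine=40.0,
        proteinuria=3000.0,
        histology=HistologyLabel.CAST_NEPHROPATHY,
    )
    fields.update(overrides)
    return Patient(**fields)


@pytest.fixture(scope="session")
def study_cohort():
    """One 67-patient synthetic cohort at the default study calibration."""
    return generate_cohort(default_cohort_spec(), seed=12345)


@pytest.fixture(scope="session")
def large_cohort():
    """Scaled cohort (x50) for statistical checks that need stable estimates."""
    return generate_cohort(default_cohort_spec().scaled(50), seed=777)
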