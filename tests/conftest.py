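import numpy as np
import pytest

from liverscore.cohort import Cohort, PatientRecord
from liverscore.synthetic_data import default_configs, simulate_cohort


def make_record(pid="p1", **overrides) -> PatientRecord:
    """A complete, mid-severity admission record; override fields at will."""
    base = dict(
        patient_id=pid, age=50.0, sex="male", sodium=136.0, potassium=4.1,
        urea=8.0, lactate=1.9, creatinine=81.0, wcc=13.0, bilirubin=45.0,
        pt_ratio=1.5, albumin=22.0, platelets=140.0, pao2=12.4,
        pf_ratio=22.0, gcs=14, map=72.0, noradrenaline_dose=0.0,
        ascites="none", encephalopathy=0, alcoholic_aetiology=True,
        icu_outcome="survived",
    )
    base.update(overrides)
    return PatientRecord(**base)


def make_cohort(records, label="test") -> Cohort:
    return Cohort(label=label, records=list(records))


@pytest.fixture(scope="session")
def sim_configs():
    return default_configs()


@pytest.fixture(scope="session")
def glasgow_cohort(sim_configs):
    return simulate_cohort(sim_configs["glasgow"], seed=42)


@pytest.fixture(scope="session")
def london_cohort(sim_configs):
    return simulate_cohort(sim_configs["london"], seed=43)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
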