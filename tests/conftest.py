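import numpy as np
import pytest

from akitraj.phenotype import PatientTimeline
from akitraj.synthetic_cohort import generate_cohort, preset_published_classes


def make_timeline(pid="t1", *, age=60.0, sex="M", race="white",
                  icu_admit=0.0, creatinine=None, prior=None,
                  antibiotics=None, cultures=None, sofa=None,
                  death_time=None, hospital_discharge=500.0, **kw):
    """A minimal timeline that passes the sepsis/AKI inclusion rules
    unless the caller overrides the relevant streams."""
    return PatientTimeline(
        patient_id=pid, age=age, sex=sex, race=race,
        icu_admit=icu_admit,
        icu_discharge=icu_admit + 120.0,
        hospital_discharge=hospital_discharge,
        death_time=death_time,
        creatinine=creatinine if creatinine is not None
        else [(icu_admit + 1.0, 1.0), (icu_admit + 24.0, 1.6),
              (icu_admit + 48.0, 1.7), (icu_admit + 90.0, 1.5)],
        antibiotics=antibiotics if antibiotics is not None
        else [icu_admit + 1.0],
        cultures=cultures if cultures is not None else [icu_admit + 4.0],
        sofa=sofa if sofa is not None else [(icu_admit + 2.0, 5)],
        prior_creatinine=prior if prior is not None
        else [(-1000.0, 0.98), (-600.0, 1.0), (-200.0, 1.02)],
        **kw)


@pytest.fixture(scope="session")
def preset_cohort_800():
    """One seeded draw of the eight-class preset, shared across tests."""
    return generate_cohort(preset_published_classes(n_patients=800, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
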