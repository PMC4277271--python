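import numpy as np
import pytest
from hypothesis import settings

from cardiorenal import Cohort, CreatinineMeasurement, PatientRecord

settings.register_profile("ci", derandomize=True, max_examples=200, deadline=None)
settings.load_profile("ci")


def make_patient(
    pid="P1",
    scr=((0.0, 90.0),),
    sex="male",
    age=60.0,
    outcome_hours=240.0,
    died=False,
    **kwargs,
):
    """Build a patient from (time_hours, scr_umol) pairs with sane defaults."""
    return PatientRecord(
        patient_id=pid,
        age_years=age,
        sex=sex,
        measurements=[CreatinineMeasurement(t, v) for t, v in scr],
        died_in_hospital=died,
        outcome_time_hours=outcome_hours,
        **kwargs,
    )


@pytest.fixture
def three_patient_cohort():
    """One concordant AKI, one KDIGO-only (K+R-), one without AKI."""
    concordant = make_patient(
        "A", scr=[(0.0, 90.0), (24.0, 150.0), (48.0, 190.0)]
    )  # 48h rise 100 >= 26.5 and peak 2.1x baseline
    kdigo_only = make_patient(
        "B", scr=[(0.0, 100.0), (36.0, 128.0), (72.0, 120.0)]
    )  # abs rise 28 in 36h but peak 1.28x baseline: AKIN+/KDIGO+, RIFLE-
    clean = make_patient("C", scr=[(0.0, 80.0), (24.0, 82.0), (48.0, 79.0)])
    return Cohort(patients=[concordant, kdigo_only, clean], provenance="fixture")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
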