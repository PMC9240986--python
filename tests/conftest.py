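from datetime import datetime

import pytest

from khds.cohort import Gait, PatientRecord, Sex


def make_record(**overrides) -> PatientRecord:
    """A well patient presentation; override fields to perturb it."""
    base = dict(
        patient_id="P000001",
        age=40,
        sex=Sex.FEMALE,
        arrival=datetime(2021, 5, 1, 10, 30),
        pregnant=False,
        alert=True,
        attentive=True,
        calm=True,
        coherent=True,
        months_backwards_pass=True,
        gait=Gait.STABLE_INDEPENDENT,
        spo2=97.0,
        resp_rate=16.0,
        presentations=(),
        admitted=False,
        died_within_24h=False,
        died_in_hospital=False,
        day_of_death=None,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def well_record() -> PatientRecord:
    return make_record()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-calibration synthetic cohort, shared across tests."""
    from khds.synthetic import default_config, generate_cohort

    return generate_cohort(default_config(), seed=20210501)
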