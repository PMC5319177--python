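import datetime as dt

import pytest

from artcov.config import StudyConfig
from artcov.io import PatientRecord, PrescriptionRecord


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


def make_patient(
    patient_id="P00001",
    enrollment_date=dt.date(2010, 5, 1),
    birth_date=dt.date(1975, 3, 15),
    gender="female",
    art_start_date=dt.date(2010, 6, 1),
    transfer_out_date=None,
    phone_status="available",
    phone_capture_date=dt.date(2013, 6, 15),
    opt_out_date=None,
) -> PatientRecord:
    if phone_status != "available":
        phone_capture_date = None
    return PatientRecord(
        patient_id=patient_id,
        enrollment_date=enrollment_date,
        birth_date=birth_date,
        gender=gender,
        art_start_date=art_start_date,
        transfer_out_date=transfer_out_date,
        phone_status=phone_status,
        phone_capture_date=phone_capture_date,
        opt_out_date=opt_out_date,
    )


def make_rx(
    issue_date,
    duration_days,
    patient_id="P00001",
    agents=frozenset({"TDF", "FTC", "EFV"}),
    line="first",
    fdc=False,
) -> PrescriptionRecord:
    if isinstance(issue_date, str):
        issue_date = dt.date.fromisoformat(issue_date)
    return PrescriptionRecord(
        patient_id=patient_id,
        issue_date=issue_date,
        duration_days=duration_days,
        agents=frozenset(agents),
        line=line,
        fdc=fdc,
    )


@pytest.fixture(scope="session")
def behavioral_members(config):
    """A moderate behavioral cohort shared by the model-layer tests."""
    from artcov.cohort import build_cohort, impute_missing
    from artcov.simulate import SimConfig, generate

    out = generate(SimConfig(n_patients=200, seed=11), config)
    members, tally = build_cohort(out.patients, out.prescriptions, config)
    impute_missing(members)
    return members, tally, out
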