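import datetime as dt

import pytest

from registryqc.records import (
    ClinicalEvent,
    EventType,
    FieldValue,
    PatientRecord,
    VitalStatus,
)


def make_record(record_id="P001", **overrides) -> PatientRecord:
    """A complete, internally consistent record (no rule should fire on it,
    except R5's xrt_start check which is satisfied by the radiation course)."""
    dx = dt.date(2001, 3, 1)
    rec = PatientRecord(
        record_id=record_id,
        gender=FieldValue.present("F"),
        dob=FieldValue.present(dt.date(1950, 5, 20)),
        cancer_site=FieldValue.present("breast"),
        diagnosis_date=FieldValue.present(dx),
        tumor_grade=FieldValue.present("2"),
        t_stage=FieldValue.present("T1"),
        vital_status=VitalStatus.ALIVE,
        relapse_date=FieldValue.not_applicable(),
        remission_documented=True,
        events=[
            ClinicalEvent(EventType.SURGERY, dx + dt.timedelta(days=20),
                          {"procedure_code": "lumpectomy"}, "surgery"),
            ClinicalEvent(EventType.XRT_START, dx + dt.timedelta(days=50),
                          {"planned_duration_days": 42}, "xrt"),
            ClinicalEvent(EventType.XRT_END, dx + dt.timedelta(days=92), (), "xrt"),
            ClinicalEvent(EventType.FOLLOW_UP, dx + dt.timedelta(days=300), (), "fu"),
        ],
    )
    for k, v in overrides.items():
        setattr(rec, k, v)
    return rec


@pytest.fixture
def complete_record():
    return make_record()


@pytest.fixture
def escalated_surgery_record():
    """Lumpectomy, radiation, then — after a quiet year and a half — a
    modified radical mastectomy with no relapse documented in between."""
    rec = make_record("P002")
    rec.relapse_date = FieldValue.unknown()
    mast_date = dt.date(2001, 3, 1) + dt.timedelta(days=20 + 540)
    rec.events = rec.events[:3] + [
        ClinicalEvent(EventType.SURGERY, mast_date,
                      {"procedure_code": "modified_radical_mastectomy"}, "surgery"),
    ]
    return rec
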