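import datetime as dt

import pytest

from copdemr import (
    BillingEvent,
    CPPEntry,
    CPPSection,
    PatientChart,
    Prescription,
    PrescriptionStatus,
    ReferenceLabel,
    SmokingRecord,
    SmokingStatus,
    default_lexicon,
    default_params,
    generate_cohort,
    scaled_params,
)

BIRTH = dt.date(1950, 6, 15)


def make_chart(
    patient_id="P1",
    birth_date=BIRTH,
    cpp=(),
    billing=(),
    rx=(),
    smoking=(),
    label=None,
    **kwargs,
):
    """Compact chart builder for tests.

    cpp: iterable of text or (text, date); billing: (code, date);
    rx: (text, date[, status]); smoking: (status, date).
    """

    def _cpp(item):
        if isinstance(item, str):
            return CPPEntry(section=CPPSection.PROBLEM_LIST, text=item)
        text, date = item
        return CPPEntry(section=CPPSection.PROBLEM_LIST, text=text, date=date)

    def _rx(item):
        status = PrescriptionStatus(item[2]) if len(item) > 2 else PrescriptionStatus.ACTIVE
        return Prescription(raw_text=item[0], date=item[1], status=status)

    return PatientChart(
        patient_id=patient_id,
        birth_date=birth_date,
        cpp_entries=[_cpp(i) for i in cpp],
        billing_events=[BillingEvent(code=c, date=d) for c, d in billing],
        prescriptions=[_rx(i) for i in rx],
        smoking_records=[SmokingRecord(status=SmokingStatus(s), date=d) for s, d in smoking],
        reference_label=ReferenceLabel(label) if label else None,
        **kwargs,
    )


def day(offset: int, base=dt.date(2005, 1, 1)) -> dt.date:
    return base + dt.timedelta(days=offset)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 800-patient cohort for pipeline-level tests."""
    return generate_cohort(scaled_params(default_params(), n=800, seed=7))


@pytest.fixture(scope="session")
def full_cohort():
    """A study-sized (n=5889) default-parameter cohort, fixed seed."""
    return generate_cohort(default_params(seed=42))
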