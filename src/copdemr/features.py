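"""Chart-level atomic criteria.

Each function answers one yes/no question about a single chart: does the
CPP document COPD, does the billing history meet a count-in-window
threshold, is a COPD-specific drug class on the medication list, is the
most recent smoking record positive. Phenotyping algorithms are boolean
combinations of these (see :mod:`copdemr.algorithms`).
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable, Literal, Union

from .charts import PatientChart, PrescriptionStatus, SmokingStatus
from .lexicon import COPD_DRUG_CLASSES, DrugClass, Lexicon, classify_drug, match_copd_term

#: Ontario physician billing stems for COPD: 491 chronic bronchitis,
#: 492 emphysema, 496 other COPD.
COPD_BILLING_CODES = frozenset({"491", "492", "496"})

Window = Union[int, Literal["ever"]]


def cpp_indicates_copd(chart: PatientChart, lexicon: Lexicon) -> bool:
    """True iff some CPP entry matches a diagnosis term without being
    suppressed by an uncertainty marker."""
    return any(match_copd_term(e.text, lexicon).positive for e in chart.cpp_entries)


def billing_criterion_met(
    chart: PatientChart,
    codes: Iterable[str],
    min_count: int,
    window_days: Window = "ever",
    dedup_same_day: bool = False,
    calendar_year: bool = False,
) -> bool:
    """Count-in-window billing criterion.

    With ``window_days="ever"`` the count runs over the whole chart.  With a
    finite window, the criterion holds iff some span of ``window_days``
    consecutive days (inclusive of both endpoints) contains at least
    ``min_count`` qualifying events; windows are anchored at each qualifying
    event date, which suffices because an optimal window can always be slid
    right until its left edge hits an event.

    ``dedup_same_day`` counts multiple same-day claims once;
    ``calendar_year`` replaces the sliding window with calendar-year
    grouping (sensitivity-analysis mode; ``window_days`` is then ignored).
    """
    codeset = {c.strip().upper() for c in codes}
    if not codeset:
        raise ValueError("codes must be non-empty")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    dates = sorted(
        ev.date for ev in chart.billing_events if ev.normalized_code in codeset
    )
    if dedup_same_day:
        dates = sorted(set(dates))
    if not dates:
        return False
    if calendar_year:
        counts: dict[int, int] = {}
        for d in dates:
            counts[d.year] = counts.get(d.year, 0) + 1
        return max(counts.values()) >= min_count
    if window_days == "ever":
        return len(dates) >= min_count
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    span = _dt.timedelta(days=window_days - 1)
    for i, anchor in enumerate(dates):
        count = sum(1 for d in dates[i:] if d <= anchor + span)
        if count >= min_count:
            return True
    return False


def drug_criterion_met(
    chart: PatientChart,
    classes: Iterable[DrugClass],
    scope: Literal["ever", "active"],
    lexicon: Lexicon,
) -> bool:
    """True iff some prescription classifies into ``classes`` and satisfies
    the scope ("ever": any date; "active": currently active status only)."""
    wanted = set(classes)
    if not wanted <= COPD_DRUG_CLASSES:
        raise ValueError(f"classes must be COPD-specific, got {wanted}")
    for rx in chart.prescriptions:
        if classify_drug(rx.raw_text, lexicon) in wanted:
            if scope == "ever" or rx.status is PrescriptionStatus.ACTIVE:
                return True
    return False


_POSITIVE_SMOKING = frozenset({SmokingStatus.CURRENT, SmokingStatus.EX})


def smoking_status_is(
    chart: PatientChart, statuses: Iterable[SmokingStatus]
) -> bool:
    """True iff the most-recent-dated smoking record has a status in
    ``statuses``. Ties on date resolve to the later record in chart order."""
    if not chart.smoking_records:
        return False
    _, latest = max(
        enumerate(chart.smoking_records), key=lambda pair: (pair[1].date, pair[0])
    )
    return latest.status in set(statuses)


def smoking_positive(chart: PatientChart) -> bool:
    """Positive smoking history: most recent record is current or ex-smoker."""
    return smoking_status_is(chart, _POSITIVE_SMOKING)
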