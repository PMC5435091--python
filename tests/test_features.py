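import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copdemr import (
    DrugClass,
    billing_criterion_met,
    cpp_indicates_copd,
    drug_criterion_met,
    smoking_positive,
)

from .conftest import day, make_chart

COPD_CODES = {"491", "492", "496"}


def brute_force_window(offsets, min_count, window_days):
    """Independent oracle: exhaustively count events in every candidate
    window [d, d+window_days-1] over the whole covered day range."""
    days = np.sort(np.asarray(offsets))
    if days.size == 0:
        return False
    best = 0
    for anchor in range(int(days.min()) - window_days, int(days.max()) + 1):
        count = int(
            np.searchsorted(days, anchor + window_days - 1, side="right")
            - np.searchsorted(days, anchor, side="left")
        )
        best = max(best, count)
    return best >= min_count


class TestBillingCriterion:
    def test_three_codes_inside_one_year(self):
        chart = make_chart(
            billing=[("496", day(0)), ("491", day(100)), ("492", day(200))]
        )
        assert billing_criterion_met(chart, COPD_CODES, 3, 365)

    def test_three_codes_spread_beyond_a_year(self):
        chart = make_chart(
            billing=[("496", day(0)), ("496", day(200)), ("496", day(400))]
        )
        assert not billing_criterion_met(chart, COPD_CODES, 3, 365)
        assert billing_criterion_met(chart, COPD_CODES, 2, 365)

    def test_single_code_ever(self):
        chart = make_chart(billing=[("491", dt.date(1999, 3, 1))])
        assert billing_criterion_met(chart, COPD_CODES, 1, "ever")

    def test_non_copd_codes_never_qualify(self):
        chart = make_chart(billing=[("786", day(0)), ("786", day(1))])
        assert not billing_criterion_met(chart, COPD_CODES, 1, "ever")

    def test_subcoded_claims_match_their_stem(self):
        chart = make_chart(billing=[("491.2", day(0))])
        assert billing_criterion_met(chart, COPD_CODES, 1, "ever")

    def test_window_endpoints_inclusive(self):
        chart = make_chart(billing=[("491", day(0)), ("491", day(364))])
        assert billing_criterion_met(chart, COPD_CODES, 2, 365)
        chart = make_chart(billing=[("491", day(0)), ("491", day(365))])
        assert not billing_criterion_met(chart, COPD_CODES, 2, 365)

    def test_same_day_claims_count_per_claim_unless_dedup(self):
        chart = make_chart(billing=[("491", day(0)), ("491", day(0))])
        assert billing_criterion_met(chart, COPD_CODES, 2, 365)
        assert not billing_criterion_met(chart, COPD_CODES, 2, 365, dedup_same_day=True)

    def test_calendar_year_mode(self):
        # Dec 2004 + Jan 2005 is one 365-day window but two calendar years
        chart = make_chart(
            billing=[("491", dt.date(2004, 12, 20)), ("491", dt.date(2005, 1, 10))]
        )
        assert billing_criterion_met(chart, COPD_CODES, 2, 365)
        assert not billing_criterion_met(chart, COPD_CODES, 2, 365, calendar_year=True)

    @given(
        offsets=st.lists(st.integers(0, 1000), min_size=0, max_size=12),
        min_count=st.integers(1, 5),
        window=st.integers(1, 500),
    )
    @settings(max_examples=300, deadline=None)
    def test_sliding_window_agrees_with_brute_force(self, offsets, min_count, window):
        chart = make_chart(billing=[("491", day(o)) for o in offsets])
        assert billing_criterion_met(chart, COPD_CODES, min_count, window) == \
            brute_force_window(offsets, min_count, window)

    @given(offsets=st.lists(st.integers(0, 800), min_size=1, max_size=10),
           min_count=st.integers(1, 4))
    @settings(max_examples=150, deadline=None)
    def test_wide_window_equals_ever(self, offsets, min_count):
        chart = make_chart(billing=[("491", day(o)) for o in offsets])
        span = max(offsets) - min(offsets) + 1
        assert billing_criterion_met(chart, COPD_CODES, min_count, span) == \
            billing_criterion_met(chart, COPD_CODES, min_count, "ever")

    @given(offsets=st.lists(st.integers(0, 800), max_size=8),
           extra=st.integers(0, 800), min_count=st.integers(1, 4),
           window=st.integers(1, 400))
    @settings(max_examples=150, deadline=None)
    def test_monotone_under_added_event(self, offsets, extra, min_count, window):
        before = make_chart(billing=[("491", day(o)) for o in offsets])
        after = make_chart(billing=[("491", day(o)) for o in offsets + [extra]])
        if billing_criterion_met(before, COPD_CODES, min_count, window):
            assert billing_criterion_met(after, COPD_CODES, min_count, window)


class TestCppCriterion:
    def test_plain_mention(self, lexicon):
        assert cpp_indicates_copd(make_chart(cpp=["COPD — stable"]), lexicon)

    def test_sole_excluded_entry_is_negative(self, lexicon):
        assert not cpp_indicates_copd(make_chart(cpp=["?COPD"]), lexicon)

    def test_no_entries(self, lexicon):
        assert not cpp_indicates_copd(make_chart(), lexicon)

    def test_any_positive_entry_suffices(self, lexicon):
        chart = make_chart(cpp=["?COPD", "hypertension", "COPD"])
        assert cpp_indicates_copd(chart, lexicon)


class TestDrugCriterion:
    def test_old_prescription_counts_with_scope_ever(self, lexicon):
        chart = make_chart(rx=[("Spiriva 18 mcg", dt.date(2001, 1, 1), "inactive")])
        assert drug_criterion_met(chart, {DrugClass.TIOTROPIUM}, "ever", lexicon)
        assert not drug_criterion_met(chart, {DrugClass.TIOTROPIUM}, "active", lexicon)

    def test_class_mismatch(self, lexicon):
        chart = make_chart(rx=[("Atrovent", day(0))])
        assert not drug_criterion_met(chart, {DrugClass.TIOTROPIUM}, "ever", lexicon)

    def test_empty_medication_list(self, lexicon):
        assert not drug_criterion_met(make_chart(), {DrugClass.TIOTROPIUM}, "ever", lexicon)

    def test_non_specific_classes_rejected(self, lexicon):
        with pytest.raises(ValueError):
            drug_criterion_met(make_chart(), {DrugClass.OTHER}, "ever", lexicon)


class TestSmokingStatus:
    def test_most_recent_record_governs(self):
        assert smoking_positive(
            make_chart(smoking=[("non", day(0)), ("current", day(700))])
        )
        assert not smoking_positive(
            make_chart(smoking=[("current", day(0)), ("non", day(700))])
        )

    def test_ex_smoker_is_positive(self):
        assert smoking_positive(make_chart(smoking=[("ex", day(0))]))

    @pytest.mark.parametrize("status", ["non", "unspecified"])
    def test_non_positive_statuses(self, status):
        assert not smoking_positive(make_chart(smoking=[(status, day(0))]))

    def test_no_records(self):
        assert not smoking_positive(make_chart())

    def test_date_tie_resolves_to_later_chart_order(self):
        assert smoking_positive(make_chart(smoking=[("non", day(0)), ("ex", day(0))]))
        assert not smoking_positive(make_chart(smoking=[("ex", day(0)), ("non", day(0))]))

    def test_order_irrelevant_when_dates_differ(self):
        chart = make_chart(smoking=[("current", day(500)), ("non", day(0))])
        assert smoking_positive(chart)
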