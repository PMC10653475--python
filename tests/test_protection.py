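"""Last-to-expire algebra and every duration metric."""

from __future__ import annotations

import random
from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obmex.classify import DeviceStatus, ExclusivityTiming, FilingTiming, ListingTiming
from obmex.cohort import group_lines
from obmex.dates import years_between
from obmex.protection import (
    AT_APPROVAL_SCOPE,
    FULL_SCOPE,
    LastItemKind,
    PatentScope,
    ProtectionScope,
    device_added_protection,
    last_to_expire,
    line_protection,
    no_mention_added_protection,
    post_approval_extension,
    product_protection,
)

from conftest import make_exclusivity, make_patent, make_product

dates_strategy = st.dates(min_value=date(1980, 1, 1), max_value=date(2060, 12, 31))


def test_last_to_expire_empty_is_none():
    assert last_to_expire([]) is None


def test_last_to_expire_max_of_three():
    assert last_to_expire(
        [date(2024, 6, 1), date(2027, 3, 10), date(2015, 1, 15)]
    ) == date(2027, 3, 10)


@settings(max_examples=100, derandomize=True)
@given(st.lists(dates_strategy, min_size=1, max_size=50))
def test_last_to_expire_equals_bruteforce_scan(ds):
    best = ds[0]
    for d in ds[1:]:  # brute-force linear scan
        if d > best:
            best = d
    assert last_to_expire(ds) == best


def test_product_protection_single_patent_pair():
    p = make_product(approval=date(2010, 1, 15))
    pats = [
        make_patent(p, date(2024, 6, 1), "US1"),
        make_patent(p, date(2027, 3, 10), "US2"),
    ]
    pp = product_protection(p, pats, [], FULL_SCOPE)
    assert pp.last_expiry == date(2027, 3, 10)
    # oracle: direct calendar-day subtraction
    assert pp.duration_years == pytest.approx((date(2027, 3, 10) - date(2010, 1, 15)).days / 365.25)
    assert pp.duration_years == pytest.approx(17.147, abs=5e-4)
    assert pp.last_item_kind is LastItemKind.PATENT_NON_DEVICE


def test_product_protection_year_algebra_exact():
    # items k*365.25 days out give exactly k years for even k
    p = make_product(approval=date(2010, 1, 15))
    e = make_exclusivity(p, p.approval_date + timedelta(days=round(4 * 365.25)))
    pp = product_protection(p, [], [e], FULL_SCOPE)
    assert pp.duration_years == 4.0
    assert pp.last_item_kind is LastItemKind.EXCLUSIVITY


def test_product_protection_none_when_no_items():
    p = make_product()
    pp = product_protection(p, [], [], FULL_SCOPE)
    assert pp.last_expiry is None and pp.duration_years is None
    assert pp.last_item_kind is LastItemKind.NONE
    assert pp.excluded_from_medians


def test_product_protection_negative_duration_retained(caplog):
    import logging

    p = make_product(approval=date(2010, 1, 15))
    pat = make_patent(p, date(2005, 1, 1))
    with caplog.at_level(logging.WARNING):
        pp = product_protection(p, [pat], [], FULL_SCOPE)
    assert pp.duration_years < 0
    assert any("negative" in rec.message for rec in caplog.records)


@settings(max_examples=100, derandomize=True)
@given(
    st.lists(dates_strategy, min_size=0, max_size=10),
    dates_strategy,
)
def test_adding_protection_never_decreases_duration(expiries, extra):
    p = make_product(approval=date(2000, 1, 1))
    pats = [make_patent(p, d, f"US{i}") for i, d in enumerate(expiries)]
    before = product_protection(p, pats, [], FULL_SCOPE)
    after = product_protection(p, pats + [make_patent(p, extra, "USX")], [], FULL_SCOPE)
    if before.duration_years is not None:
        assert after.duration_years >= before.duration_years


def test_scope_nesting_at_approval_le_overall(synthetic_run):
    for product in synthetic_run.cohort.originator_products:
        full = product_protection(
            product, synthetic_run.patents, synthetic_run.exclusivities, FULL_SCOPE
        )
        at = product_protection(
            product, synthetic_run.patents, synthetic_run.exclusivities, AT_APPROVAL_SCOPE
        )
        if at.duration_years is not None:
            assert full.duration_years is not None
            assert at.duration_years <= full.duration_years + 1e-12


def test_post_approval_extension_cases():
    p = make_product(approval=date(2010, 1, 15))
    at_pat = make_patent(p, date(2020, 1, 1), "US1")
    # no post-approval listings at all → None
    assert post_approval_extension(p, [at_pat], []) is None
    # post-approval-listed patent extending the frontier by six years
    post_pat = make_patent(
        p,
        date(2026, 1, 1),
        "US2",
        listing=ListingTiming.LISTED_POST_APPROVAL,
        filing=FilingTiming.POST_APPROVAL_FILED,
    )
    ext = post_approval_extension(p, [at_pat, post_pat], [])
    assert ext == pytest.approx((date(2026, 1, 1) - date(2020, 1, 1)).days / 365.25)
    assert ext == pytest.approx(6.0, abs=0.01)
    # post-approval patent expiring before the at-approval frontier → no gain
    early_post = make_patent(
        p, date(2015, 1, 1), "US3", listing=ListingTiming.LISTED_POST_APPROVAL
    )
    assert post_approval_extension(p, [at_pat, early_post], []) is None


def test_line_protection_single_product_equals_product_duration():
    p = make_product(approval=date(2005, 6, 1))
    pat = make_patent(p, date(2021, 9, 30))
    (line,) = group_lines([p], is_originator=True)
    span = line_protection(line, [pat], [], FULL_SCOPE)
    pp = product_protection(p, [pat], [], FULL_SCOPE)
    assert span.duration_years == pp.duration_years


def test_line_protection_two_products_span():
    a = make_product(appl_no="N1", product_no="001", approval=date(2000, 4, 20))
    b = make_product(appl_no="N1", product_no="002", approval=date(2007, 5, 1), is_device=True)
    pats = [make_patent(a, date(2017, 1, 1), "US1"), make_patent(b, date(2033, 3, 16), "US2")]
    (line,) = group_lines([a, b], is_originator=True)
    span = line_protection(line, pats, [], FULL_SCOPE)
    assert span.first_approval == date(2000, 4, 20)
    assert span.last_expiry == date(2033, 3, 16)
    assert span.duration_years == pytest.approx(
        (date(2033, 3, 16) - date(2000, 4, 20)).days / 365.25
    )
    assert span.duration_years == pytest.approx(32.9, abs=0.01)


def test_line_member_with_earlier_expiry_never_extends_span():
    a = make_product(appl_no="N1", product_no="001", approval=date(2000, 1, 1))
    b = make_product(appl_no="N1", product_no="002", approval=date(2010, 1, 1))
    pats = [make_patent(a, date(2025, 1, 1), "US1"), make_patent(b, date(2020, 1, 1), "US2")]
    (line,) = group_lines([a, b], is_originator=True)
    span = line_protection(line, pats, [], FULL_SCOPE)
    assert span.last_expiry == date(2025, 1, 1)


def test_line_duration_dominates_member_durations(synthetic_run):
    spans = {
        l.line_id: line_protection(l, synthetic_run.patents, synthetic_run.exclusivities)
        for l in synthetic_run.cohort.originator_lines
    }
    for line in synthetic_run.cohort.originator_lines:
        span = spans[line.line_id]
        for product in line.products:
            pp = product_protection(
                product, synthetic_run.patents, synthetic_run.exclusivities
            )
            if pp.duration_years is not None:
                assert span.duration_years >= pp.duration_years - 1e-12


def test_device_added_protection_cases():
    p = make_product(is_device=True)
    non_dev = make_patent(p, date(2021, 6, 30), "US1", DeviceStatus.NON_DEVICE)
    dev = make_patent(p, date(2026, 9, 15), "US2", DeviceStatus.DEVICE_NO_MENTION)
    added = device_added_protection(p, [non_dev, dev])
    assert added == pytest.approx((date(2026, 9, 15) - date(2021, 6, 30)).days / 365.25)
    assert added == pytest.approx(5.2, abs=0.02)
    # equal expiries → exactly zero
    dev_eq = make_patent(p, date(2021, 6, 30), "US3", DeviceStatus.DEVICE_MENTION)
    assert device_added_protection(p, [non_dev, dev_eq]) == 0.0
    # one class absent → undefined
    assert device_added_protection(p, [non_dev]) is None
    assert device_added_protection(p, [dev]) is None


def test_no_mention_added_protection_cases():
    p = make_product(is_device=True)
    nm = make_patent(p, date(2030, 1, 1), "US1", DeviceStatus.DEVICE_NO_MENTION)
    mention = make_patent(p, date(2025, 9, 15), "US2", DeviceStatus.DEVICE_MENTION)
    added = no_mention_added_protection(p, [nm, mention])
    assert added == pytest.approx((date(2030, 1, 1) - date(2025, 9, 15)).days / 365.25)
    assert added == pytest.approx(4.3, abs=0.01)
    # complement empty → undefined
    assert no_mention_added_protection(p, [nm]) is None
    # no-mention expiring first → negative value retained
    early_nm = make_patent(p, date(2020, 1, 1), "US3", DeviceStatus.DEVICE_NO_MENTION)
    assert no_mention_added_protection(p, [early_nm, mention]) < 0


def test_scope_filters_select_expected_subsets():
    p = make_product(is_device=True, approval=date(2010, 1, 1))
    pats = [
        make_patent(p, date(2020, 1, 1), "US1", DeviceStatus.NON_DEVICE),
        make_patent(p, date(2025, 1, 1), "US2", DeviceStatus.DEVICE_MENTION),
        make_patent(p, date(2030, 1, 1), "US3", DeviceStatus.DEVICE_NO_MENTION),
    ]
    def dur(which):
        return product_protection(
            p, pats, [], ProtectionScope(which_patents=which, include_exclusivities=False)
        ).last_expiry

    assert dur(PatentScope.ALL) == date(2030, 1, 1)
    assert dur(PatentScope.NON_DEVICE_ONLY) == date(2020, 1, 1)
    assert dur(PatentScope.DEVICE_ONLY) == date(2030, 1, 1)
    assert dur(PatentScope.DEVICE_NO_MENTION_ONLY) == date(2030, 1, 1)
    assert dur(PatentScope.OTHER_THAN_NO_MENTION) == date(2025, 1, 1)
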