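"""Timing and device-status classification of patents and exclusivities."""

from __future__ import annotations

import random
from datetime import date

import pytest

from obmex.classify import (
    DeviceStatus,
    ExclusivityCategory,
    ExclusivityTiming,
    FilingTiming,
    ListingTiming,
    MissingAnnotationError,
    PriorityTiming,
    categorize_exclusivity,
    device_status,
    exclusivity_timing,
    link_and_classify,
    load_code_map,
    patent_timing,
    priority_timing,
)
from obmex.cohort import Cohort, group_lines
from obmex.io import PatentAnnotation, RawExclusivityRow, RawPatentRow

from conftest import make_product

APPROVAL = date(2000, 4, 20)


@pytest.mark.parametrize(
    "application, expected",
    [
        (date(1998, 5, 1), FilingTiming.PRE_APPROVAL_FILED),
        (date(2005, 1, 1), FilingTiming.POST_APPROVAL_FILED),
        (APPROVAL, FilingTiming.POST_APPROVAL_FILED),  # tie rule: equal → post
    ],
)
def test_filing_timing_strict_inequality(application, expected):
    filing, _ = patent_timing(application, APPROVAL, first_listing=application)
    assert filing is expected


@pytest.mark.parametrize(
    "listing, grace, expected",
    [
        (APPROVAL, 0, ListingTiming.LISTED_AT_APPROVAL),
        (date(2000, 4, 21), 0, ListingTiming.LISTED_POST_APPROVAL),
        (date(2000, 4, 21), 1, ListingTiming.LISTED_AT_APPROVAL),
        (date(1999, 1, 1), 0, ListingTiming.LISTED_AT_APPROVAL),
    ],
)
def test_listing_timing_with_grace(listing, grace, expected):
    _, lt = patent_timing(date(1998, 1, 1), APPROVAL, listing, grace_days=grace)
    assert lt is expected


def test_missing_listing_inherits_filing_axis(caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        _, lt = patent_timing(date(1998, 1, 1), APPROVAL, None)
    assert lt is ListingTiming.LISTED_AT_APPROVAL
    assert any("first-listing" in rec.message for rec in caplog.records)


@pytest.mark.parametrize(
    "priority, expected",
    [
        (date(1999, 1, 1), PriorityTiming.PRIORITY_BEFORE_APPROVAL),
        (date(2001, 1, 1), PriorityTiming.PRIORITY_AFTER_APPROVAL),
        (APPROVAL, PriorityTiming.PRIORITY_AFTER_APPROVAL),  # tie → after
    ],
)
def test_priority_timing(priority, expected):
    assert priority_timing(priority, APPROVAL) is expected


@pytest.mark.parametrize(
    "is_device, mentions, expected",
    [
        (False, True, DeviceStatus.NON_DEVICE),
        (False, False, DeviceStatus.NON_DEVICE),
        (True, True, DeviceStatus.DEVICE_MENTION),
        (True, False, DeviceStatus.DEVICE_NO_MENTION),
    ],
)
def test_device_status_from_annotation(is_device, mentions, expected):
    ann = PatentAnnotation("US1", date(2000, 1, 1), date(2000, 1, 1), is_device, mentions)
    assert device_status(ann) is expected


@pytest.mark.parametrize(
    "code, expected",
    [
        ("NCE", ExclusivityCategory.NEW_CHEMICAL_ENTITY),
        ("NP", ExclusivityCategory.NEW_PRODUCT),
        ("NC", ExclusivityCategory.NEW_COMBINATION),
        ("NPP", ExclusivityCategory.NEW_PATIENT_POPULATION),
        ("I-123", ExclusivityCategory.NEW_INDICATION_OR_DOSING),
        ("D-77", ExclusivityCategory.NEW_INDICATION_OR_DOSING),
        ("PED", ExclusivityCategory.PEDIATRIC),
        ("NR", ExclusivityCategory.NEW_ROUTE),
        ("ZZZ", ExclusivityCategory.OTHER),
    ],
)
def test_exclusivity_code_mapping(code, expected):
    assert categorize_exclusivity(code, load_code_map()) is expected


def test_exclusivity_timing_inferred_from_expiry():
    # NCE granted at approval expires ~5 years later
    at = exclusivity_timing(
        ExclusivityCategory.NEW_CHEMICAL_ENTITY, date(2005, 4, 19), APPROVAL
    )
    assert at is ExclusivityTiming.AT_APPROVAL
    post = exclusivity_timing(
        ExclusivityCategory.NEW_CHEMICAL_ENTITY, date(2008, 1, 1), APPROVAL
    )
    assert post is ExclusivityTiming.POST_APPROVAL
    # pediatric exclusivities are always post-approval
    ped = exclusivity_timing(ExclusivityCategory.PEDIATRIC, date(2001, 1, 1), APPROVAL)
    assert ped is ExclusivityTiming.POST_APPROVAL


def _two_product_cohort():
    vial = make_product(appl_no="N1", product_no="001", approval=APPROVAL)
    pen = make_product(appl_no="N1", product_no="002", approval=date(2007, 5, 1), is_device=True)
    return Cohort(
        originator_products=[vial, pen],
        originator_lines=group_lines([vial, pen], is_originator=True),
        followon_products=[],
        followon_lines=[],
    )


def test_patent_on_vial_and_pen_yields_two_objects():
    cohort = _two_product_cohort()
    raw = [
        RawPatentRow("N1", "001", "US55", date(2020, 1, 1), date(1999, 1, 1)),
        RawPatentRow("N1", "002", "US55", date(2020, 1, 1), date(1999, 1, 1)),
    ]
    ann = [PatentAnnotation("US55", date(1998, 5, 1), date(1997, 5, 1), True, False)]
    patents, _ = link_and_classify(raw, [], ann, cohort)
    assert len(patents) == 2
    assert {p.patent_no for p in patents} == {"US55"}
    assert all(p.device_status is DeviceStatus.DEVICE_NO_MENTION for p in patents)
    # same patent, different products: timing is per product approval
    by_prod = {p.product_no: p for p in patents}
    assert by_prod["001"].filing_timing is FilingTiming.PRE_APPROVAL_FILED
    assert by_prod["002"].filing_timing is FilingTiming.PRE_APPROVAL_FILED


def test_missing_annotation_error_lists_patents():
    cohort = _two_product_cohort()
    raw = [RawPatentRow("N1", "001", "US77", date(2020, 1, 1))]
    with pytest.raises(MissingAnnotationError) as exc:
        link_and_classify(raw, [], [], cohort)
    assert "US77" in str(exc.value)


def test_listing_outside_cohort_dropped():
    cohort = _two_product_cohort()
    raw = [RawPatentRow("N999", "001", "US88", date(2020, 1, 1))]
    patents, exclusivities = link_and_classify(
        raw, [RawExclusivityRow("N999", "001", "NCE", date(2010, 1, 1))], [], cohort
    )
    assert patents == [] and exclusivities == []


def test_classification_is_permutation_invariant():
    cohort = _two_product_cohort()
    raw_p = [
        RawPatentRow("N1", "001", f"US{i}", date(2015 + i, 1, 1), date(2001, 1, 1))
        for i in range(8)
    ]
    raw_e = [
        RawExclusivityRow("N1", "001", code, date(2004, 1, 1)) for code in ("NCE", "NP", "PED")
    ]
    ann = [
        PatentAnnotation(f"US{i}", date(2000, 1, 1), date(1999, 1, 1), i % 2 == 0, i % 3 == 0)
        for i in range(8)
    ]
    base = link_and_classify(raw_p, raw_e, ann, cohort)
    shuffled_p, shuffled_e = raw_p[:], raw_e[:]
    random.Random(9).shuffle(shuffled_p)
    random.Random(9).shuffle(shuffled_e)
    again = link_and_classify(shuffled_p, shuffled_e, ann, cohort)
    assert base == again


def test_device_status_counts_are_exhaustive(synthetic_run):
    patents = synthetic_run.patents
    by_status = {s: sum(1 for p in patents if p.device_status is s) for s in DeviceStatus}
    assert sum(by_status.values()) == len(patents)
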