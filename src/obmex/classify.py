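"""Merge raw listings with curated annotations; classify patents and
exclusivities by timing and device status.

Classification is a pure function of dates and flags:

* **Filing axis** — a patent is *pre-approval filed* iff its USPTO application
  date is strictly before the linked product's FDA approval date (equal dates
  count as post: the tie rule is the strict-inequality convention, applied
  uniformly because the source material does not state one).
* **Listing axis** — a patent is *listed at approval* iff its first Orange
  Book listing date is on or before approval (+ an optional grace period,
  default 0 days). Annual-edition inputs carry year granularity; encode those
  as December 31 of the edition year upstream.
* **Device status** — from the curated annotation: non-device, device whose
  claims mention the active ingredient, or device with no such mention.
* **Exclusivity timing** — Orange Book files list only the expiry, so grant
  timing is inferred: pediatric exclusivities are always post-approval (they
  are tallied separately); any other exclusivity is *at approval* iff its
  expiry is no later than approval plus the category's standard term
  (new chemical entity 5 years, otherwise 3 years, in round(years*365.25) days).

Patents are classified per (patent, product) pair — a patent covering both
the vial and the pen yields two objects; analyses over *unique* patents
deduplicate by patent number explicitly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date, timedelta
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .cohort import Cohort
from .io import PatentAnnotation, RawExclusivityRow, RawPatentRow

logger = logging.getLogger(__name__)


class DeviceStatus(str, Enum):
    NON_DEVICE = "non_device"
    DEVICE_MENTION = "device_mention"
    DEVICE_NO_MENTION = "device_no_mention"


class FilingTiming(str, Enum):
    PRE_APPROVAL_FILED = "pre_approval_filed"
    POST_APPROVAL_FILED = "post_approval_filed"


class ListingTiming(str, Enum):
    LISTED_AT_APPROVAL = "listed_at_approval"
    LISTED_POST_APPROVAL = "listed_post_approval"


class PriorityTiming(str, Enum):
    PRIORITY_BEFORE_APPROVAL = "priority_before_approval"
    PRIORITY_AFTER_APPROVAL = "priority_after_approval"


class ExclusivityCategory(str, Enum):
    NEW_CHEMICAL_ENTITY = "new_chemical_entity"
    NEW_PRODUCT = "new_product"
    NEW_COMBINATION = "new_combination"
    NEW_PATIENT_POPULATION = "new_patient_population"
    NEW_ROUTE = "new_route"
    NEW_INDICATION_OR_DOSING = "new_indication_or_dosing"
    PEDIATRIC = "pediatric"
    OTHER = "other"


class ExclusivityTiming(str, Enum):
    AT_APPROVAL = "at_approval"
    POST_APPROVAL = "post_approval"


#: Standard regulatory terms used to infer grant timing from the listed expiry.
EXCLUSIVITY_TERM_YEARS: dict[ExclusivityCategory, float] = {
    ExclusivityCategory.NEW_CHEMICAL_ENTITY: 5.0,
}
DEFAULT_TERM_YEARS = 3.0


@dataclass(frozen=True)
class Patent:
    """One (patent, product) classification."""

    patent_no: str
    appl_no: str
    product_no: str
    expiry: date
    application_date: date
    priority_date: date
    first_listing: date | None
    device_status: DeviceStatus
    filing_timing: FilingTiming
    listing_timing: ListingTiming
    priority_timing: PriorityTiming

    @property
    def product_key(self) -> tuple[str, str]:
        return (self.appl_no, self.product_no)

    @property
    def is_device(self) -> bool:
        return self.device_status is not DeviceStatus.NON_DEVICE


@dataclass(frozen=True)
class Exclusivity:
    code: str
    category: ExclusivityCategory
    appl_no: str
    product_no: str
    expiry: date
    timing: ExclusivityTiming

    @property
    def product_key(self) -> tuple[str, str]:
        return (self.appl_no, self.product_no)


class MissingAnnotationError(KeyError):
    def __init__(self, patent_nos: Sequence[str]):
        self.patent_nos = sorted(set(patent_nos))
        super().__init__(
            "patents missing annotations: " + ", ".join(self.patent_nos)
        )


def load_code_map(path: str | Path | None = None) -> dict[str, ExclusivityCategory]:
    """Load the exclusivity code→category table (packaged default or a custom CSV
    with columns ``code_prefix,category``)."""
    if path is None:
        ref = resources.files("obmex.data").joinpath("exclusivity_codes.csv")
        text = ref.read_text(encoding="utf-8")
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with Path(path).open("r", encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh))
    return {r["code_prefix"].strip(): ExclusivityCategory(r["category"].strip()) for r in rows}


def categorize_exclusivity(
    code: str, code_map: Mapping[str, ExclusivityCategory] | None = None
) -> ExclusivityCategory:
    """Map an Orange Book exclusivity code to a category.

    Exact code match first, then the prefix before "-" (``I-123`` → ``I``);
    anything unmatched is ``other`` (with a warning).
    """
    code_map = code_map if code_map is not None else load_code_map()
    c = code.strip().upper()
    if c in code_map:
        return code_map[c]
    prefix = c.split("-", 1)[0]
    if prefix in code_map:
        return code_map[prefix]
    logger.warning("exclusivity code %r not in mapping table; categorized as other", code)
    return ExclusivityCategory.OTHER


def patent_timing(
    application_date: date,
    approval_date: date,
    first_listing: date | None,
    grace_days: int = 0,
) -> tuple[FilingTiming, ListingTiming]:
    """Classify a patent on the filing and listing axes relative to approval.

    Ties go post (filing) / fall outside the at-approval window (listing); a
    missing first-listing date inherits the filing axis with a warning.
    """
    filing = (
        FilingTiming.PRE_APPROVAL_FILED
        if application_date < approval_date
        else FilingTiming.POST_APPROVAL_FILED
    )
    if first_listing is None:
        logger.warning(
            "no first-listing date; defaulting listing timing from filing timing (%s)",
            filing.value,
        )
        listing = (
            ListingTiming.LISTED_AT_APPROVAL
            if filing is FilingTiming.PRE_APPROVAL_FILED
            else ListingTiming.LISTED_POST_APPROVAL
        )
    else:
        listing = (
            ListingTiming.LISTED_AT_APPROVAL
            if first_listing <= approval_date + timedelta(days=grace_days)
            else ListingTiming.LISTED_POST_APPROVAL
        )
    return filing, listing


def priority_timing(priority_date: date, approval_date: date) -> PriorityTiming:
    """Strictly-before comparison of the priority date to approval; tie → after."""
    return (
        PriorityTiming.PRIORITY_BEFORE_APPROVAL
        if priority_date < approval_date
        else PriorityTiming.PRIORITY_AFTER_APPROVAL
    )


def device_status(annotation: PatentAnnotation) -> DeviceStatus:
    if not annotation.is_device:
        return DeviceStatus.NON_DEVICE
    return (
        DeviceStatus.DEVICE_MENTION
        if annotation.mentions_active
        else DeviceStatus.DEVICE_NO_MENTION
    )


def exclusivity_timing(
    category: ExclusivityCategory, expiry: date, approval_date: date
) -> ExclusivityTiming:
    """Infer grant timing from the listed expiry (see module docstring)."""
    if category is ExclusivityCategory.PEDIATRIC:
        return ExclusivityTiming.POST_APPROVAL
    term_years = EXCLUSIVITY_TERM_YEARS.get(category, DEFAULT_TERM_YEARS)
    term = timedelta(days=round(term_years * 365.25))
    return (
        ExclusivityTiming.AT_APPROVAL
        if expiry <= approval_date + term
        else ExclusivityTiming.POST_APPROVAL
    )


def link_and_classify(
    raw_patents: Sequence[RawPatentRow],
    raw_exclusivities: Sequence[RawExclusivityRow],
    annotations: Iterable[PatentAnnotation],
    cohort: Cohort,
    code_map: Mapping[str, ExclusivityCategory] | None = None,
    grace_days: int = 0,
) -> tuple[list[Patent], list[Exclusivity]]:
    """Link raw listings to cohort products and classify them.

    Listings on products outside the cohort are dropped (logged); patents
    lacking an annotation raise :class:`MissingAnnotationError` listing the
    patent numbers. Output order is canonical (sorted by product then id), so
    the result is independent of input ordering.
    """
    products = cohort.product_by_key()
    ann_by_no: dict[str, PatentAnnotation] = {a.patent_no: a for a in annotations}
    code_map = code_map if code_map is not None else load_code_map()

    in_cohort = [r for r in raw_patents if (r.appl_no, r.product_no) in products]
    missing = [r.patent_no for r in in_cohort if r.patent_no not in ann_by_no]
    if missing:
        raise MissingAnnotationError(missing)

    patents: list[Patent] = []
    for r in sorted(raw_patents, key=lambda r: (r.appl_no, r.product_no, r.patent_no)):
        product = products.get((r.appl_no, r.product_no))
        if product is None:
            logger.info(
                "patent %s on %s/%s: product outside cohort; dropped",
                r.patent_no, r.appl_no, r.product_no,
            )
            continue
        ann = ann_by_no[r.patent_no]
        filing, listing = patent_timing(
            ann.application_date, product.approval_date, r.submission_date, grace_days
        )
        patents.append(
            Patent(
                patent_no=r.patent_no,
                appl_no=r.appl_no,
                product_no=r.product_no,
                expiry=r.patent_expire_date,
                application_date=ann.application_date,
                priority_date=ann.priority_date,
                first_listing=r.submission_date,
                device_status=device_status(ann),
                filing_timing=filing,
                listing_timing=listing,
                priority_timing=priority_timing(ann.priority_date, product.approval_date),
            )
        )

    exclusivities: list[Exclusivity] = []
    for r in sorted(
        raw_exclusivities, key=lambda r: (r.appl_no, r.product_no, r.exclusivity_code, r.exclusivity_date)
    ):
        product = products.get((r.appl_no, r.product_no))
        if product is None:
            logger.info(
                "exclusivity %s on %s/%s: product outside cohort; dropped",
                r.exclusivity_code, r.appl_no, r.product_no,
            )
            continue
        category = categorize_exclusivity(r.exclusivity_code, code_map)
        exclusivities.append(
            Exclusivity(
                code=r.exclusivity_code,
                category=category,
                appl_no=r.appl_no,
                product_no=r.product_no,
                expiry=r.exclusivity_date,
                timing=exclusivity_timing(category, r.exclusivity_date, product.approval_date),
            )
        )
    return patents, exclusivities
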