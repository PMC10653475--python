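"""Last-to-expire date algebra and the duration-of-protection metrics.

The central quantity is the *duration of expected protection*: the time from
a product's FDA approval to the latest expiry among its in-scope Orange Book
patents and regulatory exclusivities, expressed in 365.25-day years. On top
of it sit:

* line-level spans (first approval in an insulin line to the last expiry over
  all member products),
* the extension attributable to post-approval listings,
* device-patent added protection (last device expiry minus last non-device
  expiry, signed), and
* the added protection of device patents whose claims never mention the
  active ingredient, over the later of all other patents.

Negative differences are computed and retained — reporting layers decide
whether to filter to the positive subset. Rounding to one decimal happens
only at serialization, never here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .classify import (
    DeviceStatus,
    Exclusivity,
    ExclusivityTiming,
    FilingTiming,
    ListingTiming,
    Patent,
)
from .cohort import InsulinLine, Product
from .dates import years_between

logger = logging.getLogger(__name__)


class PatentScope(str, Enum):
    """Which patents enter the last-to-expire computation."""

    ALL = "all"
    AT_APPROVAL_ONLY = "at_approval_only"  # listing axis
    PRE_APPROVAL_FILED_ONLY = "pre_approval_filed_only"  # filing axis
    DEVICE_ONLY = "device_only"
    NON_DEVICE_ONLY = "non_device_only"
    DEVICE_NO_MENTION_ONLY = "device_no_mention_only"
    OTHER_THAN_NO_MENTION = "other_than_no_mention"


class ExclusivityTimingFilter(str, Enum):
    ALL = "all"
    AT_APPROVAL_ONLY = "at_approval_only"


@dataclass(frozen=True)
class ProtectionScope:
    """Conjunctive filters selecting the protections in play."""

    which_patents: PatentScope = PatentScope.ALL
    include_exclusivities: bool = True
    exclusivity_timing_filter: ExclusivityTimingFilter = ExclusivityTimingFilter.ALL


FULL_SCOPE = ProtectionScope()
AT_APPROVAL_SCOPE = ProtectionScope(
    which_patents=PatentScope.AT_APPROVAL_ONLY,
    exclusivity_timing_filter=ExclusivityTimingFilter.AT_APPROVAL_ONLY,
)


class LastItemKind(str, Enum):
    PATENT_DEVICE = "patent_device"
    PATENT_NON_DEVICE = "patent_non_device"
    EXCLUSIVITY = "exclusivity"
    NONE = "none"


@dataclass(frozen=True)
class ProductProtection:
    product: Product
    last_expiry: date | None
    duration_years: float | None
    last_item_kind: LastItemKind
    scope: ProtectionScope = FULL_SCOPE

    @property
    def excluded_from_medians(self) -> bool:
        """Products with no in-scope protections are excluded from duration
        medians (but stay in cohort totals)."""
        return self.last_expiry is None


@dataclass(frozen=True)
class LineSpan:
    line: InsulinLine
    first_filing: date | None
    first_approval: date
    last_expiry: date | None
    duration_years: float | None


def last_to_expire(dates: Iterable[date]) -> date | None:
    """Latest date in the collection; ``None`` for an empty collection."""
    dates = list(dates)
    return max(dates) if dates else None


def _patent_in_scope(p: Patent, which: PatentScope) -> bool:
    if which is PatentScope.ALL:
        return True
    if which is PatentScope.AT_APPROVAL_ONLY:
        return p.listing_timing is ListingTiming.LISTED_AT_APPROVAL
    if which is PatentScope.PRE_APPROVAL_FILED_ONLY:
        return p.filing_timing is FilingTiming.PRE_APPROVAL_FILED
    if which is PatentScope.DEVICE_ONLY:
        return p.is_device
    if which is PatentScope.NON_DEVICE_ONLY:
        return p.device_status is DeviceStatus.NON_DEVICE
    if which is PatentScope.DEVICE_NO_MENTION_ONLY:
        return p.device_status is DeviceStatus.DEVICE_NO_MENTION
    if which is PatentScope.OTHER_THAN_NO_MENTION:
        return p.device_status is not DeviceStatus.DEVICE_NO_MENTION
    raise ValueError(f"unknown patent scope {which!r}")


def _exclusivity_in_scope(e: Exclusivity, scope: ProtectionScope) -> bool:
    if not scope.include_exclusivities:
        return False
    if scope.exclusivity_timing_filter is ExclusivityTimingFilter.AT_APPROVAL_ONLY:
        return e.timing is ExclusivityTiming.AT_APPROVAL
    return True


def in_scope_items(
    product: Product,
    patents: Sequence[Patent],
    exclusivities: Sequence[Exclusivity],
    scope: ProtectionScope,
) -> tuple[list[Patent], list[Exclusivity]]:
    """Protections linked to *product* that pass the scope filters."""
    ps = [
        p
        for p in patents
        if p.product_key == product.key and _patent_in_scope(p, scope.which_patents)
    ]
    es = [
        e
        for e in exclusivities
        if e.product_key == product.key and _exclusivity_in_scope(e, scope)
    ]
    return ps, es


def product_protection(
    product: Product,
    patents: Sequence[Patent],
    exclusivities: Sequence[Exclusivity],
    scope: ProtectionScope = FULL_SCOPE,
) -> ProductProtection:
    """Duration from approval to the last-to-expire in-scope protection.

    Products with no in-scope items get ``None`` fields and are flagged for
    exclusion from medians. A last expiry before approval yields a negative
    duration (retained, with a warning).
    """
    ps, es = in_scope_items(product, patents, exclusivities, scope)
    expiry = last_to_expire([p.expiry for p in ps] + [e.expiry for e in es])
    if expiry is None:
        return ProductProtection(product, None, None, LastItemKind.NONE, scope)

    # kind of the item(s) achieving the max; ties break device > non-device > exclusivity
    kinds: set[LastItemKind] = set()
    for p in ps:
        if p.expiry == expiry:
            kinds.add(
                LastItemKind.PATENT_DEVICE if p.is_device else LastItemKind.PATENT_NON_DEVICE
            )
    if any(e.expiry == expiry for e in es):
        kinds.add(LastItemKind.EXCLUSIVITY)
    for kind in (LastItemKind.PATENT_DEVICE, LastItemKind.PATENT_NON_DEVICE, LastItemKind.EXCLUSIVITY):
        if kind in kinds:
            last_kind = kind
            break

    duration = years_between(product.approval_date, expiry)
    if duration < 0:
        logger.warning(
            "product %s/%s: last expiry %s precedes approval %s (negative duration)",
            product.appl_no, product.product_no, expiry, product.approval_date,
        )
    return ProductProtection(product, expiry, duration, last_kind, scope)


def post_approval_extension(
    product: Product,
    patents: Sequence[Patent],
    exclusivities: Sequence[Exclusivity],
) -> float | None:
    """Extension of protection attributable to post-approval listings.

    Difference between the full-scope duration and the at-approval-only
    duration; reported only when some post-approval listing exists and the
    gain is strictly positive (otherwise ``None``).
    """
    ps_all, es_all = in_scope_items(product, patents, exclusivities, FULL_SCOPE)
    has_post = any(
        p.listing_timing is ListingTiming.LISTED_POST_APPROVAL for p in ps_all
    ) or any(e.timing is ExclusivityTiming.POST_APPROVAL for e in es_all)
    if not has_post:
        return None
    overall = product_protection(product, patents, exclusivities, FULL_SCOPE)
    at_approval = product_protection(product, patents, exclusivities, AT_APPROVAL_SCOPE)
    if overall.last_expiry is None:
        return None
    if at_approval.last_expiry is None:
        # everything the product has was added post-approval: the whole
        # duration is extension (when positive)
        gain = overall.duration_years
    else:
        gain = years_between(at_approval.last_expiry, overall.last_expiry)
    return gain if gain is not None and gain > 0 else None


def line_protection(
    line: InsulinLine,
    patents: Sequence[Patent],
    exclusivities: Sequence[Exclusivity],
    scope: ProtectionScope = FULL_SCOPE,
) -> LineSpan:
    """Span from the line's first approval to the last in-scope expiry over all
    member products; ``first_filing`` is the earliest priority/application date
    (for timeline exports)."""
    first_approval = line.first_approval
    expiries: list[date] = []
    filings: list[date] = []
    for product in line.products:
        ps, es = in_scope_items(product, patents, exclusivities, scope)
        expiries.extend(p.expiry for p in ps)
        expiries.extend(e.expiry for e in es)
        for p in ps:
            filings.append(min(p.priority_date, p.application_date))
    expiry = last_to_expire(expiries)
    return LineSpan(
        line=line,
        first_filing=min(filings) if filings else None,
        first_approval=first_approval,
        last_expiry=expiry,
        duration_years=years_between(first_approval, expiry) if expiry else None,
    )


def device_added_protection(
    product: Product, patents: Sequence[Patent]
) -> float | None:
    """Signed years between the last-to-expire device patent and the
    last-to-expire non-device patent; ``None`` when either class is absent."""
    device = [p.expiry for p in patents if p.product_key == product.key and p.is_device]
    non_device = [
        p.expiry
        for p in patents
        if p.product_key == product.key and p.device_status is DeviceStatus.NON_DEVICE
    ]
    if not device or not non_device:
        return None
    return years_between(max(non_device), max(device))


def no_mention_added_protection(
    product: Product, patents: Sequence[Patent]
) -> float | None:
    """Signed years the last no-mention device patent outlasts the later of all
    other patents (mention-device or non-device); ``None`` if either side is
    empty."""
    no_mention = [
        p.expiry
        for p in patents
        if p.product_key == product.key
        and p.device_status is DeviceStatus.DEVICE_NO_MENTION
    ]
    complement = [
        p.expiry
        for p in patents
        if p.product_key == product.key
        and p.device_status is not DeviceStatus.DEVICE_NO_MENTION
    ]
    if not no_mention or not complement:
        return None
    return years_between(max(complement), max(no_mention))


def export_timeline(
    product_protections: Sequence[ProductProtection],
    patents: Sequence[Patent],
    line_spans: Sequence[LineSpan],
    path: str | Path,
) -> None:
    """Write the timeline CSV (entity_id, level, first_filing, approval,
    last_expiry) backing approval-to-expiry Gantt-style plots."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["entity_id", "level", "first_filing", "approval", "last_expiry"])
        for pp in product_protections:
            filings = [
                min(p.priority_date, p.application_date)
                for p in patents
                if p.product_key == pp.product.key
            ]
            writer.writerow(
                [
                    f"{pp.product.appl_no}/{pp.product.product_no}",
                    "product",
                    min(filings).isoformat() if filings else "",
                    pp.product.approval_date.isoformat(),
                    pp.last_expiry.isoformat() if pp.last_expiry else "",
                ]
            )
        for ls in line_spans:
            writer.writerow(
                [
                    ls.line.line_id,
                    "line",
                    ls.first_filing.isoformat() if ls.first_filing else "",
                    ls.first_approval.isoformat(),
                    ls.last_expiry.isoformat() if ls.last_expiry else "",
                ]
            )
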