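"""Descriptive statistics and the study report.

No inferential statistics are produced — the analysis is descriptive by
design. Quartiles use linear interpolation between order statistics
(positions 0.25/0.5/0.75 × (n−1)), the common default in mainstream
statistical software; a discrete (nearest order statistic) variant is
available via ``method="nearest"``.

Patent/exclusivity tallies and duration summaries cover originator products;
follow-on lines enter through the cohort counts and the sensitivity analysis.
Products with no listed protections are excluded from duration medians but
remain in cohort totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import (
    DeviceStatus,
    Exclusivity,
    ExclusivityCategory,
    ExclusivityTiming,
    FilingTiming,
    ListingTiming,
    Patent,
    PriorityTiming,
)
from .cohort import Cohort, Product
from .followon import (
    FollowonMatch,
    earliest_followon_by_line,
    truncated_line_protection,
    truncated_protection,
)
from .protection import (
    AT_APPROVAL_SCOPE,
    FULL_SCOPE,
    LastItemKind,
    LineSpan,
    ProductProtection,
    ProtectionScope,
    device_added_protection,
    line_protection,
    no_mention_added_protection,
    post_approval_extension,
    product_protection,
)

logger = logging.getLogger(__name__)

#: Fixed tercile bounds (inclusive approval years).
TERCILE_ERAS = ((1986, 1996), (1997, 2007), (2008, 2019))


def median_iqr(
    values: Sequence[float], method: str = "linear"
) -> tuple[float, float, float]:
    """(median, Q1, Q3) of *values*; raises on an empty input."""
    if len(values) == 0:
        raise ValueError("median_iqr of an empty list")
    arr = np.asarray(values, dtype=float)
    median, q1, q3 = np.quantile(arr, [0.5, 0.25, 0.75], method=method)
    return float(median), float(q1), float(q3)


@dataclass(frozen=True)
class DurationSummary:
    n: int
    median: float | None = None
    q1: float | None = None
    q3: float | None = None

    @classmethod
    def of(cls, values: Sequence[float], method: str = "linear") -> "DurationSummary":
        if not values:
            return cls(n=0)
        m, q1, q3 = median_iqr(values, method=method)
        return cls(n=len(values), median=m, q1=q1, q3=q3)


def _era_bounds(binning: str) -> list[tuple[int, int]]:
    if binning == "terciles":
        return list(TERCILE_ERAS)
    if binning == "five_year":
        bounds = []
        start = TERCILE_ERAS[0][0]
        end = TERCILE_ERAS[-1][1]
        y = start
        while y <= end:
            bounds.append((y, min(y + 4, end)))
            y += 5
        return bounds
    raise ValueError(f"unknown binning {binning!r} (terciles or five_year)")


def era_summary(
    products: Sequence[Product],
    patents: Sequence[Patent],
    binning: str = "terciles",
    method: str = "linear",
) -> pd.DataFrame:
    """Per-era medians (with IQR) of pre-approval patents per product, total and
    device-only. Eras bin the approval year; terciles are fixed at 1986–1996,
    1997–2007, 2008–2019."""
    bounds = _era_bounds(binning)
    lo, hi = bounds[0][0], bounds[-1][1]

    pre_by_product: dict[tuple[str, str], int] = {}
    pre_device_by_product: dict[tuple[str, str], int] = {}
    for p in patents:
        if p.filing_timing is FilingTiming.PRE_APPROVAL_FILED:
            pre_by_product[p.product_key] = pre_by_product.get(p.product_key, 0) + 1
            if p.is_device:
                pre_device_by_product[p.product_key] = (
                    pre_device_by_product.get(p.product_key, 0) + 1
                )

    per_era_total: dict[tuple[int, int], list[int]] = {b: [] for b in bounds}
    per_era_device: dict[tuple[int, int], list[int]] = {b: [] for b in bounds}
    for product in products:
        year = product.approval_date.year
        if year < lo or year > hi:
            raise ValueError(
                f"product {product.key}: approval year {year} outside eras {lo}–{hi}"
            )
        era = next(b for b in bounds if b[0] <= year <= b[1])
        per_era_total[era].append(pre_by_product.get(product.key, 0))
        per_era_device[era].append(pre_device_by_product.get(product.key, 0))

    rows = []
    for b in bounds:
        total = per_era_total[b]
        dev = per_era_device[b]
        row: dict[str, object] = {
            "era_start": b[0],
            "era_end": b[1],
            "n_products": len(total),
        }
        if total:
            m, q1, q3 = median_iqr(total, method=method)
            md, q1d, q3d = median_iqr(dev, method=method)
            row.update(
                median_patents=m, q1_patents=q1, q3_patents=q3,
                median_device_patents=md, q1_device_patents=q1d, q3_device_patents=q3d,
            )
        else:
            row.update(
                median_patents=None, q1_patents=None, q3_patents=None,
                median_device_patents=None, q1_device_patents=None, q3_device_patents=None,
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StudyReport:
    """Every tally and duration summary the analysis produces.

    ``percentages`` are unrounded (rounding to whole numbers is a
    serialization concern) and always recomputable from ``counts`` /
    ``patent_tallies`` / ``exclusivity_tallies``.
    """

    counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)
    patent_tallies: dict[str, int] = field(default_factory=dict)
    exclusivity_tallies: dict[str, int] = field(default_factory=dict)
    durations: dict[str, DurationSummary] = field(default_factory=dict)
    per_class_durations: dict[str, DurationSummary] = field(default_factory=dict)
    era_terciles: list[dict] = field(default_factory=list)
    era_five_year: list[dict] = field(default_factory=list)
    sensitivity: dict[str, DurationSummary] = field(default_factory=dict)
    followon_matches: list[dict] = field(default_factory=list)
    no_protection_products: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


def _pct(part: int, whole: int) -> float:
    return 100.0 * part / whole if whole else 0.0


def cohort_report(
    cohort: Cohort,
    patents: Sequence[Patent],
    exclusivities: Sequence[Exclusivity],
    matches: Sequence[FollowonMatch] = (),
    scope: ProtectionScope = FULL_SCOPE,
    method: str = "linear",
) -> StudyReport:
    """Assemble the full study report from the classified inputs."""
    report = StudyReport()
    orig = cohort.originator_products
    orig_keys = {p.key for p in orig}
    devices = [p for p in orig if p.is_drug_device]

    # ---- cohort counts -------------------------------------------------
    c = report.counts
    c["originator_products"] = len(orig)
    c["originator_lines"] = len(cohort.originator_lines)
    c["drug_device_products"] = len(devices)
    c["drug_only_products"] = len(orig) - len(devices)
    c["followon_products"] = len(cohort.followon_products)
    c["followon_lines"] = len(cohort.followon_lines)
    c["excluded_records"] = len(cohort.exclusion_log)
    report.percentages["pct_drug_device"] = _pct(len(devices), len(orig))

    # ---- patent tallies (originator listings; per patent-product pair) --
    op = [p for p in patents if p.product_key in orig_keys]
    t = report.patent_tallies
    t["patent_product_pairs"] = len(op)
    t["pre_approval_filed"] = sum(
        1 for p in op if p.filing_timing is FilingTiming.PRE_APPROVAL_FILED
    )
    t["post_approval_filed"] = len(op) - t["pre_approval_filed"]
    t["listed_at_approval"] = sum(
        1 for p in op if p.listing_timing is ListingTiming.LISTED_AT_APPROVAL
    )
    t["listed_post_approval"] = len(op) - t["listed_at_approval"]
    t["device_pairs"] = sum(1 for p in op if p.is_device)
    t["non_device_pairs"] = len(op) - t["device_pairs"]
    t["device_no_mention_pairs"] = sum(
        1 for p in op if p.device_status is DeviceStatus.DEVICE_NO_MENTION
    )
    t["pre_approval_device"] = sum(
        1
        for p in op
        if p.filing_timing is FilingTiming.PRE_APPROVAL_FILED and p.is_device
    )
    post_listed = [p for p in op if p.listing_timing is ListingTiming.LISTED_POST_APPROVAL]
    t["post_listed_device"] = sum(1 for p in post_listed if p.is_device)
    t["post_listed_priority_before_approval"] = sum(
        1
        for p in post_listed
        if p.priority_timing is PriorityTiming.PRIORITY_BEFORE_APPROVAL
    )
    t["post_listed_priority_after_approval"] = (
        len(post_listed) - t["post_listed_priority_before_approval"]
    )
    unique = {p.patent_no: p for p in op}
    unique_device = {p.patent_no for p in op if p.is_device}
    t["unique_patents"] = len(unique)
    t["unique_device_patents"] = len(unique_device)
    t["unique_device_no_mention_patents"] = len(
        {p.patent_no for p in op if p.device_status is DeviceStatus.DEVICE_NO_MENTION}
    )
    device_keys = {p.key for p in devices}
    pairs_on_devices = [p for p in op if p.product_key in device_keys]
    report.percentages["pct_device_patents_on_combinations"] = _pct(
        sum(1 for p in pairs_on_devices if p.is_device), len(pairs_on_devices)
    )
    report.percentages["pct_pre_approval_device"] = _pct(
        t["pre_approval_device"], t["pre_approval_filed"]
    )

    # ---- exclusivity tallies -------------------------------------------
    oe = [e for e in exclusivities if e.product_key in orig_keys]
    x = report.exclusivity_tallies
    x["total"] = len(oe)
    at = [e for e in oe if e.timing is ExclusivityTiming.AT_APPROVAL]
    post = [e for e in oe if e.timing is ExclusivityTiming.POST_APPROVAL]
    x["at_approval_total"] = len(at)
    x["post_approval_total"] = len(post)
    x["pediatric"] = sum(1 for e in oe if e.category is ExclusivityCategory.PEDIATRIC)
    for cat in ExclusivityCategory:
        x[f"at_approval_{cat.value}"] = sum(1 for e in at if e.category is cat)
        x[f"post_approval_{cat.value}"] = sum(1 for e in post if e.category is cat)

    # ---- duration metrics ----------------------------------------------
    protections = [product_protection(p, patents, exclusivities, scope) for p in orig]
    report.no_protection_products = [
        f"{pp.product.appl_no}/{pp.product.product_no}"
        for pp in protections
        if pp.excluded_from_medians
    ]
    with_prot = [pp for pp in protections if not pp.excluded_from_medians]
    report.counts["products_with_protection"] = len(with_prot)
    durations = [pp.duration_years for pp in with_prot]
    report.durations["product_overall"] = DurationSummary.of(durations, method)

    at_prot = [
        product_protection(p, patents, exclusivities, AT_APPROVAL_SCOPE) for p in orig
    ]
    report.durations["product_at_approval"] = DurationSummary.of(
        [pp.duration_years for pp in at_prot if not pp.excluded_from_medians], method
    )

    spans = [line_protection(l, patents, exclusivities, scope) for l in cohort.originator_lines]
    report.durations["line_overall"] = DurationSummary.of(
        [s.duration_years for s in spans if s.duration_years is not None], method
    )

    extensions = [
        ext
        for p in orig
        if (ext := post_approval_extension(p, patents, exclusivities)) is not None
    ]
    report.durations["post_approval_extension"] = DurationSummary.of(extensions, method)

    dev_added = [
        v for p in devices if (v := device_added_protection(p, patents)) is not None
    ]
    report.durations["device_added_all"] = DurationSummary.of(dev_added, method)
    report.durations["device_added_positive"] = DurationSummary.of(
        [v for v in dev_added if v > 0], method
    )
    nm_added = [
        v for p in devices if (v := no_mention_added_protection(p, patents)) is not None
    ]
    report.durations["no_mention_added_all"] = DurationSummary.of(nm_added, method)
    report.durations["no_mention_added_positive"] = DurationSummary.of(
        [v for v in nm_added if v > 0], method
    )
    report.counts["last_item_device_patent"] = sum(
        1 for pp in protections if pp.last_item_kind is LastItemKind.PATENT_DEVICE
    )
    report.percentages["pct_last_item_device"] = _pct(
        report.counts["last_item_device_patent"], len(orig)
    )

    # ---- per-class durations --------------------------------------------
    by_class: dict[str, list[float]] = {}
    for pp in with_prot:
        by_class.setdefault(pp.product.insulin_class.value, []).append(pp.duration_years)
    report.per_class_durations = {
        cls: DurationSummary.of(vals, method) for cls, vals in sorted(by_class.items())
    }

    # ---- era tables ------------------------------------------------------
    report.era_terciles = era_summary(orig, patents, "terciles", method).to_dict("records")
    report.era_five_year = era_summary(orig, patents, "five_year", method).to_dict("records")

    # ---- sensitivity (follow-on truncation) ------------------------------
    first_fo = earliest_followon_by_line(matches)
    line_of_product = {
        p.key: line.line_id for line in cohort.originator_lines for p in line.products
    }
    trunc = [
        v
        for pp in protections
        if (
            v := truncated_protection(pp, first_fo.get(line_of_product[pp.product.key]))
        )
        is not None
    ]
    report.sensitivity["product_truncated"] = DurationSummary.of(trunc, method)
    line_trunc = [
        v
        for s in spans
        if (v := truncated_line_protection(s, first_fo.get(s.line.line_id))) is not None
    ]
    report.sensitivity["line_truncated"] = DurationSummary.of(line_trunc, method)
    report.followon_matches = [
        {
            "originator_line": m.originator_line.line_id,
            "followon_line": m.followon_line.line_id,
            "first_followon_approval": m.first_followon_approval.isoformat(),
        }
        for m in matches
    ]
    return report
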