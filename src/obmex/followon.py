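"""Follow-on matching and the entry-truncated sensitivity analysis.

A follow-on is a product with the same active ingredients as an originator
but a different manufacturer, approved via the 505(b)(2) pathway. The
sensitivity analysis truncates each originator's protection at the approval
of its earliest matching follow-on: duration runs from FDA approval to the
earlier of the last-to-expire protection and first follow-on entry.

Matching is on exact equality of normalized active-ingredient sets (case-
insensitive, generic token stripped), so "insulin glargine" matches
"GLARGINE" across applicants. An originator line may match several follow-ons
(the earliest approval is what truncates it) and one follow-on may match
several originator lines (human insulin); all pairs are reported.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Sequence

from .cohort import Cohort, InsulinLine
from .dates import years_between
from .protection import LineSpan, ProductProtection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FollowonMatch:
    originator_line: InsulinLine
    followon_line: InsulinLine
    first_followon_approval: date


def match_followons(cohort: Cohort) -> list[FollowonMatch]:
    """All (originator line, follow-on line) pairs with identical normalized
    ingredient sets and different manufacturers. Follow-on lines matching no
    originator are warned about and omitted."""
    matches: list[FollowonMatch] = []
    for fo in cohort.followon_lines:
        matched = False
        for orig in cohort.originator_lines:
            if (
                fo.active_ingredients == orig.active_ingredients
                and fo.manufacturer != orig.manufacturer
            ):
                matches.append(
                    FollowonMatch(
                        originator_line=orig,
                        followon_line=fo,
                        first_followon_approval=fo.first_approval,
                    )
                )
                matched = True
        if not matched:
            logger.warning(
                "follow-on line %s (%s) matches no originator line",
                fo.line_id,
                "/".join(sorted(fo.active_ingredients)),
            )
    matches.sort(
        key=lambda m: (m.originator_line.line_id, m.followon_line.line_id)
    )
    return matches


def earliest_followon_by_line(matches: Sequence[FollowonMatch]) -> dict[str, date]:
    """Earliest follow-on approval per originator line id."""
    first: dict[str, date] = {}
    for m in matches:
        lid = m.originator_line.line_id
        if lid not in first or m.first_followon_approval < first[lid]:
            first[lid] = m.first_followon_approval
    return first


def truncated_protection(
    result: ProductProtection, first_followon_approval: date | None
) -> float | None:
    """Duration from approval to min(last expiry, first follow-on approval).

    With no matching follow-on the duration is unchanged; with no protections
    it stays ``None``.
    """
    if result.last_expiry is None or result.duration_years is None:
        return None
    if first_followon_approval is None:
        return result.duration_years
    end = min(result.last_expiry, first_followon_approval)
    return years_between(result.product.approval_date, end)


def truncated_line_protection(
    span: LineSpan, first_followon_approval: date | None
) -> float | None:
    """Line-level analog: the span is cut at the earliest matching follow-on."""
    if span.last_expiry is None or span.duration_years is None:
        return None
    if first_followon_approval is None:
        return span.duration_years
    end = min(span.last_expiry, first_followon_approval)
    return years_between(span.first_approval, end)


def export_matches(matches: Sequence[FollowonMatch], path: str | Path) -> None:
    """Match report CSV: (originator_line, followon_line, first_followon_approval)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["originator_line", "followon_line", "first_followon_approval"])
        for m in matches:
            writer.writerow(
                [
                    m.originator_line.line_id,
                    m.followon_line.line_id,
                    m.first_followon_approval.isoformat(),
                ]
            )
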