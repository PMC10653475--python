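"""Cohort construction: inclusion/exclusion rules and the product/line model.

The study cohort covers biosynthetic insulin products approved within a fixed
window (default 1986-01-01 through 2019-12-31: consecutive patent-listing
editions begin in 1986, and insulins left the small-molecule listing regime in
March 2020). Animal-derived products and the pre-window biosynthetic brands
(Humulin R/L/N) are excluded, with every exclusion logged.

Products sold under the same NDA (e.g., a vial and a pen) are separate
analysis units. Products sharing a brand family, active-ingredient set, and
manufacturer form an *insulin line*; brand family — not NDA alone — is the
grouping key so that a brand split across two NDAs (the Humalog case) is one
line, matching the line-level analysis convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .io import ProductMetadataRow, RawProductRow

logger = logging.getLogger(__name__)


class InsulinClass(str, Enum):
    """Onset-of-action classes (mixtures split by their components)."""

    RAPID = "rapid"
    SHORT = "short"
    INTERMEDIATE = "intermediate"
    LONG = "long"
    MIXTURE_LONG_INCRETIN = "mixture_long_incretin"
    MIXTURE_INTERMEDIATE_RAPID = "mixture_intermediate_rapid"
    MIXTURE_INTERMEDIATE_SHORT = "mixture_intermediate_short"


class Presentation(str, Enum):
    VIAL = "vial"
    SINGLE_USE_DEVICE = "single_use_device"
    REUSABLE_DEVICE = "reusable_device"
    INHALED_DEVICE = "inhaled_device"
    INFUSION_BAG = "infusion_bag"
    OTHER = "other"


#: Presentations that make a product a drug-device combination.
DEVICE_PRESENTATIONS = frozenset(
    {Presentation.SINGLE_USE_DEVICE, Presentation.REUSABLE_DEVICE, Presentation.INHALED_DEVICE}
)

#: Section-header style labels mapped onto the class enum.
_CLASS_LABELS: dict[str, InsulinClass] = {
    "rapid": InsulinClass.RAPID,
    "rapid-acting insulins": InsulinClass.RAPID,
    "rapid-acting": InsulinClass.RAPID,
    "short": InsulinClass.SHORT,
    "short-acting insulins": InsulinClass.SHORT,
    "short-acting": InsulinClass.SHORT,
    "intermediate": InsulinClass.INTERMEDIATE,
    "intermediate-acting insulin": InsulinClass.INTERMEDIATE,
    "intermediate-acting": InsulinClass.INTERMEDIATE,
    "long": InsulinClass.LONG,
    "long-acting insulins": InsulinClass.LONG,
    "long-acting": InsulinClass.LONG,
    "mixture_long_incretin": InsulinClass.MIXTURE_LONG_INCRETIN,
    "long-acting and incretin mimetic": InsulinClass.MIXTURE_LONG_INCRETIN,
    "mixture_intermediate_rapid": InsulinClass.MIXTURE_INTERMEDIATE_RAPID,
    "intermediate-acting and rapid-acting insulin mix": InsulinClass.MIXTURE_INTERMEDIATE_RAPID,
    "mixture_intermediate_short": InsulinClass.MIXTURE_INTERMEDIATE_SHORT,
    "intermediate and short-acting insulins": InsulinClass.MIXTURE_INTERMEDIATE_SHORT,
}


def assign_class(label: str) -> InsulinClass:
    """Map a curated class label (enum value or section-header text) to the enum."""
    key = label.strip().lower()
    try:
        return _CLASS_LABELS[key]
    except KeyError:
        raise ValueError(f"unknown insulin class label {label!r}") from None


def normalize_ingredient(name: str) -> str:
    """Canonical ingredient token for cross-applicant comparison.

    Uppercases, collapses whitespace, and drops the generic "INSULIN" token so
    that "insulin glargine" and "GLARGINE" compare equal; a bare "INSULIN" is
    kept as-is.
    """
    tokens = [t for t in name.upper().split() if t]
    stripped = [t for t in tokens if t != "INSULIN"]
    return " ".join(stripped) if stripped else "INSULIN"


def ingredient_key(ingredients: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_ingredient(i) for i in ingredients)


@dataclass(frozen=True)
class Product:
    """One marketed presentation, fully typed after cohort building."""

    appl_no: str
    product_no: str
    trade_name: str
    brand_family: str
    active_ingredients: tuple[str, ...]
    approval_date: date
    manufacturer: str
    insulin_class: InsulinClass
    presentation: Presentation
    is_drug_device: bool

    @property
    def key(self) -> tuple[str, str]:
        return (self.appl_no, self.product_no)

    @property
    def ingredient_set(self) -> frozenset[str]:
        return ingredient_key(self.active_ingredients)


@dataclass(frozen=True)
class InsulinLine:
    """Products sharing brand family, active-ingredient set, and manufacturer."""

    line_id: str
    products: tuple[Product, ...]
    active_ingredients: frozenset[str]
    manufacturer: str
    is_originator: bool

    def __post_init__(self) -> None:
        if not self.products:
            raise ValueError(f"line {self.line_id}: no member products")
        for p in self.products:
            if p.ingredient_set != self.active_ingredients:
                raise ValueError(
                    f"line {self.line_id}: product {p.key} ingredient set "
                    f"{set(p.ingredient_set)} != line set {set(self.active_ingredients)}"
                )

    @property
    def first_approval(self) -> date:
        return min(p.approval_date for p in self.products)


#: Default animal-derived exclusion terms (matched case-insensitively inside
#: ingredient strings).
DEFAULT_EXCLUDED_INGREDIENT_TERMS = ("BEEF", "PORK", "BOVINE", "PORCINE")

#: Biosynthetic brands approved before the window, excluded by name.
DEFAULT_EXCLUDED_TRADE_NAMES = ("HUMULIN R", "HUMULIN L", "HUMULIN N")


@dataclass(frozen=True)
class CohortConfig:
    window_start: date = date(1986, 1, 1)
    window_end: date = date(2019, 12, 31)
    excluded_ingredient_terms: tuple[str, ...] = DEFAULT_EXCLUDED_INGREDIENT_TERMS
    excluded_trade_names: tuple[str, ...] = DEFAULT_EXCLUDED_TRADE_NAMES

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise ValueError("window_start must precede window_end")

    def in_window(self, d: date) -> bool:
        # half-open [start, end + 1 day) on the approval date
        return self.window_start <= d <= self.window_end


@dataclass
class Cohort:
    originator_products: list[Product]
    originator_lines: list[InsulinLine]
    followon_products: list[Product]
    followon_lines: list[InsulinLine]
    exclusion_log: list[tuple[RawProductRow, str]] = field(default_factory=list)

    @property
    def all_products(self) -> list[Product]:
        return self.originator_products + self.followon_products

    def product_by_key(self) -> dict[tuple[str, str], Product]:
        return {p.key: p for p in self.all_products}


class MissingMetadataError(KeyError):
    """A cohort product lacked a row in the curation table."""

    def __init__(self, orphans: Sequence[tuple[str, str]]):
        self.orphans = list(orphans)
        super().__init__(
            "products missing curation metadata: "
            + ", ".join(f"{a}/{p}" for a, p in self.orphans)
        )


class LineGroupingError(ValueError):
    """Products with an identical line key disagree on manufacturer."""


def _is_animal_derived(row: RawProductRow, terms: Sequence[str]) -> bool:
    hay = " ".join(row.active_ingredients).upper() + " " + row.trade_name.upper()
    return any(term.upper() in hay for term in terms)


def build_cohort(
    products: Sequence[RawProductRow],
    config: CohortConfig | None = None,
    metadata: Sequence[ProductMetadataRow] | Mapping[tuple[str, str], ProductMetadataRow] = (),
) -> Cohort:
    """Apply inclusion rules and assemble the typed cohort.

    Every input row lands either in the cohort or in ``exclusion_log`` with a
    reason (partition property). Retained products must each have a curation
    row; orphans raise :class:`MissingMetadataError` listing the keys.
    """
    config = config or CohortConfig()
    if isinstance(metadata, Mapping):
        meta_by_key = dict(metadata)
    else:
        meta_by_key = {(m.appl_no, m.product_no): m for m in metadata}

    retained_raw: list[RawProductRow] = []
    exclusion_log: list[tuple[RawProductRow, str]] = []
    for row in sorted(products, key=lambda r: (r.appl_no, r.product_no)):
        if _is_animal_derived(row, config.excluded_ingredient_terms):
            exclusion_log.append((row, "animal-derived"))
            logger.info("excluded %s/%s (%s): animal-derived", row.appl_no, row.product_no, row.trade_name)
        elif row.trade_name.strip().upper() in {t.upper() for t in config.excluded_trade_names}:
            exclusion_log.append((row, "pre-window biosynthetic brand"))
            logger.info("excluded %s/%s (%s): pre-window brand", row.appl_no, row.product_no, row.trade_name)
        elif not config.in_window(row.approval_date):
            exclusion_log.append((row, "outside window"))
            logger.info(
                "excluded %s/%s (%s): approval %s outside window",
                row.appl_no, row.product_no, row.trade_name, row.approval_date,
            )
        else:
            retained_raw.append(row)

    orphans = [
        (r.appl_no, r.product_no)
        for r in retained_raw
        if (r.appl_no, r.product_no) not in meta_by_key
    ]
    if orphans:
        raise MissingMetadataError(orphans)

    originators: list[Product] = []
    followons: list[Product] = []
    for r in retained_raw:
        m = meta_by_key[(r.appl_no, r.product_no)]
        presentation = Presentation(m.presentation)
        product = Product(
            appl_no=r.appl_no,
            product_no=r.product_no,
            trade_name=r.trade_name,
            brand_family=m.brand_family,
            active_ingredients=r.active_ingredients,
            approval_date=r.approval_date,
            manufacturer=m.manufacturer,
            insulin_class=assign_class(m.insulin_class),
            presentation=presentation,
            is_drug_device=presentation in DEVICE_PRESENTATIONS,
        )
        status = m.originator_or_followon.strip().lower()
        if status == "originator":
            originators.append(product)
        elif status in {"followon", "follow-on", "follow_on"}:
            followons.append(product)
        else:
            raise ValueError(
                f"product {product.key}: originator_or_followon must be "
                f"'originator' or 'followon', got {m.originator_or_followon!r}"
            )

    return Cohort(
        originator_products=originators,
        originator_lines=group_lines(originators, is_originator=True),
        followon_products=followons,
        followon_lines=group_lines(followons, is_originator=False),
        exclusion_log=exclusion_log,
    )


def group_lines(products: Sequence[Product], is_originator: bool) -> list[InsulinLine]:
    """Group products into insulin lines.

    Key = (brand family, normalized active-ingredient set); all members must
    share one manufacturer. NDA is deliberately not part of the key so that a
    brand family listed under two NDAs forms a single line.
    """
    groups: dict[tuple[str, frozenset[str]], list[Product]] = {}
    for p in sorted(products, key=lambda p: (p.brand_family, p.appl_no, p.product_no)):
        groups.setdefault((p.brand_family, p.ingredient_set), []).append(p)

    lines: list[InsulinLine] = []
    for (family, ingredients), members in sorted(
        groups.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]))
    ):
        manufacturers = {p.manufacturer for p in members}
        if len(manufacturers) > 1:
            raise LineGroupingError(
                f"line {family!r}: conflicting manufacturers {sorted(manufacturers)}"
            )
        lines.append(
            InsulinLine(
                line_id=family,
                products=tuple(members),
                active_ingredients=ingredients,
                manufacturer=members[0].manufacturer,
                is_originator=is_originator,
            )
        )
    return lines
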