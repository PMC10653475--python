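"""Packaged cohort fixture: the published line-level tables of biosynthetic
originator and follow-on insulins approved 1986–2019.

The two CSVs under ``obmex/data`` transcribe the published tables (brand,
active ingredients, first approval, number of products, number of drug-device
combinations) plus each line's manufacturer. Product-level approval dates for
line members beyond the first are not printed in the tables, so the expansion
to product rows assigns the line's first-approval date to every member — the
fixture supports count-level checks and line/first-approval arithmetic, not
per-product duration analysis.

The Humalog brand family is listed under two NDAs (3 + 1 products); the
expansion reproduces that split so line grouping can be exercised.
"""

from __future__ import annotations

import datetime as _dt
from importlib import resources

import pandas as pd

from .cohort import Cohort, CohortConfig, build_cohort
from .io import ProductMetadataRow, RawProductRow

#: Inhaled products (everything else device-flagged is a pen-style injector).
_INHALED_BRANDS = {"Exubera", "Afrezza"}
#: Non-device presentations that are not vials.
_INFUSION_BAG_BRANDS = {"Myxredlin"}


def _parse_us_date(text: str) -> _dt.date:
    month, day, year = (int(part) for part in text.strip().split("/"))
    return _dt.date(year, month, day)


def _load_table(name: str) -> pd.DataFrame:
    ref = resources.files("obmex.data").joinpath(name)
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    df["first_approval"] = df["first_approval"].map(_parse_us_date)
    return df


def originator_table() -> pd.DataFrame:
    """Line-level table of originator insulins (one row per brand line)."""
    return _load_table("originator_lines.csv")


def followon_table() -> pd.DataFrame:
    """Line-level table of follow-on insulins."""
    return _load_table("followon_lines.csv")


def _expand(
    df: pd.DataFrame, status: str, nda_prefix: str
) -> tuple[list[RawProductRow], list[ProductMetadataRow]]:
    rows: list[RawProductRow] = []
    meta: list[ProductMetadataRow] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        brand: str = rec.brand
        n_products = int(rec.n_products)
        n_device = int(rec.n_drug_device)
        ingredients = tuple(
            f"INSULIN {part.strip().upper()}" for part in rec.ingredients.split("/")
        )
        # one NDA per line, except the brand documented as split across two
        ndas = [f"{nda_prefix}{i:05d}"]
        per_nda = [n_products]
        if brand == "Humalog":
            ndas = [f"{nda_prefix}{i:05d}", f"{nda_prefix}9{i:04d}"]
            per_nda = [3, 1]
        product_idx = 0
        for appl_no, count in zip(ndas, per_nda):
            for j in range(count):
                product_idx += 1
                is_device = product_idx <= n_device
                if is_device:
                    presentation = (
                        "inhaled_device" if brand in _INHALED_BRANDS else "single_use_device"
                    )
                elif brand in _INFUSION_BAG_BRANDS:
                    presentation = "infusion_bag"
                else:
                    presentation = "vial"
                product_no = f"{j + 1:03d}"
                rows.append(
                    RawProductRow(
                        appl_no=appl_no,
                        product_no=product_no,
                        trade_name=brand.upper(),
                        active_ingredients=ingredients,
                        dosage_form_route="INJECTABLE;SUBCUTANEOUS",
                        approval_date=rec.first_approval,
                        applicant=rec.manufacturer.upper(),
                    )
                )
                meta.append(
                    ProductMetadataRow(
                        appl_no=appl_no,
                        product_no=product_no,
                        brand_family=brand,
                        insulin_class=rec.insulin_class,
                        presentation=presentation,
                        originator_or_followon=status,
                        manufacturer=rec.manufacturer,
                    )
                )
    return rows, meta


def fixture_product_rows() -> tuple[list[RawProductRow], list[ProductMetadataRow]]:
    """Expand the packaged line tables into product rows + curation metadata."""
    o_rows, o_meta = _expand(originator_table(), "originator", "N9")
    f_rows, f_meta = _expand(followon_table(), "followon", "N7")
    return o_rows + f_rows, o_meta + f_meta


def fixture_cohort(config: CohortConfig | None = None) -> Cohort:
    """Build the study cohort from the packaged fixture."""
    rows, meta = fixture_product_rows()
    return build_cohort(rows, config, meta)


def line_first_approval(brand: str) -> _dt.date:
    """First-approval date of a brand line from either packaged table."""
    for table in (originator_table(), followon_table()):
        hit = table.loc[table["brand"] == brand, "first_approval"]
        if len(hit):
            return hit.iloc[0]
    raise KeyError(f"brand {brand!r} not in the packaged tables")
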