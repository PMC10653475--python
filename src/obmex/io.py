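"""Readers and writers for Orange Book-style data files and annotation tables.

The FDA distributes its approved-drug listings as tilde-delimited text files
(``products.txt``, ``patent.txt``, ``exclusivity.txt``) with one header row.
This module reads those layouts (a configurable, simplified column set), the
patent-annotation CSV that supplies curated per-patent metadata (application
and priority dates, device flag, active-ingredient-mention flag), and the
product-level curation table; it also writes files back in a canonical
dialect (ISO dates, ``~`` delimiter) and serializes study reports.

Dates are normalized to :class:`datetime.date` on read; two input dialects
are accepted (``Mon DD, YYYY`` as in the real data files, and ISO-8601).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

from .dates import DateParseError, format_date, parse_date

logger = logging.getLogger(__name__)

#: Exclusivity codes recognized without a warning (prefix before any "-").
KNOWN_EXCLUSIVITY_PREFIXES = frozenset(
    {"NCE", "NP", "NC", "NPP", "NR", "NDF", "PED", "I", "D", "ODE", "GAIN", "M", "PC"}
)


class OrangeBookParseError(ValueError):
    """A data file violated the layout contract (field count, date, header)."""


@dataclass(frozen=True)
class Dialect:
    """Parser options for the delimited data files."""

    delimiter: str = "~"
    ingredient_separator: str = ";"
    encoding: str = "utf-8"


DEFAULT_DIALECT = Dialect()

PRODUCT_COLUMNS = (
    "APPL_NO",
    "PRODUCT_NO",
    "TRADE_NAME",
    "INGREDIENT",
    "DF_ROUTE",
    "APPROVAL_DATE",
    "APPLICANT",
)
PATENT_COLUMNS = (
    "APPL_NO",
    "PRODUCT_NO",
    "PATENT_NO",
    "PATENT_EXPIRE_DATE",
    "SUBMISSION_DATE",
    "DRUG_SUBSTANCE_FLAG",
    "DRUG_PRODUCT_FLAG",
    "PATENT_USE_CODE",
)
EXCLUSIVITY_COLUMNS = (
    "APPL_NO",
    "PRODUCT_NO",
    "EXCLUSIVITY_CODE",
    "EXCLUSIVITY_DATE",
)


@dataclass(frozen=True)
class RawProductRow:
    """One marketed presentation (vial, pen, ...) as listed in products.txt."""

    appl_no: str
    product_no: str
    trade_name: str
    active_ingredients: tuple[str, ...]
    dosage_form_route: str
    approval_date: date
    applicant: str


@dataclass(frozen=True)
class RawPatentRow:
    """One (product, patent) listing from patent.txt.

    ``submission_date`` is the first Orange Book listing date when known;
    annual-edition inputs with year granularity should be encoded as
    December 31 of the edition year.
    """

    appl_no: str
    product_no: str
    patent_no: str
    patent_expire_date: date
    submission_date: date | None = None
    drug_substance_flag: str = ""
    drug_product_flag: str = ""
    use_code: str = ""


@dataclass(frozen=True)
class RawExclusivityRow:
    appl_no: str
    product_no: str
    exclusivity_code: str
    exclusivity_date: date


@dataclass(frozen=True)
class PatentAnnotation:
    """Curated per-patent metadata (dual-reviewer reading of the patent text).

    ``mentions_active`` records whether any claim mentions the active
    ingredient or its molecular structure; it is only meaningful when
    ``is_device`` is true (non-device patents cover the active ingredient or
    formulation by construction and the flag is ignored downstream).
    """

    patent_no: str
    application_date: date
    priority_date: date
    is_device: bool
    mentions_active: bool
    title: str = ""

    def __post_init__(self) -> None:
        if self.priority_date > self.application_date:
            raise ValueError(
                f"patent {self.patent_no}: priority_date {self.priority_date} "
                f"is after application_date {self.application_date}"
            )


@dataclass(frozen=True)
class ProductMetadataRow:
    """Product-level curation: class, presentation, line key, originator status."""

    appl_no: str
    product_no: str
    brand_family: str
    insulin_class: str
    presentation: str
    originator_or_followon: str
    manufacturer: str


# ---------------------------------------------------------------------------
# delimited-file primitives


def _read_delimited(
    path: str | Path, expected_columns: Sequence[str], dialect: Dialect
) -> list[tuple[int, list[str]]]:
    path = Path(path)
    with path.open("r", encoding=dialect.encoding, newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise OrangeBookParseError(f"{path}: empty file, header row required")
        header = [h.strip() for h in header]
        if header != list(expected_columns):
            raise OrangeBookParseError(
                f"{path}: unexpected header {header!r}, expected {list(expected_columns)!r}"
            )
        rows: list[tuple[int, list[str]]] = []
        for lineno, fields in enumerate(reader, start=2):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue  # blank line
            if len(fields) != len(expected_columns):
                raise OrangeBookParseError(
                    f"{path}: line {lineno}: expected {len(expected_columns)} "
                    f"fields, found {len(fields)}"
                )
            rows.append((lineno, [f.strip() for f in fields]))
    return rows


def _parse_date_field(value: str, path: Path, lineno: int, column: str) -> date:
    try:
        return parse_date(value)
    except DateParseError as exc:
        raise OrangeBookParseError(
            f"{path}: line {lineno}: column {column}: {exc}"
        ) from None


# ---------------------------------------------------------------------------
# readers


def read_products(
    path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> list[RawProductRow]:
    """Read a products.txt-style file. Ingredients are split on the dialect's
    ingredient separator (``;``)."""
    path = Path(path)
    out: list[RawProductRow] = []
    seen: set[tuple[str, str]] = set()
    for lineno, f in _read_delimited(path, PRODUCT_COLUMNS, dialect):
        appl_no, product_no, trade_name, ingredient, df_route, approval, applicant = f
        if not appl_no:
            raise OrangeBookParseError(f"{path}: line {lineno}: empty APPL_NO")
        key = (appl_no, product_no)
        if key in seen:
            raise OrangeBookParseError(
                f"{path}: line {lineno}: duplicate (APPL_NO, PRODUCT_NO) {key}"
            )
        seen.add(key)
        ingredients = tuple(
            part.strip()
            for part in ingredient.split(dialect.ingredient_separator)
            if part.strip()
        )
        out.append(
            RawProductRow(
                appl_no=appl_no,
                product_no=product_no,
                trade_name=trade_name,
                active_ingredients=ingredients,
                dosage_form_route=df_route,
                approval_date=_parse_date_field(approval, path, lineno, "APPROVAL_DATE"),
                applicant=applicant,
            )
        )
    return out


def read_patents(
    path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> list[RawPatentRow]:
    """Read a patent.txt-style file.

    Duplicate (APPL_NO, PRODUCT_NO, PATENT_NO) rows are legitimate in the wild
    and are retained; a log entry flags them for the audit trail.
    """
    path = Path(path)
    out: list[RawPatentRow] = []
    seen: set[tuple[str, str, str]] = set()
    for lineno, f in _read_delimited(path, PATENT_COLUMNS, dialect):
        appl_no, product_no, patent_no, expire, submission, subst, prod, use = f
        if not patent_no:
            raise OrangeBookParseError(f"{path}: line {lineno}: empty PATENT_NO")
        key = (appl_no, product_no, patent_no)
        if key in seen:
            logger.warning("%s: line %d: duplicate patent row %s retained", path, lineno, key)
        seen.add(key)
        out.append(
            RawPatentRow(
                appl_no=appl_no,
                product_no=product_no,
                patent_no=patent_no,
                patent_expire_date=_parse_date_field(
                    expire, path, lineno, "PATENT_EXPIRE_DATE"
                ),
                submission_date=(
                    _parse_date_field(submission, path, lineno, "SUBMISSION_DATE")
                    if submission
                    else None
                ),
                drug_substance_flag=subst,
                drug_product_flag=prod,
                use_code=use,
            )
        )
    return out


def read_exclusivities(
    path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> list[RawExclusivityRow]:
    """Read an exclusivity.txt-style file. Unknown category codes are retained
    verbatim (they map to the ``other`` category downstream) with a warning."""
    path = Path(path)
    out: list[RawExclusivityRow] = []
    for lineno, f in _read_delimited(path, EXCLUSIVITY_COLUMNS, dialect):
        appl_no, product_no, code, expiry = f
        if not code:
            raise OrangeBookParseError(f"{path}: line {lineno}: empty EXCLUSIVITY_CODE")
        prefix = code.split("-", 1)[0]
        if code not in KNOWN_EXCLUSIVITY_PREFIXES and prefix not in KNOWN_EXCLUSIVITY_PREFIXES:
            logger.warning(
                "%s: line %d: unknown exclusivity code %r retained (will map to 'other')",
                path,
                lineno,
                code,
            )
        out.append(
            RawExclusivityRow(
                appl_no=appl_no,
                product_no=product_no,
                exclusivity_code=code,
                exclusivity_date=_parse_date_field(
                    expiry, path, lineno, "EXCLUSIVITY_DATE"
                ),
            )
        )
    return out


_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(value: str, path: Path, lineno: int, column: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise OrangeBookParseError(
        f"{path}: line {lineno}: column {column}: boolean must be one of "
        f"true/false/1/0/yes/no, got {value!r}"
    )


ANNOTATION_COLUMNS = (
    "patent_no",
    "application_date",
    "priority_date",
    "is_device",
    "mentions_active",
)


def read_annotations(path: str | Path) -> list[PatentAnnotation]:
    """Read the curated patent-annotation CSV.

    A missing priority date falls back to the application date (with a
    warning); a priority date after the application date is an error.
    """
    path = Path(path)
    out: list[PatentAnnotation] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(ANNOTATION_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise OrangeBookParseError(
                f"{path}: annotation CSV missing columns {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            application = _parse_date_field(
                row["application_date"], path, lineno, "application_date"
            )
            prio_raw = (row.get("priority_date") or "").strip()
            if prio_raw:
                priority = _parse_date_field(prio_raw, path, lineno, "priority_date")
            else:
                logger.warning(
                    "%s: line %d: patent %s has no priority_date; using application_date",
                    path,
                    lineno,
                    row["patent_no"],
                )
                priority = application
            try:
                ann = PatentAnnotation(
                    patent_no=row["patent_no"].strip(),
                    application_date=application,
                    priority_date=priority,
                    is_device=_parse_bool(row["is_device"], path, lineno, "is_device"),
                    mentions_active=_parse_bool(
                        row["mentions_active"], path, lineno, "mentions_active"
                    ),
                    title=(row.get("title") or "").strip(),
                )
            except ValueError as exc:
                raise OrangeBookParseError(f"{path}: line {lineno}: {exc}") from None
            out.append(ann)
    return out


METADATA_COLUMNS = (
    "appl_no",
    "product_no",
    "brand_family",
    "insulin_class",
    "presentation",
    "originator_or_followon",
    "manufacturer",
)


def read_product_metadata(path: str | Path) -> list[ProductMetadataRow]:
    """Read the product-level curation table (CSV)."""
    path = Path(path)
    out: list[ProductMetadataRow] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(METADATA_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise OrangeBookParseError(
                f"{path}: metadata CSV missing columns {sorted(missing)}"
            )
        for row in reader:
            out.append(
                ProductMetadataRow(**{c: row[c].strip() for c in METADATA_COLUMNS})
            )
    return out


# ---------------------------------------------------------------------------
# writers (canonical dialect: '~' delimiter, ISO dates)


def write_products(
    rows: Iterable[RawProductRow], path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> None:
    path = Path(path)
    with path.open("w", encoding=dialect.encoding, newline="") as fh:
        fh.write(dialect.delimiter.join(PRODUCT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                dialect.delimiter.join(
                    [
                        r.appl_no,
                        r.product_no,
                        r.trade_name,
                        dialect.ingredient_separator.join(r.active_ingredients),
                        r.dosage_form_route,
                        format_date(r.approval_date),
                        r.applicant,
                    ]
                )
                + "\n"
            )


def write_patents(
    rows: Iterable[RawPatentRow], path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> None:
    path = Path(path)
    with path.open("w", encoding=dialect.encoding, newline="") as fh:
        fh.write(dialect.delimiter.join(PATENT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                dialect.delimiter.join(
                    [
                        r.appl_no,
                        r.product_no,
                        r.patent_no,
                        format_date(r.patent_expire_date),
                        format_date(r.submission_date) if r.submission_date else "",
                        r.drug_substance_flag,
                        r.drug_product_flag,
                        r.use_code,
                    ]
                )
                + "\n"
            )


def write_exclusivities(
    rows: Iterable[RawExclusivityRow],
    path: str | Path,
    dialect: Dialect = DEFAULT_DIALECT,
) -> None:
    path = Path(path)
    with path.open("w", encoding=dialect.encoding, newline="") as fh:
        fh.write(dialect.delimiter.join(EXCLUSIVITY_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                dialect.delimiter.join(
                    [
                        r.appl_no,
                        r.product_no,
                        r.exclusivity_code,
                        format_date(r.exclusivity_date),
                    ]
                )
                + "\n"
            )


def write_annotations(rows: Iterable[PatentAnnotation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(ANNOTATION_COLUMNS) + ["title"])
        for r in rows:
            writer.writerow(
                [
                    r.patent_no,
                    format_date(r.application_date),
                    format_date(r.priority_date),
                    "true" if r.is_device else "false",
                    "true" if r.mentions_active else "false",
                    r.title,
                ]
            )


def write_product_metadata(rows: Iterable[ProductMetadataRow], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(METADATA_COLUMNS)
        for r in rows:
            writer.writerow([getattr(r, c) for c in METADATA_COLUMNS])


# ---------------------------------------------------------------------------
# report serialization


def _round_value(key: str, value):
    """Reporting precision: durations (years) to 1 decimal, percentages to whole
    numbers, both half-away-from-zero; counts untouched."""
    if value is None or isinstance(value, bool):
        return value
    if isinstance(value, float):
        if key.startswith("pct_") or key.endswith("_pct"):
            return int(
                Decimal(repr(value)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
            )
        return float(
            Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
        )
    return value


def _flatten(obj, prefix: str = "") -> dict[str, object]:
    flat: dict[str, object] = {}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        for k, v in obj.items():
            flat.update(_flatten(v, f"{prefix}{k}." if prefix else f"{k}."))
        return flat
    if isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            flat.update(_flatten(v, f"{prefix}{i}."))
        return flat
    flat[prefix.rstrip(".")] = obj
    return flat


def export_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize a study report to JSON or CSV at the stated reporting precision
    (durations 1 decimal, percentages whole numbers). Round-trip safe: re-reading
    yields identical values at that precision."""
    path = Path(path)
    if hasattr(report, "to_dict"):
        payload = report.to_dict()
    elif dataclasses.is_dataclass(report) and not isinstance(report, type):
        payload = dataclasses.asdict(report)
    else:
        payload = dict(report)
    flat = {k: _round_value(k.rsplit(".", 1)[-1], v) for k, v in _flatten(payload).items()}
    if format == "json":
        with path.open("w", encoding="utf-8") as fh:
            json.dump(flat, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["key", "value"])
            for k in sorted(flat):
                v = flat[k]
                writer.writerow([k, "" if v is None else v])
    else:
        raise ValueError(f"unsupported report format {format!r} (csv or json)")


def read_report(path: str | Path) -> dict[str, object]:
    """Read back an exported report (inverse of :func:`export_report`)."""
    path = Path(path)
    if path.suffix == ".json":
        with path.open("r", encoding="utf-8") as fh:
            return json.load(fh)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        out: dict[str, object] = {}
        for row in reader:
            raw = row["value"]
            if raw == "":
                out[row["key"]] = None
                continue
            try:
                num = float(raw)
                out[row["key"]] = int(num) if num.is_integer() and "." not in raw else num
            except ValueError:
                out[row["key"]] = raw
        return out
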