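"""Synthetic Orange Book-shaped cohorts with recorded ground truth.

The generator emulates the structure of the studied market: insulin lines
approved across 1986–2019, 1–5 presentations per line, a device fraction and
a patents-per-product rate that both rise across the study terciles, 20-year
patent terms from the priority date, a small exclusivity menu (new chemical
entity 5 years on a line's first product, new-product 3 years on later ones,
occasional post-approval pediatric grants), and rare follow-on entry after a
long delay. Counts are Poisson and filing-day offsets are discretized
normals; both are the generator's own choices — the emulated study reports no
distributions.

Ground truth (per-product last expiry and duration, line spans, device added
protection, follow-on entry dates) is computed during generation by direct
day arithmetic over the emitted records, a code path fully independent of the
protection module, so round-tripping the files through the pipeline is a
genuine end-to-end oracle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from . import io as ob_io
from .dates import DAYS_PER_YEAR
from .io import (
    PatentAnnotation,
    ProductMetadataRow,
    RawExclusivityRow,
    RawPatentRow,
    RawProductRow,
)

logger = logging.getLogger(__name__)

_CLASSES = (
    "rapid",
    "short",
    "intermediate",
    "long",
    "mixture_long_incretin",
    "mixture_intermediate_rapid",
    "mixture_intermediate_short",
)
_MANUFACTURERS = ("ALFA BIO", "BETA THERAPEUTICS", "GAMMA PHARMA", "DELTA LABS", "EPSILON RX")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings. Defaults mirror the studied cohort's conditions."""

    n_lines: int = 25
    products_per_line: tuple[int, int] = (1, 5)  # inclusive bounds
    approval_year_range: tuple[int, int] = (1986, 2019)
    #: fraction of products that are drug-device combinations, per study tercile
    device_fraction_by_era: tuple[float, float, float] = (0.15, 0.45, 0.8)
    #: Poisson mean of patents per product, per study tercile
    patents_per_product_by_era: tuple[float, float, float] = (0.5, 4.0, 15.0)
    era_trend: bool = True  # False ⇒ middle-era rate everywhere
    patent_term_years: float = 20.0
    #: mean/sd (days) of the application-date offset from approval; negative
    #: mass = pre-approval filings
    filing_offset_mean_days: float = -1500.0
    filing_offset_sd_days: float = 1200.0
    #: max days the priority date precedes the application date (family history)
    priority_lag_max_days: int = 1095
    #: fraction of a device product's patents that are device patents
    device_patent_fraction: float = 0.63
    #: probability a device patent's claims never mention the active ingredient
    no_mention_probability: float = 0.85
    #: probability a patent is also listed on sibling products of the line
    share_within_line_probability: float = 0.3
    #: exclusivity terms in years
    nce_term_years: float = 5.0
    new_product_term_years: float = 3.0
    new_product_probability: float = 0.5
    pediatric_probability: float = 0.15
    pediatric_delay_days: tuple[int, int] = (365, 3650)
    #: probability an originator line draws a follow-on, and entry-delay bounds
    followon_probability: float = 0.12
    followon_delay_days: tuple[int, int] = (3650, 7300)
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 0:
            raise ValueError("n_lines must be >= 0")
        lo, hi = self.products_per_line
        if not (1 <= lo <= hi):
            raise ValueError("products_per_line bounds must satisfy 1 <= min <= max")
        if self.approval_year_range[0] > self.approval_year_range[1]:
            raise ValueError("approval_year_range must be ordered")
        if self.patent_term_years <= 0 or self.nce_term_years <= 0 or self.new_product_term_years <= 0:
            raise ValueError("term years must be > 0")
        for name in (
            "device_patent_fraction",
            "no_mention_probability",
            "share_within_line_probability",
            "new_product_probability",
            "pediatric_probability",
            "followon_probability",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.priority_lag_max_days < 0:
            raise ValueError("priority_lag_max_days must be >= 0")
        if any(r < 0 for r in self.patents_per_product_by_era):
            raise ValueError("patent rates must be >= 0")
        if any(not (0 <= f <= 1) for f in self.device_fraction_by_era):
            raise ValueError("device fractions must be in [0, 1]")


@dataclass
class GroundTruth:
    """Oracle values recomputable from the generated files by the pipeline."""

    #: (appl_no, product_no) → {approval, last_expiry, duration_years,
    #: device_added_years, no_mention_added_years}
    per_product: dict = field(default_factory=dict)
    #: line_id → {first_approval, last_expiry, duration_years, first_filing}
    per_line: dict = field(default_factory=dict)
    #: originator line_id → first follow-on approval date
    followon_entries: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def enc(o):
            if isinstance(o, date):
                return o.isoformat()
            raise TypeError(type(o))

        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True, default=enc)
            fh.write("\n")


@dataclass
class SyntheticCohortFiles:
    products: Path
    patents: Path
    exclusivities: Path
    annotations: Path
    metadata: Path
    ground_truth: GroundTruth


def _era_index(year: int, year_range: tuple[int, int]) -> int:
    lo, hi = year_range
    pos = (year - lo) / max(hi - lo, 1)
    return min(2, int(pos * 3))


def _term_days(years: float) -> int:
    return round(years * DAYS_PER_YEAR)


def _rand_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Uniform integer in [lo, hi); degenerate ranges return lo."""
    return lo if hi <= lo else int(rng.integers(lo, hi))


def generate(config: SyntheticConfig, outdir: str | Path) -> SyntheticCohortFiles:
    """Generate a cohort under *config* into *outdir*.

    Writes ``products.txt``, ``patent.txt``, ``exclusivity.txt``,
    ``annotations.csv``, ``metadata.csv`` (all in the canonical dialect —
    byte-identical across runs at a fixed seed) and returns the paths with the
    internally computed :class:`GroundTruth`.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    products: list[RawProductRow] = []
    patents: list[RawPatentRow] = []
    exclusivities: list[RawExclusivityRow] = []
    annotations: list[PatentAnnotation] = []
    metadata: list[ProductMetadataRow] = []
    truth = GroundTruth()

    year_lo, year_hi = config.approval_year_range
    window_end = date(year_hi, 12, 31)
    patent_counter = 0

    for li in range(1, config.n_lines + 1):
        appl_no = f"N5{li:05d}"
        line_id = f"SYNLINE-{li:03d}"
        ingredient = f"INSULIN SYN{li:03d}"
        manufacturer = _MANUFACTURERS[int(rng.integers(len(_MANUFACTURERS)))]
        insulin_class = _CLASSES[li % len(_CLASSES)]
        n_products = int(rng.integers(config.products_per_line[0], config.products_per_line[1] + 1))

        first_year = int(rng.integers(year_lo, year_hi + 1))
        first_approval = date(first_year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        if first_approval > window_end:
            first_approval = window_end

        approvals = [first_approval]
        for _ in range(n_products - 1):
            gap = int(rng.integers(180, 8 * 365))
            nxt = approvals[-1] + timedelta(days=gap)
            approvals.append(min(nxt, window_end))

        # per-product containers for truth bookkeeping
        prod_expiries: dict[str, list[date]] = {}
        prod_device_exp: dict[str, list[date]] = {}
        prod_non_device_exp: dict[str, list[date]] = {}
        prod_no_mention_exp: dict[str, list[date]] = {}
        prod_other_patent_exp: dict[str, list[date]] = {}
        line_filings: list[date] = []
        product_nos: list[str] = []

        line_patents: list[tuple[str, date, date, date, bool, bool]] = []
        # (patent_no, application, priority, expiry, is_device, mentions)

        for pi, approval in enumerate(approvals, start=1):
            product_no = f"{pi:03d}"
            product_nos.append(product_no)
            era = _era_index(approval.year, config.approval_year_range)
            device_frac = (
                config.device_fraction_by_era[era]
                if config.era_trend
                else config.device_fraction_by_era[1]
            )
            is_device = bool(rng.random() < device_frac)
            presentation = "single_use_device" if is_device else "vial"

            products.append(
                RawProductRow(
                    appl_no=appl_no,
                    product_no=product_no,
                    trade_name=line_id,
                    active_ingredients=(ingredient,),
                    dosage_form_route="INJECTABLE;SUBCUTANEOUS",
                    approval_date=approval,
                    applicant=manufacturer,
                )
            )
            metadata.append(
                ProductMetadataRow(
                    appl_no=appl_no,
                    product_no=product_no,
                    brand_family=line_id,
                    insulin_class=insulin_class,
                    presentation=presentation,
                    originator_or_followon="originator",
                    manufacturer=manufacturer,
                )
            )
            prod_expiries[product_no] = []
            prod_device_exp[product_no] = []
            prod_non_device_exp[product_no] = []
            prod_no_mention_exp[product_no] = []
            prod_other_patent_exp[product_no] = []

            rate = (
                config.patents_per_product_by_era[era]
                if config.era_trend
                else config.patents_per_product_by_era[1]
            )
            n_patents = int(rng.poisson(rate))
            for _ in range(n_patents):
                patent_counter += 1
                patent_no = f"SYN{patent_counter:07d}"
                offset = int(
                    round(rng.normal(config.filing_offset_mean_days, config.filing_offset_sd_days))
                )
                application = approval + timedelta(days=offset)
                priority = application - timedelta(days=_rand_int(rng, 0, config.priority_lag_max_days))
                expiry = priority + timedelta(days=_term_days(config.patent_term_years))
                patent_is_device = is_device and bool(rng.random() < config.device_patent_fraction)
                mentions = (
                    bool(rng.random() >= config.no_mention_probability)
                    if patent_is_device
                    else True
                )
                first_listing = max(application, approval) if offset > 0 else application
                patents.append(
                    RawPatentRow(
                        appl_no=appl_no,
                        product_no=product_no,
                        patent_no=patent_no,
                        patent_expire_date=expiry,
                        submission_date=first_listing,
                        drug_substance_flag="" if patent_is_device else "Y",
                        drug_product_flag="Y",
                        use_code="",
                    )
                )
                annotations.append(
                    PatentAnnotation(
                        patent_no=patent_no,
                        application_date=application,
                        priority_date=priority,
                        is_device=patent_is_device,
                        mentions_active=mentions if patent_is_device else True,
                        title=f"Synthetic patent {patent_counter}",
                    )
                )
                line_patents.append(
                    (patent_no, application, priority, expiry, patent_is_device, mentions)
                )
                line_filings.append(priority)
                prod_expiries[product_no].append(expiry)
                if patent_is_device:
                    prod_device_exp[product_no].append(expiry)
                    if not mentions:
                        prod_no_mention_exp[product_no].append(expiry)
                    else:
                        prod_other_patent_exp[product_no].append(expiry)
                else:
                    prod_non_device_exp[product_no].append(expiry)
                    prod_other_patent_exp[product_no].append(expiry)

                # optionally list the same patent on sibling products
                if n_products > 1 and rng.random() < config.share_within_line_probability:
                    for sib_no, sib_approval in zip(product_nos[:-1], approvals):
                        if sib_no == product_no:
                            continue
                        patents.append(
                            RawPatentRow(
                                appl_no=appl_no,
                                product_no=sib_no,
                                patent_no=patent_no,
                                patent_expire_date=expiry,
                                submission_date=max(first_listing, sib_approval)
                                if first_listing > sib_approval
                                else first_listing,
                                drug_substance_flag="" if patent_is_device else "Y",
                                drug_product_flag="Y",
                                use_code="",
                            )
                        )
                        prod_expiries[sib_no].append(expiry)
                        if patent_is_device:
                            prod_device_exp[sib_no].append(expiry)
                            if not mentions:
                                prod_no_mention_exp[sib_no].append(expiry)
                            else:
                                prod_other_patent_exp[sib_no].append(expiry)
                        else:
                            prod_non_device_exp[sib_no].append(expiry)
                            prod_other_patent_exp[sib_no].append(expiry)

            # exclusivities
            if pi == 1:
                expiry = approval + timedelta(days=_term_days(config.nce_term_years))
                exclusivities.append(
                    RawExclusivityRow(appl_no, product_no, "NCE", expiry)
                )
                prod_expiries[product_no].append(expiry)
            elif rng.random() < config.new_product_probability:
                expiry = approval + timedelta(days=_term_days(config.new_product_term_years))
                exclusivities.append(
                    RawExclusivityRow(appl_no, product_no, "NP", expiry)
                )
                prod_expiries[product_no].append(expiry)
            if rng.random() < config.pediatric_probability:
                delay = _rand_int(rng, *config.pediatric_delay_days)
                expiry = approval + timedelta(
                    days=delay + _term_days(config.new_product_term_years)
                )
                exclusivities.append(
                    RawExclusivityRow(appl_no, product_no, "PED", expiry)
                )
                prod_expiries[product_no].append(expiry)

        # ---- truth: per product ------------------------------------------
        for product_no, approval in zip(product_nos, approvals):
            exp = prod_expiries[product_no]
            last = max(exp) if exp else None
            dev = prod_device_exp[product_no]
            nd = prod_non_device_exp[product_no]
            nm = prod_no_mention_exp[product_no]
            other = prod_other_patent_exp[product_no]
            truth.per_product[f"{appl_no}/{product_no}"] = {
                "approval": approval,
                "last_expiry": last,
                "duration_years": ((last - approval).days / 365.25) if last else None,
                "device_added_years": (
                    (max(dev) - max(nd)).days / 365.25 if dev and nd else None
                ),
                "no_mention_added_years": (
                    (max(nm) - max(other)).days / 365.25 if nm and other else None
                ),
            }

        # ---- truth: line span --------------------------------------------
        all_exp = [d for exps in prod_expiries.values() for d in exps]
        line_last = max(all_exp) if all_exp else None
        truth.per_line[line_id] = {
            "first_approval": approvals[0],
            "last_expiry": line_last,
            "duration_years": (
                (line_last - approvals[0]).days / 365.25 if line_last else None
            ),
            "first_filing": min(line_filings) if line_filings else None,
        }

        # ---- follow-on ------------------------------------------------------
        if rng.random() < config.followon_probability:
            delay = _rand_int(rng, *config.followon_delay_days)
            fo_approval = min(approvals[0] + timedelta(days=delay), window_end)
            fo_appl = f"N6{li:05d}"
            fo_manufacturer = _MANUFACTURERS[
                (_MANUFACTURERS.index(manufacturer) + 1) % len(_MANUFACTURERS)
            ]
            fo_line = f"SYNFO-{li:03d}"
            products.append(
                RawProductRow(
                    appl_no=fo_appl,
                    product_no="001",
                    trade_name=fo_line,
                    active_ingredients=(ingredient,),
                    dosage_form_route="INJECTABLE;SUBCUTANEOUS",
                    approval_date=fo_approval,
                    applicant=fo_manufacturer,
                )
            )
            metadata.append(
                ProductMetadataRow(
                    appl_no=fo_appl,
                    product_no="001",
                    brand_family=fo_line,
                    insulin_class=insulin_class,
                    presentation="vial",
                    originator_or_followon="followon",
                    manufacturer=fo_manufacturer,
                )
            )
            truth.followon_entries[line_id] = fo_approval

    paths = SyntheticCohortFiles(
        products=outdir / "products.txt",
        patents=outdir / "patent.txt",
        exclusivities=outdir / "exclusivity.txt",
        annotations=outdir / "annotations.csv",
        metadata=outdir / "metadata.csv",
        ground_truth=truth,
    )
    ob_io.write_products(products, paths.products)
    ob_io.write_patents(patents, paths.patents)
    ob_io.write_exclusivities(exclusivities, paths.exclusivities)
    ob_io.write_annotations(annotations, paths.annotations)
    ob_io.write_product_metadata(metadata, paths.metadata)
    return paths


@dataclass
class RecoveryResult:
    passed: bool
    max_expiry_discrepancy_days: int
    max_duration_delta_years: float
    counts_match: bool
    n_products: int
    n_lines: int
    mismatches: list[str] = field(default_factory=list)


def parameter_recovery_check(
    config: SyntheticConfig, outdir: str | Path
) -> RecoveryResult:
    """Generate a cohort, run the full pipeline on the files, and compare the
    pipeline's durations with the generator's ground truth.

    The date algebra is deterministic, so the check demands exact agreement:
    0-day discrepancy on every last-expiry date and identical cohort counts.
    """
    from .cohort import CohortConfig, build_cohort
    from .protection import FULL_SCOPE, line_protection, product_protection
    from .classify import link_and_classify

    files = generate(config, outdir)
    truth = files.ground_truth

    products = ob_io.read_products(files.products)
    raw_patents = ob_io.read_patents(files.patents)
    raw_exclusivities = ob_io.read_exclusivities(files.exclusivities)
    annotations = ob_io.read_annotations(files.annotations)
    metadata = ob_io.read_product_metadata(files.metadata)

    year_lo, year_hi = config.approval_year_range
    cohort = build_cohort(
        products,
        CohortConfig(window_start=date(year_lo, 1, 1), window_end=date(year_hi, 12, 31)),
        metadata,
    )
    patents, exclusivities = link_and_classify(
        raw_patents, raw_exclusivities, annotations, cohort
    )

    mismatches: list[str] = []
    max_days = 0
    max_delta = 0.0

    counts_match = (
        len(cohort.originator_lines) == config.n_lines
        and len(cohort.originator_products) == sum(
            1 for k in truth.per_product
        )
        and len(cohort.followon_lines) == len(truth.followon_entries)
    )
    if not counts_match:
        mismatches.append(
            f"counts: {len(cohort.originator_lines)} lines vs {config.n_lines} configured"
        )

    for p in cohort.originator_products:
        t = truth.per_product[f"{p.appl_no}/{p.product_no}"]
        pp = product_protection(p, patents, exclusivities, FULL_SCOPE)
        if pp.last_expiry != t["last_expiry"]:
            days = (
                abs((pp.last_expiry - t["last_expiry"]).days)
                if pp.last_expiry and t["last_expiry"]
                else 10**6
            )
            max_days = max(max_days, days)
            mismatches.append(
                f"{p.appl_no}/{p.product_no}: expiry {pp.last_expiry} vs truth {t['last_expiry']}"
            )
        if pp.duration_years is not None and t["duration_years"] is not None:
            max_delta = max(max_delta, abs(pp.duration_years - t["duration_years"]))
        elif (pp.duration_years is None) != (t["duration_years"] is None):
            mismatches.append(f"{p.appl_no}/{p.product_no}: duration None mismatch")

    for line in cohort.originator_lines:
        t = truth.per_line[line.line_id]
        span = line_protection(line, patents, exclusivities, FULL_SCOPE)
        for attr, key in (
            ("first_approval", "first_approval"),
            ("last_expiry", "last_expiry"),
            ("first_filing", "first_filing"),
        ):
            if getattr(span, attr) != t[key]:
                mismatches.append(
                    f"line {line.line_id}: {attr} {getattr(span, attr)} vs truth {t[key]}"
                )
                if getattr(span, attr) and t[key]:
                    max_days = max(max_days, abs((getattr(span, attr) - t[key]).days))

    return RecoveryResult(
        passed=not mismatches,
        max_expiry_discrepancy_days=max_days,
        max_duration_delta_years=max_delta,
        counts_match=counts_match,
        n_products=len(cohort.originator_products),
        n_lines=len(cohort.originator_lines),
        mismatches=mismatches,
    )
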