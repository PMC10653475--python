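"""Shared fixtures: the packaged cohort tables and a synthetic pipeline run."""

from __future__ import annotations

from datetime import date
from types import SimpleNamespace

import pytest

from obmex import io as ob_io
from obmex.classify import (
    DeviceStatus,
    ExclusivityCategory,
    ExclusivityTiming,
    FilingTiming,
    ListingTiming,
    Patent,
    PriorityTiming,
    Exclusivity,
    link_and_classify,
)
from obmex.cohort import CohortConfig, InsulinClass, Presentation, Product, build_cohort
from obmex.fixtures import fixture_cohort
from obmex.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def table_cohort():
    """Cohort built from the packaged published-table fixture."""
    return fixture_cohort()


def make_product(
    appl_no: str = "N100001",
    product_no: str = "001",
    approval: date = date(2010, 1, 15),
    is_device: bool = False,
    brand: str = "TESTBRAND",
    manufacturer: str = "ACME",
    ingredients: tuple[str, ...] = ("INSULIN TESTMER",),
    insulin_class: InsulinClass = InsulinClass.LONG,
) -> Product:
    return Product(
        appl_no=appl_no,
        product_no=product_no,
        trade_name=brand,
        brand_family=brand,
        active_ingredients=ingredients,
        approval_date=approval,
        manufacturer=manufacturer,
        insulin_class=insulin_class,
        presentation=Presentation.SINGLE_USE_DEVICE if is_device else Presentation.VIAL,
        is_drug_device=is_device,
    )


def make_patent(
    product: Product,
    expiry: date,
    patent_no: str = "US0000001",
    device_status: DeviceStatus = DeviceStatus.NON_DEVICE,
    application: date | None = None,
    priority: date | None = None,
    listing: ListingTiming = ListingTiming.LISTED_AT_APPROVAL,
    filing: FilingTiming = FilingTiming.PRE_APPROVAL_FILED,
) -> Patent:
    application = application or product.approval_date
    priority = priority or application
    return Patent(
        patent_no=patent_no,
        appl_no=product.appl_no,
        product_no=product.product_no,
        expiry=expiry,
        application_date=application,
        priority_date=priority,
        first_listing=application,
        device_status=device_status,
        filing_timing=filing,
        listing_timing=listing,
        priority_timing=PriorityTiming.PRIORITY_BEFORE_APPROVAL,
    )


def make_exclusivity(
    product: Product,
    expiry: date,
    code: str = "NCE",
    category: ExclusivityCategory = ExclusivityCategory.NEW_CHEMICAL_ENTITY,
    timing: ExclusivityTiming = ExclusivityTiming.AT_APPROVAL,
) -> Exclusivity:
    return Exclusivity(
        code=code,
        category=category,
        appl_no=product.appl_no,
        product_no=product.product_no,
        expiry=expiry,
        timing=timing,
    )


def run_pipeline(files):
    """Read generated files and run cohort building + classification."""
    products = ob_io.read_products(files.products)
    metadata = ob_io.read_product_metadata(files.metadata)
    cohort = build_cohort(products, CohortConfig(), metadata)
    patents, exclusivities = link_and_classify(
        ob_io.read_patents(files.patents),
        ob_io.read_exclusivities(files.exclusivities),
        ob_io.read_annotations(files.annotations),
        cohort,
    )
    return SimpleNamespace(
        cohort=cohort,
        patents=patents,
        exclusivities=exclusivities,
        truth=files.ground_truth,
        files=files,
    )


@pytest.fixture(scope="session")
def synthetic_run(tmp_path_factory):
    """A mid-sized synthetic cohort pushed through the full pipeline."""
    outdir = tmp_path_factory.mktemp("syncohort")
    files = generate(SyntheticConfig(n_lines=40, seed=11), outdir)
    return run_pipeline(files)
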