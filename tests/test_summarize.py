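"""Descriptive statistics and study-report assembly."""

from __future__ import annotations

import random
from datetime import date

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obmex.classify import FilingTiming
from obmex.followon import match_followons
from obmex.summarize import DurationSummary, cohort_report, era_summary, median_iqr

from conftest import make_patent, make_product


def _quartiles_bruteforce(values):
    """Independent sort-based implementation of interpolated quartiles."""
    xs = sorted(values)
    n = len(xs)

    def at(q):
        pos = q * (n - 1)
        lo = int(pos)
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return xs[lo] + frac * (xs[hi] - xs[lo])

    return at(0.5), at(0.25), at(0.75)


@pytest.mark.parametrize(
    "values, expected",
    [
        ([5], (5, 5, 5)),
        ([1, 2, 3, 4], (2.5, 1.75, 3.25)),
        ([1, 1, 10], (1, 1, 5.5)),
    ],
)
def test_median_iqr_hand_computed(values, expected):
    assert median_iqr(values) == pytest.approx(expected)


def test_median_iqr_empty_rejected():
    with pytest.raises(ValueError):
        median_iqr([])


@settings(max_examples=150, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=500))
def test_median_iqr_matches_bruteforce(values):
    m, q1, q3 = median_iqr(values)
    bm, bq1, bq3 = _quartiles_bruteforce(values)
    assert m == pytest.approx(bm)
    assert q1 == pytest.approx(bq1)
    assert q3 == pytest.approx(bq3)
    assert min(values) <= q1 <= m <= q3 <= max(values)


def test_discrete_quartile_variant_available():
    # "lower" picks order statistics without interpolation
    m, q1, q3 = median_iqr([1, 2, 3, 4], method="lower")
    assert (m, q1, q3) == (2, 1, 3)


def test_era_tercile_boundaries():
    p_first = make_product(appl_no="N1", approval=date(1996, 12, 31))
    p_second = make_product(appl_no="N2", approval=date(1997, 1, 1))
    p_third = make_product(appl_no="N3", approval=date(2008, 1, 1))
    pats = [make_patent(p_second, date(2015, 1, 1), f"US{i}") for i in range(3)]
    df = era_summary([p_first, p_second, p_third], pats, "terciles")
    assert list(df["era_start"]) == [1986, 1997, 2008]
    assert list(df["n_products"]) == [1, 1, 1]
    assert df.loc[0, "median_patents"] == 0  # 1996 approval → first era
    assert df.loc[1, "median_patents"] == 3
    assert df.loc[2, "median_patents"] == 0


def test_era_empty_bin_reported_without_median():
    p = make_product(approval=date(1990, 1, 1))
    df = era_summary([p], [], "terciles")
    row = df[df["era_start"] == 2008].iloc[0]
    assert row["n_products"] == 0
    assert pd.isna(row["median_patents"])


def test_era_five_year_bins_cover_window():
    df = era_summary([], [], "five_year")
    assert df.iloc[0][["era_start", "era_end"]].tolist() == [1986, 1990]
    assert df.iloc[-1][["era_start", "era_end"]].tolist() == [2016, 2019]
    assert len(df) == 7


def test_era_rejects_out_of_window_approval():
    p = make_product(approval=date(1975, 1, 1))
    with pytest.raises(ValueError, match="outside eras"):
        era_summary([p], [], "terciles")


def test_only_pre_approval_filings_counted():
    p = make_product(approval=date(2010, 1, 1))
    pre = make_patent(p, date(2020, 1, 1), "US1", filing=FilingTiming.PRE_APPROVAL_FILED)
    post = make_patent(p, date(2025, 1, 1), "US2", filing=FilingTiming.POST_APPROVAL_FILED)
    df = era_summary([p], [pre, post], "terciles")
    assert df.loc[2, "median_patents"] == 1


def test_fixture_report_counts(table_cohort):
    report = cohort_report(table_cohort, [], [], match_followons(table_cohort))
    assert report.counts["originator_products"] == 56
    assert report.counts["originator_lines"] == 25
    assert report.counts["drug_device_products"] == 33
    assert report.counts["followon_products"] == 5
    assert report.counts["followon_lines"] == 3
    assert report.percentages["pct_drug_device"] == pytest.approx(100 * 33 / 56)


def test_report_percentages_recomputable_from_counts(synthetic_run):
    report = cohort_report(
        synthetic_run.cohort,
        synthetic_run.patents,
        synthetic_run.exclusivities,
        match_followons(synthetic_run.cohort),
    )
    c = report.counts
    assert report.percentages["pct_drug_device"] == pytest.approx(
        100 * c["drug_device_products"] / c["originator_products"]
    )
    t = report.patent_tallies
    assert t["pre_approval_filed"] + t["post_approval_filed"] == t["patent_product_pairs"]
    assert t["device_pairs"] + t["non_device_pairs"] == t["patent_product_pairs"]
    x = report.exclusivity_tallies
    assert x["at_approval_total"] + x["post_approval_total"] == x["total"]


def test_report_medians_match_generator_truth(synthetic_run):
    report = cohort_report(
        synthetic_run.cohort,
        synthetic_run.patents,
        synthetic_run.exclusivities,
        match_followons(synthetic_run.cohort),
    )
    truth_durations = [
        rec["duration_years"]
        for rec in synthetic_run.truth.per_product.values()
        if rec["duration_years"] is not None
    ]
    expected = DurationSummary.of(truth_durations)
    got = report.durations["product_overall"]
    assert got.n == expected.n
    assert got.median == pytest.approx(expected.median)
    assert got.q1 == pytest.approx(expected.q1)
    assert got.q3 == pytest.approx(expected.q3)


def test_report_invariant_under_input_permutation(synthetic_run):
    matches = match_followons(synthetic_run.cohort)
    base = cohort_report(
        synthetic_run.cohort, synthetic_run.patents, synthetic_run.exclusivities, matches
    )
    pats = list(synthetic_run.patents)
    excl = list(synthetic_run.exclusivities)
    random.Random(5).shuffle(pats)
    random.Random(6).shuffle(excl)
    again = cohort_report(synthetic_run.cohort, pats, excl, matches)
    assert base.counts == again.counts
    assert base.patent_tallies == again.patent_tallies
    assert base.durations == again.durations
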