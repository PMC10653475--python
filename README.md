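# obmex — Orange Book market-exclusivity analytics

`obmex` quantifies how long FDA-approved drug products are expected to be
protected from competition by their Orange Book-listed patents and regulatory
exclusivities. It was built around the US insulin market (biosynthetic
insulins approved 1986–2019, before insulin moved to the biologics regime),
where most products are drug-device combinations and delivery-device patents
play an outsized role — but the machinery is generic over any Orange
Book-shaped cohort.

It is aimed at pharmaceutical-policy and regulatory-science researchers who
work with Orange Book data files (`products.txt`, `patent.txt`,
`exclusivity.txt`) plus a curated patent-annotation table (application and
priority dates, device flag, active-ingredient-mention flag).

## The quantities it computes

For a product approved at date $a$ with in-scope protections expiring at
dates $e_1,\dots,e_k$, the **duration of expected protection** is

$$ D = \frac{\max_i e_i - a}{365.25}\ \text{years}, $$

the time from approval to the *last-to-expire* patent or exclusivity. On top
of this last-to-expire algebra the package computes:

- **line-level spans** — from the first approval in an *insulin line*
  (products sharing brand family, active ingredients, and manufacturer) to the
  last expiry over all member products;
- **post-approval extension** — the gain of the overall duration over the
  duration from at-approval listings alone, attributing added protection to
  patents listed (or exclusivities granted) after approval;
- **device added protection** — last-to-expire device patent minus
  last-to-expire non-device patent (signed), and the analogous metric for
  device patents whose claims never mention the active ingredient;
- **follow-on sensitivity** — durations truncated at the approval of the
  first follow-on competitor (same active ingredients, different
  manufacturer, 505(b)(2) pathway);
- **descriptive summaries** — medians with interquartile ranges, per-class
  tables, and patent counts per product across study-period terciles
  (1986–1996, 1997–2007, 2008–2019) and 5-year bins.

Patents are classified per (patent, product) pair on two timing axes (USPTO
filing date vs approval; first Orange Book listing vs approval) and by device
status; exclusivities by category code (NCE, NP, NC, NPP, PED, I-*, …) and
grant timing. See `docs/methods.md` for conventions and edge cases.

## Worked example

The packaged fixture transcribes the published line-level cohort tables of
biosynthetic originator and follow-on insulins (1986–2019):

```python
>>> from obmex.fixtures import fixture_cohort
>>> from obmex.followon import match_followons, earliest_followon_by_line
>>> cohort = fixture_cohort()
>>> len(cohort.originator_products), len(cohort.originator_lines)
(56, 25)
>>> sum(p.is_drug_device for p in cohort.originator_products)
33
>>> first = earliest_followon_by_line(match_followons(cohort))
>>> first["Lantus"]
datetime.date(2015, 12, 16)
```

56 originator products across 25 insulin lines, 33 of them (59%) drug-device
combinations, and the first follow-on to the Lantus (insulin glargine) line —
Basaglar — approved 2015-12-16, 15.7 years after Lantus itself.

The same pipeline runs from the shell on any Orange Book-shaped inputs; a
synthetic cohort with recorded ground truth exercises every stage:

```bash
obmex simulate --out sim --seed 42
obmex report --config cfg.json --format json   # cfg.json points at sim/
obmex reproduce-tables --out checks            # recompute the fixture counts
```

`obmex simulate` emulates the studied market: rising device fractions and
patents-per-product across eras, 20-year patent terms from the priority date,
a 5-year new-chemical-entity / 3-year new-product exclusivity menu, and rare
delayed follow-on entry. Its ground truth is computed by date arithmetic
independent of the analysis code, so the pipeline can be checked against it
exactly (0-day discrepancy).

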