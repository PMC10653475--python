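# Methods

## Problem and data model

The package measures expected protection from competition for FDA-approved
drug products, built around the 1986–2019 biosynthetic-insulin cohort. The
unit of analysis is the *product*: one marketed presentation (vial, pen,
inhaler cartridge, infusion bag) under a New Drug Application (NDA). Products
sharing a brand family, normalized active-ingredient set, and manufacturer
form an *insulin line*. Three record types attach to products:

- **patents** — Orange Book listings with an expiry date, joined to a curated
  annotation (USPTO application date, priority date, device flag, and whether
  any claim mentions the active ingredient or its molecular structure);
- **regulatory exclusivities** — category code and expiry date;
- **product metadata** — curated class (onset of action), presentation,
  originator/follow-on status, brand family, manufacturer.

Inputs are tilde-delimited data files in the Orange Book layout plus two CSV
curation tables. Two date dialects are accepted (`Mon DD, YYYY` and
ISO-8601); everything is normalized to ISO dates internally. Inputs taken
from annual editions, where the first-listing date has one-year granularity,
should be encoded as December 31 of the edition year.

## Cohort rules

The study window is 1986-01-01 through 2019-12-31 inclusive, tested on the
approval date only (consecutive patent-listing editions begin in 1986;
insulins left the small-molecule listing regime in March 2020). Animal-derived
products (ingredient strings containing beef/pork/bovine/porcine terms) and
the three pre-window biosynthetic brands (Humulin R, L, N) are excluded.
Every input row either enters the cohort or lands in the exclusion log with a
reason — the partition is asserted in tests.

**Line grouping** keys on (brand family, ingredient set), requiring a single
manufacturer per group, rather than on the NDA alone. This is deliberate: one
brand family in the studied cohort (Humalog) spans two NDAs, and the
line-level analysis treats it as a single line. Ingredient normalization
uppercases, collapses whitespace, and drops the generic token "INSULIN", so
"insulin glargine" and "GLARGINE" compare equal across applicants.

## Classification conventions

All classifications are pure functions of dates and flags; input order never
affects a label.

- **Filing axis**: pre-approval iff the application date is strictly before
  the product's approval date. Ties count as post — the source material does
  not state a tie rule, so the strict-inequality convention is applied
  uniformly (and likewise for the priority axis: tie → after).
- **Listing axis**: listed-at-approval iff the first Orange Book listing date
  is ≤ approval + grace (default grace 0 days). A missing listing date
  inherits the filing axis with a warning.
- The filing tally (patents filed before approval) and the listing tally
  (patents added to the Orange Book after approval) are different axes; both
  are computed and reported separately, and duration scopes exist for each.
- **Device status** is three-valued: non-device, device-with-mention,
  device-no-mention. It comes from the curated annotation; no claim-text
  inference is performed. A keyword fallback on dosage-form strings was
  considered and rejected — the studied determination was manual, so the flag
  is an input.
- **Exclusivity categories** map from codes via a packaged, editable table
  (NCE → new chemical entity, NP → new product, NC → new combination,
  NPP → new patient population, NR → new route, I-*/D-* → new
  indication/dosing, PED → pediatric; unknown → other, with a warning).
- **Exclusivity grant timing** is not present in the data files (only the
  expiry is listed), so it is inferred: pediatric exclusivities are always
  post-approval (they are tallied separately); any other exclusivity is
  at-approval iff expiry ≤ approval + standard term, where the term is
  5 years for new chemical entities and 3 years otherwise, counted in
  round(years × 365.25) days. This reproduces grant timing exactly for
  exclusivities granted on the approval date and classifies later grants as
  post-approval.

Patents are classified per (patent, product) pair: a patent covering both the
vial and the pen contributes one object per product, because per-product
listing tallies are the analysis unit. Analyses over unique patents
deduplicate by patent number explicitly.

## Duration metrics

Durations are calendar-day differences divided by 365.25 — this reproduces
decimal-year reporting without month-arithmetic ambiguity. Rounding to one
decimal (and percentages to whole numbers, half away from zero) happens only
at report serialization, never inside computations.

- **Product protection**: approval → last-to-expire in-scope item. Scope
  filters compose conjunctively: patent subset (all / listed-at-approval /
  pre-approval-filed / device / non-device / no-mention / all-but-no-mention)
  × exclusivity inclusion × exclusivity timing. Products with no in-scope
  items return nothing and are excluded from duration medians while remaining
  in cohort totals. A last expiry before approval yields a negative duration,
  retained with a warning (lossless and auditable; reporting layers filter).
- **Last-item kind** (device patent / non-device patent / exclusivity) breaks
  expiry ties in that preference order — documented because ties occur when a
  patent covers several presentations.
- **Post-approval extension**: overall duration minus at-approval-only
  duration, reported only when a post-approval listing exists and the gain is
  strictly positive.
- **Line span**: first member approval → last member in-scope expiry; the
  earliest priority/application date is carried for timeline exports.
- **Device added protection**: last device expiry − last non-device expiry,
  signed; undefined when either class is absent. The no-mention variant
  compares no-mention device patents against the later of everything else.
  Signed values are kept; published-style summaries use the positive subset.
- **Pediatric exclusivities** are consumed as listed expiry dates — no
  six-month term arithmetic is performed, since the files list final dates.
- **Follow-on sensitivity**: matching requires exact normalized ingredient-set
  equality and a different manufacturer. An originator truncates at its
  earliest matching follow-on approval; a follow-on may match several
  originator lines (human insulin), and all pairs are reported. Truncated
  duration = approval → min(last expiry, entry), never exceeding the
  untruncated value.

## Statistics

Medians and IQRs use linear interpolation between order statistics
(positions 0.25/0.5/0.75 × (n−1)); the published analysis does not state a
quartile convention, so the mainstream default is used and a discrete
(order-statistic) variant is exposed via the `method` argument. Era tables
bin approval years into the fixed terciles 1986–1996 / 1997–2007 / 2008–2019
and into 5-year bins (the last bin is 2016–2019). No hypothesis testing is
performed — the analysis is descriptive.

## Packaged fixture

`obmex/data/originator_lines.csv` and `followon_lines.csv` transcribe the
published line-level cohort tables (25 originator lines summing to 56
products, 33 of them drug-device combinations; 3 follow-on lines, 5
products), with each line's manufacturer added from the published text. The
published table's ingredient strings are transcribed as printed. Product-level
approval dates beyond each line's first approval are not printed, so the
fixture expansion assigns the line's first-approval date to every member:
the fixture supports count-level checks and first-approval arithmetic, not
per-product duration analysis. The published source gives two inconsistent
Humalog product splits (3+1 in the cohort table footnote vs 5+1 in a figure
caption); the fixture follows the cohort table (4 products across two NDAs).

## Synthetic cohorts and what passing tests show

The generator emulates the studied market's structure: 25 lines by default
(1–5 products each) approved uniformly across 1986–2019; device fractions of
0.15/0.45/0.8 and Poisson patents-per-product means of 0.5/4/15 across the
three terciles (qualitatively matching the observed 0 → 4 → 17 median trend);
filing-date offsets from approval drawn from a discretized normal
(mean −1500 days, sd 1200, putting roughly a tenth of filings post-approval);
20-year patent terms from the priority date; 63% of a device product's
patents on the device, 85% of those with no active-ingredient mention; an
NCE (5-year) exclusivity on each line's first product and new-product
(3-year) exclusivities on half of the rest, with occasional post-approval
pediatric grants; and follow-on entry with probability 0.12 per line after a
10–20-year delay. The published study reports none of these distributions, so
the shapes (Poisson counts, normal offsets) are the generator's own choices,
fixed once.

Ground truth is computed during generation by raw day arithmetic over the
emitted records — a code path independent of the protection module — so the
generate → read → classify → protect round trip is a genuine oracle, and the
pipeline is required to match it exactly (0-day discrepancy). What passing
recovery tests show is that the pipeline's bookkeeping and date algebra are
correct; they do not validate curation quality, real-world listing lags, term
adjustments, or litigation outcomes, none of which the generator models.

## Problem sizes and numerical choices

Tests run the generator at 20–100 lines (≈60–320 products) and the oracle
suites at 1000 random instances, sizes at which every stage is exact and the
full suite completes in seconds. The acceptance script uses 100 lines.
Deterministic seeding (NumPy `default_rng`) makes generated files
byte-identical across runs. Degenerate inputs are defined behaviour: empty
item lists yield "no protection" rather than errors; empty eras report a
count of zero and no median; `median_iqr` of an empty list is an error.

## Known limitations

- Patent-term adjustments, terminal disclaimers, litigation, and settlement
  outcomes are out of scope; durations are *expected* protection from listed
  expiry dates.
- Exclusivity grant timing is inferred from expiry and standard terms; a
  non-standard term granted at approval later than its standard window would
  be misclassified as post-approval.
- The headline medians of the studied cohort (16.0 / 15.6 / 17.6 years)
  require the underlying curated patent-level dataset, which is not publicly
  deposited;
  the package reproduces the published cohort counts and cross-metric
  consistency values, and validates the duration algebra against synthetic
  ground truth instead.
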