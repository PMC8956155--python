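# Methods

This note records the models and procedures `labequity` implements, the
assumptions behind them, and the numerical and design choices made where
the problem left room.

## Workload model

A finalized report is the unit of work, attributed entirely to the
pathologist who placed the finalizing signature — not to whoever the case
was assigned to, nor to contributors who reported ancillary studies
without finalizing (a known under-count for biomarker-heavy practices,
see Limitations). Case attributes (class, site, specimen count, block
count, named ancillary counts) are mapped to units by a declarative
tariff: an ordered list of rules, each a predicate plus a linear
contribution `base + per_specimen·s + per_block·b + Σ per_ancillary·a`
per metric. Rules use **first-match** semantics because point tariffs
place each case in exactly one category; rule order is therefore part of
the tariff. Multiple metrics (workload points, fee units, blocks, case
counts) ride on one schema so that every downstream table can be produced
for any of them. Per-case precomputed units, when present in the input,
override the tariff for that metric, which lets laboratories feed in
units scored by their own upstream systems.

Two case classes are excluded before analysis — in-house cancer-review
cases and cases referred in from external laboratories — because their
attributes are systematically incomplete in LIS exports. Exclusions are
tallied per class and year and carried in the run manifest.

## Activity-based FTE

```
FTE = 1.0        if distinct ISO signing weeks > 41
FTE = weeks/48   otherwise
```

The measure is derived purely from signing activity, so it covers locums
and part-timers that employment records may miss. The 48-week divisor
reflects a contract pathologist's typical 4 weeks of leave; the 41-week
cut-off reflects full-time staff taking six or more weeks. Week identity
uses the ISO-8601 week-date system while the year a case belongs to is
the calendar year of its sign-out date; a calendar year can therefore
touch up to 54 distinct ISO week keys (e.g. 2012 spans 2011-W52,
2012-W01..52 and 2013-W01), and validation allows that. Pro-rata
annualized workload is raw units divided by FTE and is the member-level
quantity used for all inequality statistics.

## Group assignment

Groups are re-derived every year from case mix alone. A pathologist whose
surgical sign-outs come mostly from hospital organization *alpha* joins
group alpha; otherwise they fall to *beta*, subclassified into beta1 or
beta2 by all-case site fractions. Ties go to beta and to beta2
respectively (the rule's else-branches). A pathologist with no surgical
cases in a year (cytology-only) is assigned by all-case organization
fractions instead; this fallback is logged, since the original rule is
silent about the case. The mapping of alpha/beta1/beta2 onto published
group numbers is a configurable permutation (identity by default) —
deployments may wish to hide it for anonymity.

Group-year summaries report both the mean of members' pro-rata units and
the group total divided by the group FTE sum; these are different
statistics (members enter the first unweighted) and both are emitted.
Period rows are arithmetic means of the yearly values, so period signer
counts can be fractional. A single-member group-year has a missing
(NaN) sample SD, never zero.

## Inequality metrics

For nonnegative member values x₁..xₙ:

* plain Gini `G = Σᵢⱼ|xᵢ−xⱼ|/(2n²x̄)`, computed via the sorted-rank
  identity (O(n log n)); bias-corrected variant multiplies by n/(n−1).
  The pipeline defaults to **bias-corrected**, matching the common
  default of reference implementations (e.g. DescTools `Gini` with
  `unbiased=TRUE`); `--estimator plain` switches. Results are provably in
  [0,1] for nonnegative input; only floating-point residue is clipped.
  Fewer than two members, or an all-zero vector, yield NaN with a
  warning.
* Hoover index `H = Σ|xᵢ−x̄|/(2Σxᵢ)` — the redistributable share; always
  ≤ plain G (checked as a property test).
* Lorenz curve: sorted cumulative-share polyline; the trapezoid-area
  identity `G = 1 − 2·area` is used as an internal cross-check.
* Gini tables are computed on full-time members (FTE exactly 1.0) and,
  as a variant, on members above a >0.3-FTE threshold; members enter
  unweighted. An FTE-weighted Gini exists for sensitivity analysis only.

## Robin Hood FTEs

With pooled per-FTE workload `w̄ = Σ_g units_g / Σ_g FTE_g`, the
adjustment `Δ_g = units_g/w̄ − FTE_g` is the number of FTEs group *g*
must gain (positive, deficit) or shed (negative, surplus) for every group
to carry exactly `w̄` per FTE; the real-valued adjustments sum to zero by
construction and applying them equalizes per-FTE workload to within
1e-9. For presentation, integers are produced by rounding
half-away-from-zero and assigning the residual to the group with the
largest absolute adjustment, so integer rows also sum to zero. The period
table averages the yearly real-valued adjustments and then rounds
(`round_then_average` is available behind a flag). Percentages are the
adjustment relative to the group's own FTEs.

## SAD events and rates

A significant absence or departure (SAD) flags pathologist-year (p, y)
when `weeks(p, y−1) − weeks(p, y) > 13` — a quarter-year drop — and
(p, y−1) was not itself a SAD. Events are decided in ascending year
order so the exclusion always refers to an already-decided status. Edge
rules: the first study year yields no events (no prior); a new hire
cannot generate an event in their first year; a prior-year signer absent
in the current year is compared against 0 weeks (callers pass the study
window's last year so final-year departures are evaluated); zero weeks
in both years generates nothing. The drop threshold is exposed
(`--drop-weeks`) for sensitivity analysis.

`SADR = Σ events / FTEs`. Yearly group rates use the group's FTE total;
an event whose pathologist has no pathologist-year row in the event year
(signed nothing) is attributed to their prior-year group — the rule
source is silent here, and the event-year group is used whenever it
exists. Group period rates are means of yearly rates. The whole-lab
cumulative period rate divides total events by the **mean** yearly lab
FTE total over the event period (a summed-denominator alternative exists
behind a flag), and `rescale_period` converts cumulative rates between
windows of different lengths (e.g. an 8-year rate × 3/8 for comparison
with published 3-year turnover figures).

## Synthetic laboratory

The generator emulates the structure of a regional laboratory: three
groups tied to two hospital organizations and four sites, with distinct
mean per-FTE workloads, within-group dispersion, partial years, hires,
absences and departures. Choices, and what they imply for what a green
test establishes:

* **Week plans first.** Signing weeks are fixed deterministically (the
  first 46 week keys for a full-timer; absences/departures truncate;
  replacement hires start `residual + 3` weeks in), so weeks, FTE and
  SAD events are exact ledger quantities, not statistical ones.
* **Gamma workload noise.** A pathologist-year's unit total is drawn
  from a gamma law with mean `group mean × FTE` and coefficient of
  variation `dispersion` (positive, right-skewed; lognormal available via
  `noise="lognormal"`). Dispersion 0 gives the mean exactly.
* **Back-solved case attributes.** The drawn total is quantized to the
  0.5-unit grid of the synthetic tariff (1 unit/case + 0.5/block) and
  realized as integer per-case block counts, so scoring the generated
  cases reproduces ledgered totals exactly (quantization error ≤ 0.25
  units on totals of thousands). Scoring and aggregation are therefore
  jointly testable against the ledger at machine precision.
* **Deterministic case mix.** Per-site and per-class counts are computed
  deterministically (85% home site by default, the rest spread over the
  other sites), so yearly group assignment is exact ledger truth.
* **Scaled case volume.** The default `cases_per_week=10` is ~4.5× below
  a real regional lab's ~45; unit totals are drawn at full scale, so all
  per-FTE, inequality and turnover metrics are unaffected while test
  runtimes stay small. The full-scale scenario uses 10/10/13 pathologist
  slots (~32 FTE) over 2011–2019 with 30 scheduled turnover events in
  2012–2019, none in consecutive years for the same person, each leaving
  a >13-week drop — so exactly 30 SAD events are implied.
* **Dispersion calibration.** `calibrate_dispersion` bisects the
  monotone map dispersion → mean simulated bias-corrected Gini (200
  gamma samples of group size per evaluation, common random numbers) to
  full interval convergence, then verifies the achieved mean is within
  ±0.01 of the target. Converging fully rather than stopping at the
  first within-tolerance evaluation avoids leaving a systematic offset
  of up to 0.01 in the calibrated group.

What the generator does **not** emulate: report text, seasonal or weekly
volume structure, correlation of a pathologist's workload across years,
case-mix drift, or any causal link between workload and departures —
turnover is scheduled, not endogenous. A green parameter-recovery test
therefore establishes that the pipeline measures what the generator
states, not that real laboratories behave like the generator.

The period-average full-time Gini of a single full-scale realization has
a sampling SD of roughly 0.004–0.016 (group-size and dispersion
dependent), so recovery checks on Gini targets average several seeded
replicates to bring the check's precision in line with its ±0.02 band;
event-count checks are exact per replicate.

## Limitations

* Work by pathologists who report ancillary studies without finalizing
  the case is not captured; consult work is credited to the primary
  pathologist.
* SADs cannot distinguish long absences from departures, by design.
* The shipped tariff is illustrative; reproducing any published point or
  fee schedule requires supplying that schedule as a schema file.
* 7Z-archive ingestion requires the optional `py7zr` package; without it
  the helper raises a clear configuration error and tables must be
  unpacked manually.
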