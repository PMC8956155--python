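# labequity

Workload-equity analytics for hospital pathology laboratories.

In salaried pathology practice, workload has no link to pay and is rarely
audited, so substantial maldistribution of professional work can persist
unnoticed — with consequences for diagnostic quality, burnout and staff
turnover. `labequity` turns the case-level sign-out records that every
laboratory information system already holds into the quantities needed to
see that distribution:

* **Workload scoring.** Each finalized report is converted into workload
  units under a declarative, user-editable tariff (point systems such as
  the Canadian L4E, fee-schedule "shadow billings", block counts, plain
  case counts — all just metrics of one schema). First-match rule
  semantics mirror tariff tables; the shipped example tariff is
  illustrative, not any published schedule.
* **Activity-based FTEs.** A pathologist signing cases in more than 41
  distinct ISO-8601 weeks of a calendar year counts as 1.0 FTE; otherwise
  FTE = weeks/48. No employment records required. A partial-year
  workload is annualized *pro rata* by dividing by the FTE.
* **Inequality metrics.** For members' pro-rata units: the Gini
  coefficient (plain `G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄)` and bias-corrected
  `n/(n−1)` variants), the Lorenz curve, and the Hoover (Robin Hood)
  index `H = Σ|xᵢ−x̄| / (2Σxᵢ)`.
* **Robin Hood FTEs.** With pooled per-FTE workload
  `w̄ = Σ units / Σ FTE`, group *g* needs `Δ_g = units_g/w̄ − FTE_g`
  additional full-time equivalents for all groups to carry equal work per
  FTE. Positive = staffing deficit, negative = surplus; the adjustments
  sum to zero.
* **SAD detection.** A *significant absence or departure* flags a
  pathologist whose signing-week count falls by more than 13 ISO weeks
  (a quarter year) versus the prior year, with a consecutive-year
  exclusion so one departure straddling a year boundary is not counted
  twice. `SADR = Σ events / FTEs` is an LIS-derived turnover signal.
* **Synthetic laboratory.** A seedable generator emulates a regional lab
  (three hospital groups with distinct mean workloads, tunable
  within-group Gini, hires, absences, departures) and emits a
  ground-truth ledger that predicts every downstream metric — the basis
  of the test suite.

## Worked example

Run the pipeline on the small packaged scenario (3 groups × 4
pathologists × 4 years, one scheduled departure and one absence):

```bash
labequity report --scenario paperlike_small --out out/
# wrote report tables to out/
# period SAD events: 2 over 3 years (cumulative rate 16.9%)
```

`out/group_period.csv` — study-period averages of the yearly group
summaries (means are of members' pro-rata units; `units_per_fte` is the
group total divided by the group FTE sum, a different statistic):

```
group  n_signers  fte_total  member_mean  member_sd  units_per_fte
    1        4.0        4.0       7972.1      645.2         7972.1
    2        4.0        3.9       7253.6     1201.3         7286.6
    3        4.2        4.0       4460.0     1159.5         4416.0
```

The generator's intended means were 8000 / 7000 / 4000 units per FTE —
recovered up to within-group dispersion. `out/robin_period.csv` shows the
redistribution that would equalize per-FTE workload:

```
group  adjustment  adjustment_int  percent_of_group
    1        0.87               1             21.77
    2        0.44               0             11.32
    3       -1.31              -1            -32.59
```

Groups 1 and 2 are under-staffed for the work they carry (positive), group
3 over-staffed; the row sums to zero because it is a pure redistribution.
`out/sad_period.csv` attributes the two injected turnover events to their
groups (yearly-rate averages 0 / 0.098 / 0.082), and `out/gini_period.csv`
gives the within-group full-time Gini coefficients (0.051 / 0.104 /
0.157 here). Add `--plots` for FTE-by-year and units-per-FTE-by-year
figures, or use `labequity synth` to export the raw case table plus its
truth ledger. Real data enters through `labequity ingest`/`score` with a
YAML column map and tariff schema (see `src/labequity/schemas/`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's acceptance quantity end to end: it synthesizes a
one-pathologist case table with sign-outs in exactly 24 distinct ISO
weeks of a calendar year (dates drawn from the seed), runs it through
exclusion filtering, tariff scoring and pathologist-year aggregation, and
reports the activity-based FTE the pipeline derives.
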