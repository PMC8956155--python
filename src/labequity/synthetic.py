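"""Seedable synthetic laboratory with a known ground-truth ledger.

The generator emulates the structure of a regional hospital laboratory:
three pathologist groups tied to hospital organizations/sites with
distinct mean per-FTE workloads, tunable within-group dispersion, partial
years, new hires, and scheduled absences/departures that produce
significant-absence-or-departure (SAD) events downstream.

How a pathologist-year is realized:

1. A signing-week plan is fixed first (full-timers sign the first
   ``weeks_full_time`` ISO weeks of the calendar year; absences and
   departures truncate the plan; hires start mid-year), which pins down
   ``weeks_signed`` and hence the FTE exactly.
2. The year's workload-unit total is drawn from a gamma law with mean
   ``group mean × FTE`` and coefficient of variation ``dispersion``
   (lognormal available via ``noise="lognormal"``); a coefficient of
   variation of 0 gives the mean deterministically.
3. The drawn total is quantized to the synthetic tariff's 0.5-unit grid
   and back-solved into integer per-case block counts, so scoring the
   generated cases under :func:`synthetic_tariff` reproduces the ledgered
   total exactly (quantization error ≤ 0.25 units on totals of thousands).

Cancer-review and external-referral cases — which the ingest step is
expected to exclude — are injected on top with per-year counts recorded
in the ledger.

The :class:`TruthLedger` predicts every downstream quantity: weeks, FTE,
group and unit totals exactly; group mean per-FTE workloads and Gini
coefficients up to sampling error at the configured group sizes.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import CaseRecord, ConfigurationError, cases_to_frame
from .scoring import Contribution, Rule, WorkloadSchema
from .staffing import GroupingConfig, compute_fte, iso_week_key

GROUP_LABELS = ("alpha", "beta1", "beta2")


class CalibrationError(RuntimeError):
    """Dispersion calibration could not bracket or reach the target."""


@dataclass(frozen=True)
class GroupSpec:
    """One pathologist group and the hospital sites it serves."""

    name: str                    # grouping label: alpha | beta1 | beta2
    organization: str
    sites: tuple[str, ...]
    n_pathologists: int
    mean_units_per_fte: float
    dispersion: float = 0.0      # coefficient of variation of yearly totals
    surgical_share: float = 0.85

    def __post_init__(self) -> None:
        if self.name not in GROUP_LABELS:
            raise ConfigurationError(f"group name must be one of {GROUP_LABELS}")
        if self.n_pathologists < 1 or not self.sites:
            raise ConfigurationError("groups need >=1 pathologist and >=1 site")
        if self.mean_units_per_fte <= 0 or self.dispersion < 0:
            raise ConfigurationError("mean_units_per_fte > 0 and dispersion >= 0 required")
        if not 0 <= self.surgical_share <= 1:
            raise ConfigurationError("surgical_share must be in [0, 1]")


@dataclass(frozen=True)
class TurnoverEvent:
    """A scheduled absence (returns next year) or departure (gone for good)."""

    group: int       # 0-based index into SyntheticConfig.groups
    slot: int        # pathologist position within the group
    year: int
    residual_weeks: int
    kind: str = "absence"

    def __post_init__(self) -> None:
        if self.kind not in ("absence", "departure"):
            raise ConfigurationError("turnover kind must be 'absence' or 'departure'")
        if self.residual_weeks < 0:
            raise ConfigurationError("residual_weeks must be >= 0")


@dataclass(frozen=True)
class HireEvent:
    """An additional pathologist starting mid-study (grows the group)."""

    group: int
    year: int
    start_week: int


@dataclass
class SyntheticConfig:
    years: tuple[int, int] = (2011, 2019)
    groups: Sequence[GroupSpec] = ()
    turnover: Sequence[TurnoverEvent] = ()
    hires: Sequence[HireEvent] = ()
    weeks_full_time: int = 46
    cases_per_week: int = 10
    cross_site_share: float = 0.15
    review_per_year: int = 180
    external_per_year: int = 830
    rehire_gap_weeks: int = 3
    replace_departures: bool = True
    noise: str = "gamma"         # or "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if y1 < y0:
            raise ConfigurationError("years range is empty")
        if not self.groups:
            raise ConfigurationError("at least one group is required")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ConfigurationError("group names must be unique")
        if self.cases_per_week < 1 or self.weeks_full_time < 1:
            raise ConfigurationError("cases_per_week and weeks_full_time must be >= 1")
        if not 0 <= self.cross_site_share < 0.5:
            raise ConfigurationError("cross_site_share must be in [0, 0.5)")
        if self.noise not in ("gamma", "lognormal"):
            raise ConfigurationError("noise must be 'gamma' or 'lognormal'")


@dataclass
class TruthLedger:
    """Ground truth sufficient to predict every downstream metric."""

    pathologist_years: pd.DataFrame  # pid, year, group, group_label, home_site, weeks, fte, units_L4E, pro_rata_L4E
    expected_sad: pd.DataFrame       # pathologist_id, year, weeks_prior, weeks_current
    exclusions: pd.DataFrame         # year, case_class, count
    group_intent: pd.DataFrame       # group, label, n_slots, mean_units_per_fte, dispersion


# ---------------------------------------------------------------------------
# Tariff and grouping config used by synthetic scenarios


def synthetic_tariff() -> WorkloadSchema:
    """Flat tariff (1 unit per case + 0.5 per block) used by the generator.

    The per-block term gives a 0.5-unit grid on which any target yearly
    total can be hit exactly with integer block counts.
    """
    every = Rule(
        name="any-case",
        match={},
        contributions={
            "L4E": Contribution(base=1.0, per_block=0.5),
            "cases": Contribution(base=1.0),
            "blocks": Contribution(per_block=1.0),
        },
    )
    return WorkloadSchema(
        metric_names=("L4E", "cases", "blocks"),
        rules=(every,),
        version_tag="synthetic-tariff-0.1",
        unmatched_policy="error",
    )


def grouping_config(cfg: SyntheticConfig) -> GroupingConfig:
    """Derive the site→organization topology from the group specs."""
    org_of_site: dict[str, str] = {}
    subgroup: dict[str, str] = {}
    alpha_org = ""
    for g in cfg.groups:
        for s in g.sites:
            org_of_site[s] = g.organization
            if g.name in ("beta1", "beta2"):
                subgroup[s] = g.name
        if g.name == "alpha":
            alpha_org = g.organization
    return GroupingConfig(
        org_of_site=org_of_site, alpha_org=alpha_org, subgroup_of_site=subgroup
    )


# ---------------------------------------------------------------------------
# Calendar plumbing


def _calendar_weeks(year: int) -> list[tuple[tuple[int, int], list[dt.date]]]:
    """Ordered distinct ISO week keys touched by a calendar year, with the
    dates of that year falling in each."""
    day = dt.date(year, 1, 1)
    out: dict[tuple[int, int], list[dt.date]] = {}
    while day.year == year:
        out.setdefault(iso_week_key(day), []).append(day)
        day += dt.timedelta(days=1)
    return list(out.items())


@dataclass
class _Occupant:
    pid: str
    group_idx: int
    home_site: str
    plan: dict[int, tuple[int, int]] = field(default_factory=dict)  # year -> (start_idx 1-based, n_weeks)


def _build_occupants(cfg: SyntheticConfig) -> list[_Occupant]:
    y0, y1 = cfg.years
    years = range(y0, y1 + 1)
    occupants: list[_Occupant] = []
    current: dict[tuple[int, int], _Occupant] = {}

    for gi, g in enumerate(cfg.groups):
        for slot in range(g.n_pathologists):
            occ = _Occupant(
                pid=f"P{gi + 1}_{slot:02d}",
                group_idx=gi,
                home_site=g.sites[slot % len(g.sites)],
                plan={y: (1, cfg.weeks_full_time) for y in years},
            )
            occupants.append(occ)
            current[(gi, slot)] = occ

    hire_seq = 0
    for ev in sorted(cfg.turnover, key=lambda e: (e.year, e.group, e.slot)):
        if not (y0 <= ev.year <= y1):
            raise ConfigurationError(f"turnover year {ev.year} outside study window")
        if ev.residual_weeks > cfg.weeks_full_time:
            raise ConfigurationError(
                f"infeasible schedule: residual_weeks {ev.residual_weeks} exceeds "
                f"weeks_full_time {cfg.weeks_full_time}"
            )
        key = (ev.group, ev.slot)
        if key not in current:
            raise ConfigurationError(f"turnover references unknown slot {key}")
        occ = current[key]
        if ev.residual_weeks > 0:
            occ.plan[ev.year] = (1, ev.residual_weeks)
        else:
            occ.plan.pop(ev.year, None)
        if ev.kind == "departure":
            for y in list(occ.plan):
                if y > ev.year:
                    del occ.plan[y]
            if cfg.replace_departures:
                hire_seq += 1
                start = ev.residual_weeks + cfg.rehire_gap_weeks + 1
                hire = _Occupant(
                    pid=f"H{ev.group + 1}_{ev.year}_{hire_seq:02d}",
                    group_idx=ev.group,
                    home_site=occ.home_site,
                    plan={y: (1, cfg.weeks_full_time) for y in years if y > ev.year},
                )
                hire.plan[ev.year] = (start, cfg.weeks_full_time)
                occupants.append(hire)
                current[key] = hire

    for ev in cfg.hires:
        if not (y0 <= ev.year <= y1):
            raise ConfigurationError(f"hire year {ev.year} outside study window")
        g = cfg.groups[ev.group]
        hire_seq += 1
        occ = _Occupant(
            pid=f"H{ev.group + 1}_{ev.year}_{hire_seq:02d}",
            group_idx=ev.group,
            home_site=g.sites[hire_seq % len(g.sites)],
            plan={y: (1, cfg.weeks_full_time) for y in years if y > ev.year},
        )
        occ.plan[ev.year] = (ev.start_week, cfg.weeks_full_time)
        occupants.append(occ)
    return occupants


def _site_class_arrays(
    n: int, home: str, all_sites: Sequence[str], cross_share: float,
    surgical_share: float, rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Deterministic per-site/per-class counts (home-site plurality is
    guaranteed by construction), shuffled into a random case order."""
    others = [s for s in all_sites if s != home]
    n_cross = int(round(n * cross_share)) if others else 0
    counts: list[tuple[str, int]] = [(home, n - n_cross)]
    if others:
        per, rem = divmod(n_cross, len(others))
        counts += [(s, per + (1 if i < rem else 0)) for i, s in enumerate(others)]
    sites: list[str] = []
    classes: list[str] = []
    for site, cnt in counts:
        n_surg = int(round(cnt * surgical_share))
        sites += [site] * cnt
        classes += ["surgical"] * n_surg + ["cytology"] * (cnt - n_surg)
    order = rng.permutation(n)
    return [sites[i] for i in order], [classes[i] for i in order]


# ---------------------------------------------------------------------------
# Main generator


def generate_lab(cfg: SyntheticConfig) -> tuple[list[CaseRecord], TruthLedger]:
    """Generate a case-level dataset plus its :class:`TruthLedger`.

    Deterministic for a fixed config (the seed lives in the config): the
    same config yields byte-identical case tables.
    """
    rng = np.random.default_rng(cfg.seed)
    y0, y1 = cfg.years
    week_cache = {y: _calendar_weeks(y) for y in range(y0, y1 + 1)}
    org_of_site = {s: g.organization for g in cfg.groups for s in g.sites}
    all_sites = [s for g in cfg.groups for s in g.sites]
    occupants = _build_occupants(cfg)

    cases: list[CaseRecord] = []
    ledger_rows = []
    active_weeks: dict[int, list[tuple[_Occupant, tuple[tuple[int, int], list[dt.date]]]]] = {
        y: [] for y in range(y0, y1 + 1)
    }
    seq = 0

    for occ in occupants:
        g = cfg.groups[occ.group_idx]
        for year in sorted(occ.plan):
            start, n_planned = occ.plan[year]
            year_weeks = week_cache[year]
            avail = len(year_weeks) - (start - 1)
            n_weeks = min(n_planned, max(avail, 0))
            if n_weeks <= 0:
                continue
            my_weeks = year_weeks[start - 1 : start - 1 + n_weeks]
            active_weeks[year] += [(occ, wk) for wk in my_weeks]
            fte = compute_fte(n_weeks)
            n_cases = n_weeks * cfg.cases_per_week

            mean = g.mean_units_per_fte * fte
            d = g.dispersion
            if d == 0:
                total = mean
            elif cfg.noise == "gamma":
                shape = 1.0 / d**2
                total = float(rng.gamma(shape, mean * d**2))
            else:
                sigma2 = math.log(1.0 + d**2)
                total = float(rng.lognormal(math.log(mean) - sigma2 / 2, math.sqrt(sigma2)))

            # quantize to the 0.5-unit grid reachable with integer blocks
            n_blocks = max(0, int(round((total - n_cases) / 0.5)))
            true_total = n_cases + 0.5 * n_blocks
            q, r = divmod(n_blocks, n_cases)
            block_counts = [q + 1] * r + [q] * (n_cases - r)

            sites, classes = _site_class_arrays(
                n_cases, occ.home_site, all_sites, cfg.cross_site_share,
                g.surgical_share, rng,
            )

            i = 0
            for (_, dates) in my_weeks:
                idx = np.sort(rng.integers(0, len(dates), size=cfg.cases_per_week))
                for j in idx:
                    seq += 1
                    b = block_counts[i]
                    cases.append(
                        CaseRecord(
                            case_id=f"C{seq:07d}",
                            pathologist_id=occ.pid,
                            signout_date=dates[int(j)],
                            site=sites[i],
                            organization=org_of_site[sites[i]],
                            case_class=classes[i],
                            specimen_count=1 + b // 3,
                            block_count=b,
                        )
                    )
                    i += 1

            ledger_rows.append(
                {
                    "pathologist_id": occ.pid,
                    "year": year,
                    "group": occ.group_idx + 1,
                    "group_label": g.name,
                    "home_site": occ.home_site,
                    "weeks_signed": n_weeks,
                    "fte": fte,
                    "units_L4E": true_total,
                    "pro_rata_L4E": true_total / fte,
                }
            )

    # excluded-class cases on top (removed again by ingest exclusions)
    excl_rows = []
    for year in range(y0, y1 + 1):
        pool = active_weeks[year]
        if not pool:
            continue
        for case_class, n_extra in (
            ("review", cfg.review_per_year),
            ("external_referral", cfg.external_per_year),
        ):
            for k in range(n_extra):
                occ, (_, dates) = pool[int(rng.integers(0, len(pool)))]
                seq += 1
                cases.append(
                    CaseRecord(
                        case_id=f"C{seq:07d}",
                        pathologist_id=occ.pid,
                        signout_date=dates[int(rng.integers(0, len(dates)))],
                        site=occ.home_site,
                        organization=org_of_site[occ.home_site],
                        case_class=case_class,
                        specimen_count=1,
                        block_count=2,
                    )
                )
            if n_extra:
                excl_rows.append({"year": year, "case_class": case_class, "count": n_extra})

    truth_py = pd.DataFrame(ledger_rows).sort_values(["pathologist_id", "year"]).reset_index(drop=True)
    ledger = TruthLedger(
        pathologist_years=truth_py,
        expected_sad=_expected_sad(truth_py, first_year=y0),
        exclusions=pd.DataFrame(excl_rows, columns=["year", "case_class", "count"]),
        group_intent=pd.DataFrame(
            [
                {
                    "group": gi + 1,
                    "label": g.name,
                    "n_slots": g.n_pathologists,
                    "mean_units_per_fte": g.mean_units_per_fte,
                    "dispersion": g.dispersion,
                }
                for gi, g in enumerate(cfg.groups)
            ]
        ),
    )
    return cases, ledger


def generate_frame(cfg: SyntheticConfig) -> tuple[pd.DataFrame, TruthLedger]:
    """Like :func:`generate_lab` but returning the canonical case frame."""
    cases, ledger = generate_lab(cfg)
    return cases_to_frame(cases), ledger


def _expected_sad(truth_py: pd.DataFrame, first_year: int, drop_weeks: int = 13) -> pd.DataFrame:
    """Independent bookkeeping of the SAD events implied by planned weeks."""
    weeks = {
        (r.pathologist_id, int(r.year)): int(r.weeks_signed)
        for r in truth_py.itertuples(index=False)
    }
    last = int(truth_py["year"].max()) if len(truth_py) else first_year
    pids = sorted({r[0] for r in weeks})
    flagged: set[tuple[str, int]] = set()
    rows = []
    for year in range(first_year + 1, last + 1):
        for pid in pids:
            prior = weeks.get((pid, year - 1), 0)
            if prior == 0:
                continue
            current = weeks.get((pid, year), 0)
            if prior - current > drop_weeks and (pid, year - 1) not in flagged:
                flagged.add((pid, year))
                rows.append(
                    {
                        "pathologist_id": pid,
                        "year": year,
                        "weeks_prior": prior,
                        "weeks_current": current,
                    }
                )
    return pd.DataFrame(rows, columns=["pathologist_id", "year", "weeks_prior", "weeks_current"])


# ---------------------------------------------------------------------------
# Dispersion calibration


def _gini_rows(x: np.ndarray, estimator: str) -> np.ndarray:
    """Row-wise Gini of a (replicates, n) matrix."""
    n = x.shape[1]
    xs = np.sort(x, axis=1)
    i = np.arange(1, n + 1)
    g = ((2 * i - n - 1) * xs).sum(axis=1) / (n * xs.sum(axis=1))
    if estimator == "bias_corrected":
        g = g * n / (n - 1)
    return g


def calibrate_dispersion(
    target_gini: float,
    n: int,
    seed: int = 0,
    estimator: str = "bias_corrected",
    replicates: int = 200,
    tol: float = 0.01,
    bracket: tuple[float, float] = (1e-6, 1.5),
) -> float:
    """Dispersion (gamma CV) whose simulated group Gini matches a target.

    Bisects the monotone map dispersion → mean simulated Gini (over
    ``replicates`` gamma samples of size ``n``, common random numbers per
    evaluation) down to a negligible dispersion interval, then verifies
    the achieved mean is within ``tol`` of the target.  Full interval
    convergence (rather than stopping at the first within-``tol``
    evaluation) avoids leaving a systematic offset of up to ``tol`` in the
    calibrated group.
    """
    if not 0 <= target_gini < 0.5:
        raise CalibrationError("target Gini must be in [0, 0.5)")
    if n < 2:
        raise CalibrationError("need n >= 2 members to calibrate a Gini")
    if target_gini == 0:
        return 0.0

    def mean_gini(d: float) -> float:
        rng = np.random.default_rng(seed)
        shape = 1.0 / d**2
        sims = rng.gamma(shape, 1.0, size=(replicates, n))
        return float(_gini_rows(sims, estimator).mean())

    lo, hi = bracket
    if mean_gini(hi) < target_gini - tol:
        raise CalibrationError(
            f"target Gini {target_gini} not reachable with dispersion <= {hi}"
        )
    while hi - lo > 1e-4:
        mid = 0.5 * (lo + hi)
        if mean_gini(mid) < target_gini:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    achieved = mean_gini(mid)
    if abs(achieved - target_gini) > tol:
        raise CalibrationError(
            f"calibration reached Gini {achieved:.4f}, outside ±{tol} of {target_gini}"
        )
    return mid


# ---------------------------------------------------------------------------
# Packaged scenarios


def _default_groups(
    means: tuple[float, float, float],
    dispersions: tuple[float, float, float],
    slots: tuple[int, int, int],
) -> tuple[GroupSpec, ...]:
    return (
        GroupSpec("alpha", "alpha_org", ("AH",), slots[0], means[0], dispersions[0], 0.90),
        GroupSpec("beta1", "beta_org", ("B1H",), slots[1], means[1], dispersions[1], 0.85),
        GroupSpec("beta2", "beta_org", ("B2H", "B2S"), slots[2], means[2], dispersions[2], 0.75),
    )


def paperlike_small(seed: int = 7) -> SyntheticConfig:
    """Small smoke scenario: 3 groups x 4 pathologists x 4 years."""
    return SyntheticConfig(
        years=(2016, 2019),
        groups=_default_groups((8000.0, 7000.0, 4000.0), (0.08, 0.18, 0.30), (4, 4, 4)),
        turnover=(
            TurnoverEvent(2, 1, 2017, 18, "departure"),
            TurnoverEvent(1, 0, 2018, 20, "absence"),
        ),
        cases_per_week=6,
        review_per_year=40,
        external_per_year=150,
        seed=seed,
    )


#: 30 scheduled turnover events over 2012-2019.  No slot occupant has
#: events in consecutive years, every residual leaves a >13-week drop, and
#: departures are backfilled by hires, so exactly 30 SAD events result.
_FULL_TURNOVER: tuple[TurnoverEvent, ...] = tuple(
    TurnoverEvent(g, s, y, r, k)
    for (g, s, y, r, k) in (
        (0, 0, 2012, 20, "departure"),
        (1, 0, 2012, 25, "absence"),
        (1, 1, 2012, 10, "departure"),
        (2, 0, 2012, 15, "absence"),
        (0, 1, 2013, 8, "absence"),
        (1, 2, 2013, 30, "departure"),
        (2, 1, 2013, 22, "departure"),
        (0, 2, 2014, 18, "departure"),
        (1, 3, 2014, 12, "absence"),
        (1, 4, 2014, 28, "absence"),
        (0, 3, 2015, 25, "absence"),
        (1, 5, 2015, 16, "departure"),
        (2, 2, 2015, 9, "absence"),
        (2, 3, 2015, 20, "departure"),
        (0, 4, 2016, 30, "departure"),
        (1, 6, 2016, 21, "absence"),
        (1, 7, 2016, 7, "departure"),
        (0, 5, 2017, 14, "absence"),
        (1, 8, 2017, 26, "departure"),
        (2, 4, 2017, 11, "absence"),
        (0, 6, 2018, 23, "departure"),
        (0, 7, 2018, 10, "absence"),
        (1, 9, 2018, 19, "absence"),
        (2, 5, 2018, 27, "departure"),
        (0, 8, 2019, 29, "absence"),
        (0, 9, 2019, 6, "departure"),
        (1, 0, 2019, 17, "absence"),
        (1, 1, 2019, 24, "absence"),
        (2, 6, 2019, 13, "departure"),
        (2, 7, 2019, 5, "absence"),
    )
)


def paperlike_full(
    seed: int = 11,
    means: tuple[float, float, float] = (8100.0, 6900.0, 4200.0),
    target_ginis: tuple[float, float, float] = (0.05, 0.16, 0.23),
    dispersions: tuple[float, float, float] | None = None,
) -> SyntheticConfig:
    """Full-scale scenario: 3 groups, ~32 FTEs, 9 years, 30 turnover events.

    Group dispersions are calibrated so the simulated full-time group Gini
    matches ``target_ginis`` unless explicit ``dispersions`` are given.
    Case volume is scaled down (~10 cases per signing week) relative to a
    real lab; unit totals are drawn at full scale, so all per-FTE and
    inequality metrics are unaffected.
    """
    slots = (10, 10, 13)
    if dispersions is None:
        cal_seed = (seed + 17) % 2**31
        dispersions = tuple(
            calibrate_dispersion(t, n=n, seed=cal_seed) for t, n in zip(target_ginis, slots)
        )
    return SyntheticConfig(
        years=(2011, 2019),
        groups=_default_groups(means, dispersions, slots),
        turnover=_FULL_TURNOVER,
        cases_per_week=10,
        review_per_year=180,
        external_per_year=830,
        seed=seed,
    )


SCENARIOS = {"paperlike_small": paperlike_small, "paperlike_full": paperlike_full}
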