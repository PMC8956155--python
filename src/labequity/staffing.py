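"""Aggregate scored cases into pathologist-years and group-year summaries.

The full-time-equivalent (FTE) measure is activity-based: it is derived
from the number of distinct ISO-8601 weeks in which a pathologist signed
out at least one case during a calendar year, not from employment
records::

    fte = 1.0            if weeks_signed > 41
    fte = weeks / 48     otherwise

The 48-week denominator reflects a contract pathologist's typical 4 weeks
off; the 41-week cut-off reflects full-time staff taking six or more
weeks off.  A pathologist-year's pro-rata workload is its raw unit total
divided by its FTE, i.e. workload expressed on a per-full-year basis.

Group membership is re-derived every year from case mix alone: a
pathologist whose surgical sign-outs come mostly from hospital
organization "alpha" joins the alpha group; otherwise they fall to "beta"
and are subclassified into beta1 or beta2 by their all-case site
fractions.  Ties go to beta and beta2 respectively.  The mapping of the
alpha/beta1/beta2 labels onto published group numbers is configurable
(identity by default) because real deployments may hide it for anonymity.

Note a case belongs to the CALENDAR year of its sign-out date while week
identity uses the ISO week-date system, so a calendar year may touch up
to 54 distinct ISO week keys (both end-weeks can belong to neighbouring
ISO years).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import ConfigurationError
from .scoring import UNITS_PREFIX

log = logging.getLogger(__name__)

PRO_RATA_PREFIX = "pro_rata_"

GROUP_LABELS = ("alpha", "beta1", "beta2")


@dataclass(frozen=True)
class GroupingConfig:
    """Site/organization topology for yearly group assignment."""

    org_of_site: Mapping[str, str]
    alpha_org: str
    subgroup_of_site: Mapping[str, str]  # beta-org site -> "beta1" | "beta2"
    label_map: Mapping[str, int] = field(
        default_factory=lambda: {"alpha": 1, "beta1": 2, "beta2": 3}
    )

    def __post_init__(self) -> None:
        bad = set(self.subgroup_of_site.values()) - {"beta1", "beta2"}
        if bad:
            raise ConfigurationError(f"subgroup_of_site values must be beta1/beta2, got {bad}")
        if set(self.label_map) != set(GROUP_LABELS):
            raise ConfigurationError("label_map must cover alpha, beta1, beta2")
        if sorted(self.label_map.values()) != [1, 2, 3]:
            raise ConfigurationError("label_map must be a permutation of {1,2,3}")


# ---------------------------------------------------------------------------
# Week / FTE primitives


def iso_week_key(d: dt.date) -> tuple[int, int]:
    """(ISO year, ISO week) of a calendar date."""
    iso = d.isocalendar()
    return (iso[0], iso[1])


def weeks_signed(dates: Iterable[dt.date]) -> int:
    """Number of distinct ISO weeks among sign-out dates."""
    return len({iso_week_key(d) for d in dates})


def compute_fte(weeks: int) -> float:
    """Activity-based FTE from a distinct-signing-week count."""
    if weeks < 0:
        raise ValueError(f"weeks_signed must be >= 0, got {weeks}")
    if weeks > 54:
        raise ValueError(f"weeks_signed cannot exceed 54, got {weeks}")
    return 1.0 if weeks > 41 else weeks / 48.0


# ---------------------------------------------------------------------------
# Group assignment


def assign_group(
    surgical_frac_by_org: Mapping[str, float],
    case_frac_by_site: Mapping[str, float],
    grouping: GroupingConfig,
) -> tuple[str, int, bool]:
    """Assign one pathologist-year to alpha / beta1 / beta2.

    Returns ``(label, group_number, used_fallback)``.  The alpha-vs-beta
    step compares surgical case fractions by organization; when the
    pathologist signed no surgical cases at all (e.g. cytology-only), the
    all-case organization fractions are used instead and the fallback flag
    is set.  The beta1-vs-beta2 step always uses all-case site fractions.
    """
    total_surg = sum(surgical_frac_by_org.values())
    used_fallback = total_surg <= 0
    if used_fallback:
        by_org: dict[str, float] = {}
        for site, frac in case_frac_by_site.items():
            org = grouping.org_of_site.get(site, "")
            by_org[org] = by_org.get(org, 0.0) + frac
    else:
        by_org = dict(surgical_frac_by_org)

    alpha_f = by_org.get(grouping.alpha_org, 0.0)
    beta_f = sum(v for k, v in by_org.items() if k != grouping.alpha_org)
    if alpha_f > beta_f:
        label = "alpha"
    else:  # ties go to beta
        beta1_f = sum(
            f for s, f in case_frac_by_site.items()
            if grouping.subgroup_of_site.get(s) == "beta1"
        )
        beta2_f = sum(
            f for s, f in case_frac_by_site.items()
            if grouping.subgroup_of_site.get(s) == "beta2"
        )
        label = "beta1" if beta1_f > beta2_f else "beta2"  # ties go to beta2
    return label, grouping.label_map[label], used_fallback


# ---------------------------------------------------------------------------
# Pathologist-years


def build_pathologist_years(
    scored: pd.DataFrame,
    grouping: GroupingConfig,
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per (pathologist, calendar year) with at least one case.

    Columns: ``pathologist_id, year, weeks_signed, fte, group_label,
    group, group_fallback, n_cases, units_<m>, pro_rata_<m>`` for each
    metric ``m``.  Workload is attributed entirely to the finalizing
    pathologist; pro-rata units are raw units divided by the FTE.
    """
    if metrics is None:
        metrics = [c[len(UNITS_PREFIX):] for c in scored.columns if c.startswith(UNITS_PREFIX)]
    unit_cols = [UNITS_PREFIX + m for m in metrics]

    f = scored.copy()
    dtcol = pd.to_datetime(f["signout_date"])
    f["_year"] = dtcol.dt.year
    iso = dtcol.dt.isocalendar()
    f["_isokey"] = iso.year.astype(int) * 100 + iso.week.astype(int)

    keys = ["pathologist_id", "_year"]
    agg_spec = {"weeks_signed": ("_isokey", "nunique"), "n_cases": ("_isokey", "size")}
    for col in unit_cols:
        agg_spec[col] = (col, "sum")
    agg = f.groupby(keys, sort=True).agg(**agg_spec)

    surg = (
        f[f["case_class"] == "surgical"]
        .groupby(keys + ["organization"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    allsite = f.groupby(keys + ["site"], observed=True).size().unstack(fill_value=0)

    rows = []
    n_fallback = 0
    for (pid, year), r in agg.iterrows():
        weeks = int(r["weeks_signed"])
        fte = compute_fte(weeks)
        if (pid, year) in surg.index:
            s = surg.loc[(pid, year)]
            stot = float(s.sum())
            surg_frac = {org: cnt / stot for org, cnt in s.items() if cnt} if stot else {}
        else:
            surg_frac = {}
        sites = allsite.loc[(pid, year)]
        ctot = float(sites.sum())
        site_frac = {site: cnt / ctot for site, cnt in sites.items() if cnt}

        label, number, fallback = assign_group(surg_frac, site_frac, grouping)
        n_fallback += fallback
        row = {
            "pathologist_id": pid,
            "year": int(year),
            "weeks_signed": weeks,
            "fte": fte,
            "group_label": label,
            "group": number,
            "group_fallback": fallback,
            "n_cases": int(r["n_cases"]),
        }
        for m, col in zip(metrics, unit_cols):
            raw = float(r[col])
            row[col] = raw
            row[PRO_RATA_PREFIX + m] = raw / fte if fte > 0 else np.nan
        rows.append(row)

    if n_fallback:
        log.info("group assignment used the all-case fallback for %d pathologist-year(s)", n_fallback)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group-year summaries


def group_summary(
    pathologist_years: pd.DataFrame,
    metric: str,
    full_time_only: bool = False,
    min_fte: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(group, year) aggregates plus the study-period average.

    The yearly table carries the group's signer count, FTE sum, raw unit
    total, units per FTE (``units_total / fte_total``), and summary
    statistics (mean, sd, median, min, max) of the members' PRO-RATA
    yearly units — note the member mean of pro-rata units is generally not
    the same number as ``units_total / fte_total``; both are reported.

    The period table is the arithmetic mean of the yearly values per
    group (signer counts may therefore be fractional).  A group-year with
    a single member has a missing (NaN) sd, never zero.
    """
    sel = pathologist_years
    if full_time_only:
        sel = sel[sel["fte"] == 1.0]
    if min_fte is not None:
        sel = sel[sel["fte"] > min_fte]
    ucol = UNITS_PREFIX + metric
    pcol = PRO_RATA_PREFIX + metric

    yearly = (
        sel.groupby(["group", "year"])
        .agg(
            n_signers=("pathologist_id", "size"),
            fte_total=("fte", "sum"),
            units_total=(ucol, "sum"),
            member_mean=(pcol, "mean"),
            member_sd=(pcol, "std"),
            member_median=(pcol, "median"),
            member_min=(pcol, "min"),
            member_max=(pcol, "max"),
        )
        .reset_index()
    )
    yearly["units_per_fte"] = yearly["units_total"] / yearly["fte_total"]

    period = (
        yearly.drop(columns=["year"])
        .groupby("group")
        .mean(numeric_only=True)
        .reset_index()
    )
    return yearly, period
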