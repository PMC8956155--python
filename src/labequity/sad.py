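"""Significant-absence-or-departure (SAD) events and rates.

A SAD event flags a pathologist whose distinct ISO signing-week count in
a calendar year falls by MORE than ``drop_weeks`` (default 13, a quarter
year) versus the prior year, provided the prior year was not itself a SAD
for that pathologist.  The consecutive-year exclusion prevents a
departure straddling a year boundary from being counted twice.  The
construct deliberately cannot distinguish a long absence (e.g. leave)
from a departure — both disrupt service the same way.

Rules at the edges:

* the first study year has no prior year, so it yields no events;
* a new hire (no prior-year signing) cannot generate an event in their
  first year;
* a pathologist who signed in the prior year but not at all in the
  current year is compared against 0 current weeks;
* a pathologist with zero weeks in both years generates nothing.

The SAD rate is ``SADR = Σ events / FTEs``.  Yearly group rates divide
the group's event count by the group's FTE total; the period rate per
group is the mean of its yearly rates.  The whole-laboratory cumulative
period rate divides total events by the MEAN yearly laboratory FTE total
over the event period (a per-year-summed denominator is available via
``cumulative_denominator="sum"``), and ``rescale_period`` converts a
cumulative rate between observation windows of different lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SADEvent:
    pathologist_id: str
    year: int
    weeks_current: int
    weeks_prior: int

    @property
    def drop(self) -> int:
        return self.weeks_prior - self.weeks_current


@dataclass
class SADRateResult:
    """Yearly and period SAD rates."""

    yearly: pd.DataFrame          # group, year, sad_count, fte_total, sadr
    period: pd.DataFrame          # group, sadr (mean of yearly rates), sad_count
    cumulative: dict = field(default_factory=dict)  # lab-wide period rate


def detect_sad_events(
    weeks: pd.DataFrame,
    drop_weeks: int = 13,
    first_year: int | None = None,
    last_year: int | None = None,
) -> list[SADEvent]:
    """Apply the drop rule with the consecutive-year exclusion.

    ``weeks`` needs columns ``pathologist_id, year, weeks_signed`` with at
    most one row per pathologist-year; years missing for a pathologist
    count as 0 weeks.  Events are decided in ascending year order so the
    exclusion always refers to an already-decided prior-year status.
    ``first_year`` (default: the earliest year present) yields no events;
    pass ``last_year`` when the study window extends beyond the last year
    with any signing activity, so that final-year departures (0 current
    weeks) are still evaluated.
    """
    needed = {"pathologist_id", "year", "weeks_signed"}
    if not needed <= set(weeks.columns):
        raise ValueError(f"weeks table needs columns {sorted(needed)}")
    if weeks.duplicated(["pathologist_id", "year"]).any():
        raise ValueError("weeks table has duplicate pathologist-year rows")
    if len(weeks) == 0:
        return []
    if first_year is None:
        first_year = int(weeks["year"].min())
    if last_year is None:
        last_year = int(weeks["year"].max())

    lookup: dict[tuple[str, int], int] = {
        (str(r.pathologist_id), int(r.year)): int(r.weeks_signed)
        for r in weeks.itertuples(index=False)
    }
    pathologists = sorted({str(p) for p in weeks["pathologist_id"]})

    events: list[SADEvent] = []
    flagged: set[tuple[str, int]] = set()
    for year in range(first_year + 1, last_year + 1):
        for pid in pathologists:
            prior = lookup.get((pid, year - 1), 0)
            if prior == 0:
                continue  # new hire or already gone: no phantom chains
            current = lookup.get((pid, year), 0)
            if prior - current > drop_weeks and (pid, year - 1) not in flagged:
                events.append(SADEvent(pid, year, current, prior))
                flagged.add((pid, year))
    return events


def events_frame(events: list[SADEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathologist_id": e.pathologist_id,
                "year": e.year,
                "weeks_prior": e.weeks_prior,
                "weeks_current": e.weeks_current,
                "drop": e.drop,
            }
            for e in events
        ],
        columns=["pathologist_id", "year", "weeks_prior", "weeks_current", "drop"],
    )


def sad_rate(
    events: list[SADEvent],
    pathologist_years: pd.DataFrame,
    cumulative_denominator: str = "mean",
) -> SADRateResult:
    """Group-year SAD rates, period averages and the lab-wide period rate.

    Each event is attributed to the pathologist's group in the EVENT year;
    when the pathologist signed nothing that year (so no pathologist-year
    row exists) the prior-year group is used.  Group FTE denominators sum
    over all of the group's signers, and years before the first possible
    event year are excluded from the rate tables.
    """
    if cumulative_denominator not in ("mean", "sum"):
        raise ValueError("cumulative_denominator must be 'mean' or 'sum'")
    py = pathologist_years
    group_of: dict[tuple[str, int], object] = {
        (str(r.pathologist_id), int(r.year)): r.group for r in py.itertuples(index=False)
    }

    years = sorted(py["year"].unique())
    event_years = years[1:]
    groups = sorted(py["group"].unique())

    counts: dict[tuple[object, int], int] = {}
    unattributed = 0
    for e in events:
        grp = group_of.get((e.pathologist_id, e.year))
        if grp is None:
            grp = group_of.get((e.pathologist_id, e.year - 1))
        if grp is None:
            unattributed += 1
            continue
        counts[(grp, e.year)] = counts.get((grp, e.year), 0) + 1
    if unattributed:
        log.warning("%d SAD event(s) could not be attributed to a group", unattributed)

    fte_by_gy = py.groupby(["group", "year"])["fte"].sum()
    rows = []
    for year in event_years:
        for grp in groups:
            fte_total = float(fte_by_gy.get((grp, year), 0.0))
            n = counts.get((grp, year), 0)
            rows.append(
                {
                    "group": grp,
                    "year": int(year),
                    "sad_count": n,
                    "fte_total": fte_total,
                    "sadr": n / fte_total if fte_total > 0 else np.nan,
                }
            )
    yearly = pd.DataFrame(rows, columns=["group", "year", "sad_count", "fte_total", "sadr"])

    period = (
        yearly.groupby("group")
        .agg(sad_count=("sad_count", "sum"), sadr=("sadr", "mean"))
        .reset_index()
    )

    lab_fte_by_year = py.groupby("year")["fte"].sum()
    lab_fte = lab_fte_by_year[lab_fte_by_year.index.isin(event_years)]
    denom = float(lab_fte.mean()) if cumulative_denominator == "mean" else float(lab_fte.sum())
    total_events = int(yearly["sad_count"].sum())
    cumulative = {
        "n_events": total_events,
        "n_years": len(event_years),
        "denominator": denom,
        "rate": total_events / denom if denom > 0 else np.nan,
    }
    return SADRateResult(yearly=yearly, period=period, cumulative=cumulative)


def rescale_period(rate: float, from_years: float, to_years: float) -> float:
    """Rescale a cumulative rate between observation windows.

    E.g. a ~100% rate over 8 years corresponds to 100 × 3/8 = 37.5% over
    a 3-year window, comparable with published 3-year turnover figures.
    """
    if from_years <= 0 or to_years <= 0:
        raise ValueError("period lengths must be positive")
    return rate * to_years / from_years
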