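"""Workload inequality: Gini, Lorenz curve, Hoover index, Robin Hood FTEs.

For nonnegative workloads :math:`x_1..x_n` with mean :math:`\\bar x`:

* plain Gini  :math:`G = \\sum_i\\sum_j |x_i-x_j| / (2 n^2 \\bar x)` —
  0 for perfect equality, :math:`(n-1)/n` when one member holds all;
* bias-corrected Gini multiplies by :math:`n/(n-1)` (the common default
  of reference implementations such as DescTools' ``Gini(unbiased=)``);
* Hoover index :math:`H = \\sum_i |x_i-\\bar x| / (2\\sum_i x_i)` — the
  fraction of total workload that would have to be redistributed to reach
  perfect equality;
* the Lorenz curve is the sorted cumulative-share polyline, satisfying
  :math:`G_{plain} = 1 - 2\\,\\mathrm{area}` under the curve.

``robin_hood_ftes`` translates between-group inequality into staffing
units: with pooled per-FTE workload
:math:`\\bar w = \\sum_g U_g / \\sum_g F_g`, group :math:`g` needs
:math:`\\Delta_g = U_g/\\bar w - F_g` additional FTEs for all groups to
carry equal work per FTE.  Positive = deficit (more staff needed),
negative = surplus; the real-valued adjustments sum to zero by
construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ESTIMATORS = ("plain", "bias_corrected")


def _clean(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if np.any(x < 0):
        raise ValueError("inequality metrics are defined for nonnegative values")
    return x


def gini(values, estimator: str = "plain") -> float:
    """Gini coefficient of nonnegative values.

    Returns NaN (with a warning) for fewer than two values or an all-zero
    vector, where the coefficient is undefined.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    x = _clean(values)
    n = x.size
    if n < 2:
        warnings.warn("Gini undefined for fewer than two values; returning NaN")
        return float("nan")
    total = x.sum()
    if total == 0:
        warnings.warn("Gini undefined for an all-zero vector; returning NaN")
        return float("nan")
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    # Sorted-rank identity for the mean absolute difference formulation.
    g = float(((2 * i - n - 1) * xs).sum() / (n * total))
    if estimator == "bias_corrected":
        g *= n / (n - 1)
    # Provably in [0, 1] for nonnegative inputs (plain <= (n-1)/n, corrected
    # <= 1); only floating-point residue is clipped here.
    return min(max(g, 0.0), 1.0)


def gini_weighted(values, weights, estimator: str = "plain") -> float:
    """Weighted Gini (sensitivity variant; members enter with weights).

    Not used for the headline group tables, where members enter
    unweighted as pro-rata units per FTE.
    """
    x = _clean(values)
    w = np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be nonnegative, same length, not all zero")
    if x.size < 2 or (x * w).sum() == 0:
        warnings.warn("weighted Gini undefined; returning NaN")
        return float("nan")
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    p = ws / ws.sum()
    mu = (xs * p).sum()
    cw = np.cumsum(p)
    # pairwise |xi-xj| expectation via sorted cumulative weights
    g = float((p * xs * (2 * cw - p - 1)).sum() / mu)
    if estimator == "bias_corrected":
        n = x.size
        g *= n / (n - 1)
    return g


def lorenz(values) -> np.ndarray:
    """Lorenz curve points, shape (n+1, 2), from (0,0) to (1,1).

    Values are sorted ascending; point ``k`` is the cumulative population
    share and cumulative units share of the ``k`` smallest members.  An
    all-zero vector degenerates to the diagonal (with a warning).
    """
    x = _clean(values)
    n = x.size
    if n < 1:
        raise ValueError("lorenz requires at least one value")
    xs = np.sort(x)
    total = xs.sum()
    pop = np.arange(n + 1) / n
    if total == 0:
        warnings.warn("all-zero vector: Lorenz curve degenerates to the diagonal")
        return np.column_stack([pop, pop])
    share = np.concatenate([[0.0], np.cumsum(xs) / total])
    return np.column_stack([pop, share])


def lorenz_gini(values) -> float:
    """Plain Gini via the trapezoid area under the Lorenz curve."""
    pts = lorenz(values)
    area = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return 1.0 - 2.0 * area


def hoover(values) -> float:
    """Hoover (Robin Hood) index: share of total that must move to equalize."""
    x = _clean(values)
    if x.size < 1:
        raise ValueError("hoover requires at least one value")
    total = x.sum()
    if total == 0:
        warnings.warn("Hoover undefined for an all-zero vector; returning NaN")
        return float("nan")
    return float(np.abs(x - x.mean()).sum() / (2 * total))


# ---------------------------------------------------------------------------
# Robin Hood FTEs


@dataclass
class RedistributionResult:
    """Per-group FTE adjustments that equalize per-FTE workload.

    ``table`` columns: group, fte_total, units_total, adjustment (real),
    adjustment_int (sum-preserving integers for presentation),
    percent_of_group (adjustment as % of the group's FTEs).
    """

    table: pd.DataFrame
    grand_mean_units_per_fte: float


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _integerize(adjust: np.ndarray) -> np.ndarray:
    """Round half-away-from-zero, then push the residual onto the group
    with the largest absolute adjustment so the integers also sum to 0."""
    ints = np.array([_round_half_away(a) for a in adjust], dtype=int)
    residual = -int(ints.sum())
    if residual:
        ints[int(np.argmax(np.abs(adjust)))] += residual
    return ints


def robin_hood_ftes(group_rows: pd.DataFrame) -> RedistributionResult:
    """FTE redistribution equalizing per-FTE workload across groups.

    ``group_rows`` must carry one row per group for a single year with
    columns ``group``, ``fte_total`` and ``units_total``.  With pooled
    per-FTE workload w̄, each group's adjustment is
    ``units_total / w̄ − fte_total``; applying the real-valued adjustments
    makes every group's per-FTE workload exactly w̄, and they sum to zero.
    """
    needed = {"group", "fte_total", "units_total"}
    if not needed <= set(group_rows.columns):
        raise ValueError(f"group_rows needs columns {sorted(needed)}")
    fte = group_rows["fte_total"].to_numpy(dtype=float)
    units = group_rows["units_total"].to_numpy(dtype=float)
    if np.any(fte <= 0):
        raise ValueError("every group must have fte_total > 0")
    if units.sum() <= 0:
        raise ValueError("redistribution undefined with zero total work")
    wbar = units.sum() / fte.sum()
    adjust = units / wbar - fte
    table = pd.DataFrame(
        {
            "group": group_rows["group"].to_numpy(),
            "fte_total": fte,
            "units_total": units,
            "adjustment": adjust,
            "adjustment_int": _integerize(adjust),
            "percent_of_group": adjust / fte * 100.0,
        }
    )
    return RedistributionResult(table=table, grand_mean_units_per_fte=float(wbar))


def average_redistribution(
    yearly: pd.DataFrame, mode: str = "average_then_round"
) -> pd.DataFrame:
    """Period-average Robin Hood table from yearly redistribution rows.

    ``yearly`` concatenates the per-year ``RedistributionResult.table``s
    with a ``year`` column.  The headline mode averages the real-valued
    yearly adjustments per group and integerizes the averages (so the
    integer row still sums to zero); ``round_then_average`` instead
    averages the yearly integer presentations.
    """
    if mode not in ("average_then_round", "round_then_average"):
        raise ValueError("mode must be 'average_then_round' or 'round_then_average'")
    g = yearly.groupby("group").agg(
        fte_total=("fte_total", "mean"),
        units_total=("units_total", "mean"),
        adjustment=("adjustment", "mean"),
        adjustment_int_mean=("adjustment_int", "mean"),
    ).reset_index()
    if mode == "average_then_round":
        g["adjustment_int"] = _integerize(g["adjustment"].to_numpy())
    else:
        g["adjustment_int"] = [_round_half_away(a) for a in g["adjustment_int_mean"]]
    g["percent_of_group"] = g["adjustment"] / g["fte_total"] * 100.0
    return g.drop(columns=["adjustment_int_mean"])


# ---------------------------------------------------------------------------
# Gini tables over pathologist-years


def gini_table(
    pathologist_years: pd.DataFrame,
    metric: str,
    estimator: str = "bias_corrected",
    full_time_only: bool = True,
    min_fte: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(group, year) Gini of members' pro-rata units, plus period means.

    Members enter unweighted as pro-rata units per FTE.  ``full_time_only``
    keeps members with FTE exactly 1; ``min_fte`` keeps members above the
    threshold.  An "all" row pools every retained member in the year.
    Group-years with fewer than two members yield NaN.
    """
    from .staffing import PRO_RATA_PREFIX  # local import to avoid cycle

    sel = pathologist_years
    if full_time_only:
        sel = sel[sel["fte"] == 1.0]
    if min_fte is not None:
        sel = sel[sel["fte"] > min_fte]
    pcol = PRO_RATA_PREFIX + metric

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # n<2 group-years are reported as NaN
        for year, ydf in sel.groupby("year"):
            for grp, gdf in ydf.groupby("group"):
                rows.append(
                    {
                        "group": grp,
                        "year": int(year),
                        "n": len(gdf),
                        "gini": gini(gdf[pcol].to_numpy(), estimator),
                        "hoover": hoover(gdf[pcol].to_numpy()) if len(gdf) else float("nan"),
                    }
                )
            rows.append(
                {
                    "group": "all",
                    "year": int(year),
                    "n": len(ydf),
                    "gini": gini(ydf[pcol].to_numpy(), estimator),
                    "hoover": hoover(ydf[pcol].to_numpy()) if len(ydf) else float("nan"),
                }
            )
    yearly = pd.DataFrame(rows, columns=["group", "year", "n", "gini", "hoover"])
    period = (
        yearly.drop(columns=["year"]).groupby("group", sort=False).mean(numeric_only=True).reset_index()
    )
    return yearly, period
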