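"""End-to-end orchestration: cases in, paper-style tables and plots out.

``run_pipeline`` takes a :class:`RunConfig` naming either a case table on
disk or a synthetic scenario, applies exclusions, scores the cases under
the active tariff, builds pathologist-years and group summaries, and
derives the four headline tables:

1. group workload summary (yearly + period average of the yearly values),
2. Gini table (full-time-only, plus a >min-FTE variant),
3. Robin Hood FTE redistribution (yearly + period average),
4. SAD events and rates.

Every run is deterministic given its inputs and seed, carries provenance
metadata (schema version, estimator, filters) in a JSON manifest, and
verifies conservation of work: total case units after exclusions must
equal the summed group totals in every year.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .ingest import (
    ConfigurationError,
    ExclusionConfig,
    apply_exclusions,
    read_case_table,
)
from .inequality import average_redistribution, gini_table, robin_hood_ftes
from .sad import detect_sad_events, events_frame, sad_rate
from .scoring import UNITS_PREFIX, WorkloadSchema, score_table
from .staffing import GroupingConfig, build_pathologist_years, group_summary
from .synthetic import SyntheticConfig, generate_lab, grouping_config, synthetic_tariff

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A validation or conservation failure aborting a run."""


@dataclass
class RunConfig:
    """One pipeline run.  Exactly one of ``scenario`` / ``input_path``."""

    scenario: SyntheticConfig | None = None
    input_path: str | Path | None = None
    column_map: Mapping[str, str] | None = None
    dialect: Mapping[str, str] | None = None
    site_org_map: Mapping[str, str] | None = None
    schema: WorkloadSchema | None = None         # defaults to the synthetic tariff
    grouping: GroupingConfig | None = None       # derived from scenario if absent
    exclusions: ExclusionConfig = field(default_factory=ExclusionConfig)
    metric: str = "L4E"
    estimator: str = "bias_corrected"
    min_fte: float = 0.3
    drop_weeks: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.input_path is None):
            raise ConfigurationError("exactly one of scenario/input_path must be set")
        if self.scenario is None and self.grouping is None:
            raise ConfigurationError("file input requires an explicit grouping config")


@dataclass
class ReportBundle:
    """All tables produced by one run, plus the provenance manifest."""

    pathologist_years: pd.DataFrame
    group_yearly: pd.DataFrame
    group_period: pd.DataFrame
    gini_yearly: pd.DataFrame
    gini_period: pd.DataFrame
    gini_yearly_minfte: pd.DataFrame
    gini_period_minfte: pd.DataFrame
    robin_yearly: pd.DataFrame
    robin_period: pd.DataFrame
    sad_events: pd.DataFrame
    sad_yearly: pd.DataFrame
    sad_period: pd.DataFrame
    sad_cumulative: dict
    manifest: dict

    _tables = (
        "pathologist_years",
        "group_yearly",
        "group_period",
        "gini_yearly",
        "gini_period",
        "gini_yearly_minfte",
        "gini_period_minfte",
        "robin_yearly",
        "robin_period",
        "sad_events",
        "sad_yearly",
        "sad_period",
    )

    def write(self, outdir: str | Path, plots: bool = False) -> dict[str, str]:
        """Write CSV tables + manifest (and optionally plots); returns
        relative file name -> sha256 of the written bytes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        checksums: dict[str, str] = {}
        for name in self._tables:
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False, float_format="%.6f")
            checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest = dict(self.manifest)
        manifest["sad_cumulative"] = self.sad_cumulative
        manifest["checksums"] = checksums
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        if plots:
            self.plot(outdir)
        return checksums

    def plot(self, outdir: str | Path) -> list[Path]:
        """FTEs by group-year and units-per-FTE by group-year line plots."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for col, title, fname in (
            ("fte_total", "FTEs by group and year", "fte_by_group_year.png"),
            ("units_per_fte", "Workload units per FTE by group and year", "units_per_fte_by_group_year.png"),
        ):
            pivot = self.group_yearly.pivot(index="year", columns="group", values=col)
            fig, ax = plt.subplots(figsize=(7, 4.5))
            for grp in pivot.columns:
                ax.plot(pivot.index, pivot[grp], marker="o", label=f"group {grp}")
            ax.set_xlabel("year")
            ax.set_ylabel(col.replace("_", " "))
            ax.set_title(title)
            ax.legend()
            fig.tight_layout()
            path = outdir / fname
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
        return written


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute the full analysis; see the module docstring."""
    schema = cfg.schema or synthetic_tariff()
    if cfg.metric not in schema.metric_names:
        raise ConfigurationError(f"metric {cfg.metric!r} not in schema {schema.metric_names}")

    ledger = None
    if cfg.scenario is not None:
        cases, ledger = generate_lab(cfg.scenario)
        grouping = cfg.grouping or grouping_config(cfg.scenario)
        n_read, n_rejected = len(cases), 0
    else:
        if not cfg.column_map:
            raise ConfigurationError("file input requires a column_map")
        cases, report = read_case_table(
            cfg.input_path, cfg.column_map, cfg.dialect, cfg.site_org_map
        )
        grouping = cfg.grouping
        n_read, n_rejected = report.n_rows, len(report.rejects)

    kept, excl_report = apply_exclusions(cases, cfg.exclusions)
    if not kept:
        raise PipelineError("no cases remain after exclusions")

    scored, score_report = score_table(kept, schema)
    pyears = build_pathologist_years(scored, grouping, metrics=list(schema.metric_names))

    group_yearly, group_period = group_summary(pyears, cfg.metric)
    _check_conservation(scored, group_yearly, cfg.metric)

    gini_yearly, gini_period = gini_table(
        pyears, cfg.metric, cfg.estimator, full_time_only=True
    )
    gini_yearly_minfte, gini_period_minfte = gini_table(
        pyears, cfg.metric, cfg.estimator, full_time_only=False, min_fte=cfg.min_fte
    )

    robin_parts = []
    for year, ydf in group_yearly.groupby("year"):
        res = robin_hood_ftes(ydf)
        t = res.table.copy()
        t.insert(0, "year", int(year))
        robin_parts.append(t)
    robin_yearly = pd.concat(robin_parts, ignore_index=True)
    robin_period = average_redistribution(robin_yearly)

    weeks = pyears[["pathologist_id", "year", "weeks_signed"]]
    y0, y1 = cfg.exclusions.study_years
    events = detect_sad_events(
        weeks, drop_weeks=cfg.drop_weeks, first_year=y0, last_year=y1
    )
    rates = sad_rate(events, pyears)

    manifest = {
        "labequity_version": __version__,
        "schema_version": schema.version_tag,
        "metric": cfg.metric,
        "estimator": cfg.estimator,
        "min_fte": cfg.min_fte,
        "drop_weeks": cfg.drop_weeks,
        "seed": cfg.seed,
        "input": "synthetic" if cfg.scenario is not None else str(cfg.input_path),
        "n_cases_read": n_read,
        "n_rows_rejected": n_rejected,
        "n_cases_excluded": excl_report.total_removed,
        "n_cases_analyzed": len(kept),
        "n_cases_unmatched": score_report.n_unmatched,
        "excluded_classes": sorted(cfg.exclusions.excluded_classes),
        "study_years": list(cfg.exclusions.study_years),
    }
    return ReportBundle(
        pathologist_years=pyears,
        group_yearly=group_yearly,
        group_period=group_period,
        gini_yearly=gini_yearly,
        gini_period=gini_period,
        gini_yearly_minfte=gini_yearly_minfte,
        gini_period_minfte=gini_period_minfte,
        robin_yearly=robin_yearly,
        robin_period=robin_period,
        sad_events=events_frame(events),
        sad_yearly=rates.yearly,
        sad_period=rates.period,
        sad_cumulative=rates.cumulative,
        manifest=manifest,
    )


def _check_conservation(scored: pd.DataFrame, group_yearly: pd.DataFrame, metric: str) -> None:
    """Sum of case units per year must equal the summed group totals."""
    col = UNITS_PREFIX + metric
    by_year = scored.groupby(pd.to_datetime(scored["signout_date"]).dt.year)[col].sum()
    grouped = group_yearly.groupby("year")["units_total"].sum()
    for year, total in by_year.items():
        if abs(total - grouped.get(year, 0.0)) > 1e-6 * max(1.0, abs(total)):
            raise PipelineError(
                f"conservation violated in {year}: case units {total} != group units "
                f"{grouped.get(year, 0.0)}"
            )
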