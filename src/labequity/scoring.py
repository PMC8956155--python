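"""Convert case attributes into workload units under a declarative tariff.

A :class:`WorkloadSchema` maps case attributes onto one or more workload
metrics — e.g. point-based professional-effort units (L4E-style), shadow
billing fees, block counts, or a plain case count.  Each rule carries a
match predicate on case fields and a linear contribution per metric::

    units = base + per_specimen * specimen_count + per_block * block_count
            + sum_a per_ancillary[a] * ancillary_count[a]

Rules use FIRST-MATCH semantics: rule order is significant and a case is
scored by the first rule whose predicate it satisfies, mirroring tariff
tables in which each case falls in exactly one category.  Cases carrying
``precomputed_units`` for a metric keep the precomputed value for that
metric regardless of the rules (pass-through mode).

The packaged example schema (``schemas/illustrative_l4e.yaml``) is
ILLUSTRATIVE ONLY: its point values are invented for demonstration and do
not reproduce any national tariff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ingest import (
    ANCILLARY_PREFIX,
    PRECOMPUTED_PREFIX,
    CaseRecord,
    ConfigurationError,
    cases_to_frame,
)

log = logging.getLogger(__name__)

UNITS_PREFIX = "units_"

_MATCH_KEYS = {"case_class", "site", "specimen_min", "specimen_max", "has_ancillary"}


class ScoringError(ValueError):
    """A case could not be scored under the active schema."""


@dataclass(frozen=True)
class Contribution:
    """Linear per-metric contribution of one rule."""

    base: float = 0.0
    per_specimen: float = 0.0
    per_block: float = 0.0
    per_ancillary: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.base, self.per_specimen, self.per_block, *self.per_ancillary.values()]
        if any(v < 0 for v in vals):
            raise ConfigurationError("tariff contributions must be nonnegative")


@dataclass(frozen=True)
class Rule:
    """Match predicate plus per-metric contributions."""

    name: str
    match: Mapping[str, object] = field(default_factory=dict)
    contributions: Mapping[str, Contribution] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.match) - _MATCH_KEYS
        if unknown:
            raise ConfigurationError(
                f"rule {self.name!r}: unknown match keys {sorted(unknown)}"
            )

    def mask(self, frame: pd.DataFrame) -> np.ndarray:
        """Boolean row mask of cases matching this rule's predicate."""
        m = np.ones(len(frame), dtype=bool)
        if "case_class" in self.match:
            want = self.match["case_class"]
            want = [want] if isinstance(want, str) else list(want)
            m &= frame["case_class"].isin(want).to_numpy()
        if "site" in self.match:
            want = self.match["site"]
            want = [want] if isinstance(want, str) else list(want)
            m &= frame["site"].isin(want).to_numpy()
        if "specimen_min" in self.match:
            m &= (frame["specimen_count"] >= int(self.match["specimen_min"])).to_numpy()
        if "specimen_max" in self.match:
            m &= (frame["specimen_count"] <= int(self.match["specimen_max"])).to_numpy()
        if "has_ancillary" in self.match:
            col = ANCILLARY_PREFIX + str(self.match["has_ancillary"])
            if col in frame.columns:
                m &= (frame[col] > 0).to_numpy()
            else:
                m &= False
        return m


@dataclass(frozen=True)
class WorkloadSchema:
    """Ordered tariff over one or more workload metrics.

    ``unmatched_policy`` decides what happens to a case no rule matches
    (and whose metrics are not all precomputed): ``"error"`` aborts naming
    the case, ``"zero"`` scores a zero vector and counts a warning.
    """

    metric_names: tuple[str, ...]
    rules: tuple[Rule, ...]
    version_tag: str = "unversioned"
    unmatched_policy: str = "error"

    def __post_init__(self) -> None:
        if not self.metric_names:
            raise ConfigurationError("schema must declare at least one metric")
        if self.unmatched_policy not in ("error", "zero"):
            raise ConfigurationError("unmatched_policy must be 'error' or 'zero'")
        for rule in self.rules:
            extra = set(rule.contributions) - set(self.metric_names)
            if extra:
                raise ConfigurationError(
                    f"rule {rule.name!r} contributes to undeclared metrics {sorted(extra)}"
                )


@dataclass
class ScoreReport:
    """Bookkeeping from :func:`score_frame`."""

    n_cases: int = 0
    n_unmatched: int = 0
    n_precomputed: int = 0


MetricVector = dict[str, float]


# ---------------------------------------------------------------------------


def score_frame(
    frame: pd.DataFrame, schema: WorkloadSchema
) -> tuple[pd.DataFrame, ScoreReport]:
    """Score every case row, adding one ``units_<metric>`` column per metric.

    Deterministic, first-match rule semantics; precomputed ``pre_<metric>``
    values override the tariff for that metric.  Returns a scored copy and
    a :class:`ScoreReport`.
    """
    out = frame.copy()
    n = len(out)
    matched = np.zeros(n, dtype=bool)
    units = {m: np.zeros(n) for m in schema.metric_names}

    spec = out["specimen_count"].to_numpy(dtype=float)
    blocks = out["block_count"].to_numpy(dtype=float)

    for rule in schema.rules:
        sel = ~matched & rule.mask(out)
        if not sel.any():
            continue
        for metric, contrib in rule.contributions.items():
            v = np.full(sel.sum(), contrib.base)
            if contrib.per_specimen:
                v += contrib.per_specimen * spec[sel]
            if contrib.per_block:
                v += contrib.per_block * blocks[sel]
            for name, w in contrib.per_ancillary.items():
                col = ANCILLARY_PREFIX + name
                if col in out.columns:
                    v += w * out[col].to_numpy(dtype=float)[sel]
            units[metric][sel] += v
        matched |= sel

    report = ScoreReport(n_cases=n)

    # Precomputed values win for their metric; a case precomputed on every
    # metric counts as matched even if no rule covers it.
    pre_all = np.ones(n, dtype=bool) if schema.metric_names else np.zeros(n, dtype=bool)
    any_pre = np.zeros(n, dtype=bool)
    for metric in schema.metric_names:
        col = PRECOMPUTED_PREFIX + metric
        if col in out.columns:
            have = out[col].notna().to_numpy()
            units[metric] = np.where(have, out[col].to_numpy(dtype=float), units[metric])
            pre_all &= have
            any_pre |= have
        else:
            pre_all &= False
    report.n_precomputed = int(any_pre.sum())

    unmatched = ~matched & ~pre_all
    report.n_unmatched = int(unmatched.sum())
    if report.n_unmatched:
        if schema.unmatched_policy == "error":
            bad = out.loc[unmatched, "case_id"].iloc[0]
            raise ScoringError(
                f"{report.n_unmatched} case(s) match no tariff rule "
                f"(first: case_id={bad!r}) under policy 'error'"
            )
        log.warning("%d unmatched case(s) scored as zero", report.n_unmatched)

    for metric in schema.metric_names:
        out[UNITS_PREFIX + metric] = units[metric]
    return out, report


def score_case(case: CaseRecord, schema: WorkloadSchema) -> MetricVector:
    """Score a single case, returning metric -> units."""
    scored, _ = score_frame(cases_to_frame([case]), schema)
    return {m: float(scored[UNITS_PREFIX + m].iloc[0]) for m in schema.metric_names}


def score_table(
    cases: Sequence[CaseRecord] | pd.DataFrame, schema: WorkloadSchema
) -> tuple[pd.DataFrame, ScoreReport]:
    """Score a case set (records or canonical frame) elementwise."""
    frame = cases if isinstance(cases, pd.DataFrame) else cases_to_frame(list(cases))
    if len(frame) == 0:
        out = frame.copy()
        for m in schema.metric_names:
            out[UNITS_PREFIX + m] = pd.Series(dtype=float)
        return out, ScoreReport(n_cases=0)
    return score_frame(frame, schema)


def totals(scored: pd.DataFrame, schema: WorkloadSchema) -> MetricVector:
    """Total units per metric over a scored frame."""
    return {m: float(scored[UNITS_PREFIX + m].sum()) for m in schema.metric_names}


# ---------------------------------------------------------------------------
# YAML schema files


def schema_from_dict(cfg: Mapping) -> WorkloadSchema:
    rules = []
    for r in cfg.get("rules", ()):
        contribs = {}
        for metric, c in (r.get("contributions") or {}).items():
            contribs[metric] = Contribution(
                base=float(c.get("base", 0.0)),
                per_specimen=float(c.get("per_specimen", 0.0)),
                per_block=float(c.get("per_block", 0.0)),
                per_ancillary={k: float(v) for k, v in (c.get("per_ancillary") or {}).items()},
            )
        rules.append(Rule(name=str(r.get("name", "rule")), match=r.get("match") or {}, contributions=contribs))
    return WorkloadSchema(
        metric_names=tuple(cfg.get("metrics", ())),
        rules=tuple(rules),
        version_tag=str(cfg.get("version", "unversioned")),
        unmatched_policy=str(cfg.get("unmatched_policy", "error")),
    )


def schema_from_yaml(path: str | Path) -> WorkloadSchema:
    """Load a tariff schema from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return schema_from_dict(cfg)


def illustrative_schema() -> WorkloadSchema:
    """The packaged example tariff (invented point values, for demos/tests)."""
    ref = resources.files("labequity").joinpath("schemas/illustrative_l4e.yaml")
    return schema_from_dict(yaml.safe_load(ref.read_text()))
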