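"""Read, validate and filter case-level sign-out tables.

A laboratory information system export is expected as a flat delimited
table with one row per finalized report.  Column names in the source file
are mapped onto canonical field names through a user-supplied column map,
so exports from different systems can be ingested without editing the
file.  Rows that cannot be validated (unparseable sign-out date, empty
pathologist pseudonym, negative counts, unknown case class) are rejected
individually and reported with their row index; they are never silently
dropped.

Two case classes are routinely excluded before any workload analysis:
``review`` (cancer-review cases re-examined in-house) and
``external_referral`` (cases referred in from outside laboratories),
because their attributes are incomplete in typical exports.  Exclusion is
driven by :class:`ExclusionConfig` and every removal is tallied per case
class and calendar year.
"""

from __future__ import annotations

import datetime as dt
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: Recognized case classes.
CASE_CLASSES = ("surgical", "cytology", "review", "external_referral")

#: Canonical fields that the column map must cover.
MANDATORY_FIELDS = ("pathologist_id", "signout_date", "site", "case_class")

#: Canonical fields that may be omitted (sensible defaults apply).
OPTIONAL_FIELDS = ("case_id", "organization", "specimen_count", "block_count")

#: DataFrame column prefixes for ancillary-test counts and precomputed units.
ANCILLARY_PREFIX = "anc_"
PRECOMPUTED_PREFIX = "pre_"

#: Sentinel year label for removals outside the study window.
OUT_OF_WINDOW = "out_of_window"


class ConfigurationError(ValueError):
    """Raised when a config (column map, schema, scenario) is unusable."""


@dataclass(frozen=True)
class CaseRecord:
    """One finalized pathology report.

    ``ancillary_counts`` maps named ancillary tests (e.g. immunostains) to
    nonnegative counts.  ``precomputed_units`` optionally carries workload
    units already computed upstream per metric; scoring passes these
    through untouched.
    """

    case_id: str
    pathologist_id: str
    signout_date: dt.date
    site: str
    organization: str
    case_class: str
    specimen_count: int = 0
    block_count: int = 0
    ancillary_counts: Mapping[str, int] = field(default_factory=dict)
    precomputed_units: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.pathologist_id:
            raise ValueError("pathologist_id must be non-empty")
        if self.specimen_count < 0 or self.block_count < 0:
            raise ValueError("specimen and block counts must be >= 0")
        if any(v < 0 for v in self.ancillary_counts.values()):
            raise ValueError("ancillary counts must be >= 0")
        if self.case_class not in CASE_CLASSES:
            raise ValueError(f"unknown case_class {self.case_class!r}")


@dataclass(frozen=True)
class ExclusionConfig:
    """Which case classes to drop and which calendar years to keep."""

    excluded_classes: frozenset[str] = frozenset({"review", "external_referral"})
    study_years: tuple[int, int] = (2011, 2019)

    def __post_init__(self) -> None:
        y0, y1 = self.study_years
        if y1 < y0:
            raise ConfigurationError("study_years range is empty")


@dataclass
class ValidationReport:
    """Outcome of reading one case table."""

    n_rows: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_valid(self) -> int:
        return self.n_rows - len(self.rejects)

    @property
    def ok(self) -> bool:
        return not self.rejects


@dataclass
class ExclusionReport:
    """Per-(reason, year) removal tallies from :func:`apply_exclusions`."""

    removed: dict[tuple[str, int | str], int] = field(default_factory=dict)

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"reason": k[0], "year": k[1], "n_removed": v}
            for k, v in sorted(self.removed.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))
        ]
        return pd.DataFrame(rows, columns=["reason", "year", "n_removed"])


# ---------------------------------------------------------------------------
# DataFrame <-> record conversion


def cases_to_frame(cases: Sequence[CaseRecord]) -> pd.DataFrame:
    """Build the canonical case DataFrame from records.

    Ancillary counts become ``anc_<name>`` columns and precomputed units
    become ``pre_<metric>`` columns (NaN where absent).
    """
    anc_names: set[str] = set()
    pre_names: set[str] = set()
    for c in cases:
        anc_names.update(c.ancillary_counts)
        if c.precomputed_units:
            pre_names.update(c.precomputed_units)

    data: dict[str, list] = {
        "case_id": [c.case_id for c in cases],
        "pathologist_id": [c.pathologist_id for c in cases],
        "signout_date": [c.signout_date for c in cases],
        "site": [c.site for c in cases],
        "organization": [c.organization for c in cases],
        "case_class": [c.case_class for c in cases],
        "specimen_count": [c.specimen_count for c in cases],
        "block_count": [c.block_count for c in cases],
    }
    for name in sorted(anc_names):
        data[ANCILLARY_PREFIX + name] = [c.ancillary_counts.get(name, 0) for c in cases]
    for name in sorted(pre_names):
        data[PRECOMPUTED_PREFIX + name] = [
            (c.precomputed_units or {}).get(name, float("nan")) for c in cases
        ]
    frame = pd.DataFrame(data)
    frame["signout_date"] = pd.to_datetime(frame["signout_date"])
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[CaseRecord]:
    """Inverse of :func:`cases_to_frame`."""
    anc_cols = [c for c in frame.columns if c.startswith(ANCILLARY_PREFIX)]
    pre_cols = [c for c in frame.columns if c.startswith(PRECOMPUTED_PREFIX)]
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        anc = {c[len(ANCILLARY_PREFIX):]: int(d[c]) for c in anc_cols if d[c]}
        pre = {
            c[len(PRECOMPUTED_PREFIX):]: float(d[c])
            for c in pre_cols
            if pd.notna(d[c])
        }
        records.append(
            CaseRecord(
                case_id=str(d["case_id"]),
                pathologist_id=str(d["pathologist_id"]),
                signout_date=pd.Timestamp(d["signout_date"]).date(),
                site=str(d["site"]),
                organization=str(d["organization"]),
                case_class=str(d["case_class"]),
                specimen_count=int(d["specimen_count"]),
                block_count=int(d["block_count"]),
                ancillary_counts=anc,
                precomputed_units=pre or None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Reading delimited tables


def read_case_table(
    path: str | Path,
    column_map: Mapping[str, str],
    dialect: Mapping[str, str] | None = None,
    site_org_map: Mapping[str, str] | None = None,
) -> tuple[list[CaseRecord], ValidationReport]:
    """Read a delimited sign-out table into validated :class:`CaseRecord`s.

    Parameters
    ----------
    path:
        Delimited text file, one row per finalized report.
    column_map:
        Canonical field -> source column name.  Must cover
        :data:`MANDATORY_FIELDS`.  Ancillary-count columns are declared as
        ``"ancillary.<name>"`` keys and precomputed unit columns as
        ``"units.<metric>"`` keys.
    dialect:
        Optional ``{"sep": ..., "quotechar": ...}`` overrides (RFC-4180
        comma/double-quote by default).
    site_org_map:
        Site -> organization lookup, used when the table itself has no
        organization column.

    Returns
    -------
    (records, report):
        Well-formed rows in original order, and a
        :class:`ValidationReport` listing each rejected row index with the
        reason.  Malformed rows never abort the read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    missing = [f for f in MANDATORY_FIELDS if f not in column_map]
    if missing:
        raise ConfigurationError(
            f"column_map is missing mandatory canonical fields: {', '.join(missing)}"
        )

    opts = {"sep": ",", "quotechar": '"'}
    if dialect:
        opts.update(dialect)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, **opts)

    absent = [src for src in column_map.values() if src not in raw.columns]
    if absent:
        raise ConfigurationError(
            f"source table {path.name} lacks mapped columns: {', '.join(absent)}"
        )

    report = ValidationReport(n_rows=len(raw))
    records: list[CaseRecord] = []
    for i in range(len(raw)):
        row = raw.iloc[i]

        def get(canon: str, default: str = "") -> str:
            src = column_map.get(canon)
            return str(row[src]).strip() if src is not None else default

        date_text = get("signout_date")
        ts = pd.to_datetime(date_text, errors="coerce")
        if pd.isna(ts):
            report.rejects.append((i, f"unparseable signout_date {date_text!r}"))
            continue
        pid = get("pathologist_id")
        if not pid:
            report.rejects.append((i, "empty pathologist_id"))
            continue
        case_class = get("case_class")
        if case_class not in CASE_CLASSES:
            report.rejects.append((i, f"unknown case_class {case_class!r}"))
            continue

        counts = {}
        bad_count = False
        for fld in ("specimen_count", "block_count"):
            text = get(fld, "0") or "0"
            try:
                val = int(float(text))
            except ValueError:
                report.rejects.append((i, f"unparseable {fld} {text!r}"))
                bad_count = True
                break
            if val < 0:
                report.rejects.append((i, f"negative {fld} {val}"))
                bad_count = True
                break
            counts[fld] = val
        if bad_count:
            continue

        anc = {}
        pre = {}
        skip = False
        for canon, src in column_map.items():
            if canon.startswith("ancillary."):
                text = str(row[src]).strip() or "0"
                try:
                    v = int(float(text))
                except ValueError:
                    report.rejects.append((i, f"unparseable ancillary count {text!r}"))
                    skip = True
                    break
                if v < 0:
                    report.rejects.append((i, f"negative ancillary count {v}"))
                    skip = True
                    break
                anc[canon.split(".", 1)[1]] = v
            elif canon.startswith("units."):
                text = str(row[src]).strip()
                if text:
                    pre[canon.split(".", 1)[1]] = float(text)
        if skip:
            continue

        site = get("site")
        org = get("organization")
        if not org and site_org_map:
            org = site_org_map.get(site, "")
        records.append(
            CaseRecord(
                case_id=get("case_id") or f"row{i}",
                pathologist_id=pid,
                signout_date=ts.date(),
                site=site,
                organization=org,
                case_class=case_class,
                specimen_count=counts["specimen_count"],
                block_count=counts["block_count"],
                ancillary_counts=anc,
                precomputed_units=pre or None,
            )
        )

    for idx, reason in report.rejects:
        log.warning("rejected row %d of %s: %s", idx, path.name, reason)
    return records, report


def apply_exclusions(
    cases: Sequence[CaseRecord], cfg: ExclusionConfig
) -> tuple[list[CaseRecord], ExclusionReport]:
    """Drop excluded case classes and out-of-window years.

    Every removal is tallied per (reason, calendar year); the operation is
    idempotent and ``len(input) == len(output) + report.total_removed``.
    """
    y0, y1 = cfg.study_years
    removed: Counter = Counter()
    kept: list[CaseRecord] = []
    for c in cases:
        year = c.signout_date.year
        if c.case_class in cfg.excluded_classes:
            removed[(c.case_class, year)] += 1
        elif not (y0 <= year <= y1):
            removed[(OUT_OF_WINDOW, year)] += 1
        else:
            kept.append(c)
    report = ExclusionReport(removed=dict(removed))
    if report.total_removed:
        log.info(
            "excluded %d of %d cases (%s)",
            report.total_removed,
            len(cases),
            dict(removed),
        )
    return kept, report


# ---------------------------------------------------------------------------
# Config files and archives


def load_ingest_config(path: str | Path) -> dict:
    """Load a YAML/JSON ingest config (column map, site map, exclusions)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    out = {
        "column_map": cfg.get("column_map", {}),
        "site_org_map": cfg.get("site_org_map", {}),
        "dialect": cfg.get("dialect"),
    }
    if "exclusions" in cfg:
        exc = cfg["exclusions"]
        out["exclusions"] = ExclusionConfig(
            excluded_classes=frozenset(exc.get("excluded_classes", ())),
            study_years=tuple(exc.get("study_years", (2011, 2019))),
        )
    return out


def extract_archive(archive: str | Path, dest: str | Path) -> list[Path]:
    """Unpack a 7Z container of case tables into ``dest``.

    Requires the optional ``py7zr`` dependency; raises
    :class:`ConfigurationError` when it is not installed.  The extracted
    tables must then be read with :func:`read_case_table` and a column map
    confirmed by the user.
    """
    try:
        import py7zr  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ConfigurationError(
            "7Z extraction requires the optional 'py7zr' package; install it "
            "or unpack the archive manually and point read_case_table at the "
            "contained table"
        ) from exc
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    with py7zr.SevenZipFile(archive) as z:  # pragma: no cover
        z.extractall(dest)
    return sorted(dest.rglob("*"))  # pragma: no cover
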