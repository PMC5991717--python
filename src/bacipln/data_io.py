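"""Reading, validation and filtering of gill-net catch records.

The observation unit is one gill-net set: one deployment of a standardized
gill net at a (lake, station) location in a given year, yielding an integer
count of fish of one species.  A :class:`CatchTable` wraps a pandas
DataFrame of such records together with a provenance log that tracks every
filter applied and how many records it removed, so that
``input = retained + removed`` can always be audited.

Three inclusion filters mirror the study design of long-term BACI
monitoring of the Rainy-Namakan reservoir complex:

* *station consistency* — because sampling locations drifted over the
  decades, only stations sampled in every year their lake was sampled
  (within the 1990-2014 study window) are retained;
* *lake exclusions* — lake-specific year ranges with known methodology
  problems or missing data are dropped (by default, Namakan Lake before
  1993 and Sand Point Lake 1992);
* *period assignment* — records are labelled Pre (1990-1999) or Post
  (2005-2014); the 2000-2004 gap implements a five-year lag between the
  water-level management change and the years treated as "after", because
  adult fish recruit to the gear at age 2-3.

Each filter is a pure row predicate once its *plan* (the keep/drop decision
context) is fixed.  The station-consistency plan is computed once from the
raw table and is exclusion-aware, so the three default filters commute: the
pipeline result does not depend on the order in which they run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_COLUMNS",
    "DEFAULT_EXCLUSIONS",
    "DEFAULT_PERIODS",
    "DEFAULT_ROLES",
    "STUDY_WINDOW",
    "CatchTable",
    "PeriodDefinition",
    "SchemaError",
    "ValidationError",
    "apply_lake_exclusions",
    "assign_periods",
    "filter_consistent_stations",
    "plan_station_filter",
    "read_catch_table",
    "write_canonical_csv",
]

#: Canonical column order of a catch table.
CANONICAL_COLUMNS = ["lake", "station", "year", "species", "count", "role"]

#: Inclusive study window of the monitoring program.
STUDY_WINDOW = (1990, 2014)

#: Default lake-specific exclusions: Namakan Lake data before 1993
#: (methodology change) and Sand Point Lake 1992 (no data provided).
DEFAULT_EXCLUSIONS: list[tuple[str, tuple[int, int]]] = [
    ("Namakan Lake", (1990, 1992)),
    ("Sand Point Lake", (1992, 1992)),
]

#: Control/impact designation of the six study lakes.
DEFAULT_ROLES: dict[str, str] = {
    "Lake of the Woods": "control",
    "Lake Vermilion": "control",
    "Lake Kabetogama": "impact",
    "Namakan Lake": "impact",
    "Rainy Lake": "impact",
    "Sand Point Lake": "impact",
}


class SchemaError(ValueError):
    """A required column is missing or the file layout is unusable."""


class ValidationError(ValueError):
    """A record violates a value constraint (e.g. a negative count)."""


@dataclass(frozen=True)
class PeriodDefinition:
    """Inclusive year ranges defining the Before and After periods.

    Defaults encode the study's five-year lag: before 1990-1999, after
    2005-2014, with 2000-2004 assigned to neither period.
    """

    before: tuple[int, int] = (1990, 1999)
    after: tuple[int, int] = (2005, 2014)

    def __post_init__(self) -> None:
        b0, b1 = self.before
        a0, a1 = self.after
        if b0 > b1 or a0 > a1:
            raise ValueError("period year ranges must be non-decreasing")
        if b1 >= a0:
            raise ValueError("before period must strictly precede after period")

    def label(self, year: int) -> str | None:
        """Return ``'pre'``, ``'post'`` or None for a calendar year."""
        if self.before[0] <= year <= self.before[1]:
            return "pre"
        if self.after[0] <= year <= self.after[1]:
            return "post"
        return None


DEFAULT_PERIODS = PeriodDefinition()


@dataclass
class CatchTable:
    """Gill-net catch records plus a provenance/filter log.

    ``records`` holds one row per gill-net set x species with the canonical
    columns (``lake, station, year, species, count, role`` and, after
    :func:`assign_periods`, ``period``).  ``provenance`` is a list of dicts,
    one per ingestion or filter step, each recording the action, counts in
    and removed, and a human-readable detail string.
    """

    records: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def derive(self, records: pd.DataFrame, entry: dict) -> "CatchTable":
        """New table with one provenance entry appended."""
        entry = dict(entry)
        entry.setdefault("n_in", len(self.records))
        entry.setdefault("n_out", len(records))
        entry.setdefault("n_removed", entry["n_in"] - entry["n_out"])
        return CatchTable(records.reset_index(drop=True), [*self.provenance, entry])

    def filter_log(self) -> str:
        """Plain-text rendering of the provenance log."""
        lines = []
        for e in self.provenance:
            lines.append(
                f"{e.get('action', '?')}: in={e.get('n_in', '?')} "
                f"removed={e.get('n_removed', '?')} out={e.get('n_out', '?')}"
                + (f" | {e['detail']}" if e.get("detail") else "")
            )
        return "\n".join(lines)


def _validate_counts(counts: pd.Series) -> pd.Series:
    """Coerce a count column to non-negative integers, or raise."""
    numeric = pd.to_numeric(counts, errors="coerce")
    bad = numeric.isna() | (numeric < 0) | (numeric != numeric.round())
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        # 1-based data rows, header excluded
        raise ValidationError(
            f"count must be a non-negative integer; offending value "
            f"{counts.iloc[idx]!r} at row {idx + 1}"
        )
    return numeric.astype(int)


def read_catch_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    roles: Mapping[str, str] | None = None,
    sheet: int | str = 0,
) -> CatchTable:
    """Read gill-net catch records from a CSV or XLSX file.

    Parameters
    ----------
    path:
        Source file; ``.xlsx``/``.xls`` are read via openpyxl, anything
        else as CSV with a header row.
    schema:
        Mapping from canonical column names (``lake``, ``station``,
        ``year``, ``species``, ``count``, optionally ``role``) to the
        column names used in the file.  Unmapped canonical names are
        looked up verbatim.
    roles:
        Lake -> ``control``/``impact`` map used when the file has no role
        column.  Defaults to the six study lakes.
    sheet:
        Worksheet to read when the source is a workbook.

    Returns
    -------
    CatchTable
        One record per input row, columns canonicalised, provenance
        recording the source path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if path.suffix.lower() in {".xlsx", ".xls"}:
        raw = pd.read_excel(path, sheet_name=sheet)
    else:
        raw = pd.read_csv(path)

    schema = dict(schema or {})
    colmap: dict[str, str] = {}
    missing: list[str] = []
    for canon in ["lake", "station", "year", "species", "count"]:
        source = schema.get(canon, canon)
        if source not in raw.columns:
            missing.append(f"{canon!r} (looked for column {source!r})")
        else:
            colmap[canon] = source
    if missing:
        raise SchemaError("missing required column(s): " + ", ".join(missing))

    df = pd.DataFrame({canon: raw[src] for canon, src in colmap.items()})
    # Dates are truncated to calendar years; the surveys are annual.
    if pd.api.types.is_datetime64_any_dtype(df["year"]):
        df["year"] = df["year"].dt.year
    try:
        df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    except (ValueError, TypeError):
        df["year"] = pd.to_datetime(df["year"], errors="raise").dt.year.astype(int)
    df["count"] = _validate_counts(df["count"])
    df["lake"] = df["lake"].astype(str)
    df["station"] = df["station"].astype(str)
    df["species"] = df["species"].astype(str)

    role_src = schema.get("role", "role")
    if role_src in raw.columns:
        df["role"] = raw[role_src].astype(str)
    else:
        role_map = dict(roles or DEFAULT_ROLES)
        df["role"] = df["lake"].map(role_map)
        if df["role"].isna().any():
            unknown = sorted(df.loc[df["role"].isna(), "lake"].unique())
            raise SchemaError(
                "no role column and no role mapping for lake(s): "
                + ", ".join(unknown)
            )
    bad_roles = set(df["role"].unique()) - {"control", "impact"}
    if bad_roles:
        raise ValidationError(f"role must be control or impact, got {sorted(bad_roles)}")

    table = CatchTable(df[CANONICAL_COLUMNS].reset_index(drop=True))
    table.provenance.append(
        {
            "action": "read",
            "detail": f"source={path.name}",
            "n_in": len(df),
            "n_out": len(df),
            "n_removed": 0,
        }
    )
    return table


def _excluded_years(
    lake: str, rules: Sequence[tuple[str, tuple[int, int]]]
) -> set[int]:
    out: set[int] = set()
    for rule_lake, (y0, y1) in rules:
        if rule_lake == lake:
            out.update(range(y0, y1 + 1))
    return out


def plan_station_filter(
    table: CatchTable,
    mode: str = "strict",
    exclusions: Sequence[tuple[str, tuple[int, int]]] | None = None,
    window: tuple[int, int] = STUDY_WINDOW,
    periods: PeriodDefinition | None = None,
) -> set[tuple[str, str]]:
    """Decide which (lake, station) pairs survive the consistency rule.

    ``strict`` (default): a station is kept iff it was sampled in every
    year its lake was sampled within the study window, ignoring years the
    exclusion rules remove for that lake.  ``per-period`` (looser): kept
    iff sampled in at least one year of each period.

    The plan is computed once from the table it is given; applying it is a
    pure row predicate, which is what makes the default filters commute.
    """
    if mode not in {"strict", "per-period"}:
        raise ValueError(f"unknown station-consistency mode {mode!r}")
    exclusions = DEFAULT_EXCLUSIONS if exclusions is None else exclusions
    df = table.records
    lo, hi = window
    in_window = df[(df["year"] >= lo) & (df["year"] <= hi)]
    keep: set[tuple[str, str]] = set()
    station_years = in_window.groupby(["lake", "station"])["year"].agg(set)
    lake_years = in_window.groupby("lake")["year"].agg(set)
    if mode == "strict":
        for (lake, station), years in station_years.items():
            required = set(lake_years[lake]) - _excluded_years(lake, exclusions)
            if required <= set(years):
                keep.add((lake, station))
    else:
        periods = periods or DEFAULT_PERIODS
        for (lake, station), years in station_years.items():
            labels = {periods.label(y) for y in years}
            if "pre" in labels and "post" in labels:
                keep.add((lake, station))
    return keep


def filter_consistent_stations(
    table: CatchTable,
    mode: str = "strict",
    plan: set[tuple[str, str]] | None = None,
    exclusions: Sequence[tuple[str, tuple[int, int]]] | None = None,
    window: tuple[int, int] = STUDY_WINDOW,
    periods: PeriodDefinition | None = None,
) -> CatchTable:
    """Retain only records from consistently sampled stations.

    When ``plan`` is None it is computed from this table via
    :func:`plan_station_filter`; pipelines that need order-independence
    compute the plan once from the raw table and pass it here.
    """
    if plan is None:
        plan = plan_station_filter(table, mode, exclusions, window, periods)
    df = table.records
    keys = list(zip(df["lake"], df["station"]))
    mask = np.array([k in plan for k in keys], dtype=bool)
    removed_stations = sorted({k for k, ok in zip(keys, mask) if not ok})
    if mask.sum() == 0 and len(df) > 0:
        logger.warning("station-consistency filter removed every record")
    detail = f"mode={mode}; removed stations: " + (
        ", ".join(f"{l}/{s}" for l, s in removed_stations) if removed_stations else "none"
    )
    return table.derive(df[mask], {"action": "filter_consistent_stations", "detail": detail})


def apply_lake_exclusions(
    table: CatchTable,
    rules: Sequence[tuple[str, tuple[int, int]]] | None = None,
) -> CatchTable:
    """Drop records matching lake-specific excluded year ranges."""
    rules = DEFAULT_EXCLUSIONS if rules is None else list(rules)
    df = table.records
    mask = np.ones(len(df), dtype=bool)
    details = []
    lakes_present = set(df["lake"].unique())
    for lake, (y0, y1) in rules:
        if lake not in lakes_present:
            logger.info("exclusion rule for absent lake %r ignored", lake)
            details.append(f"{lake} {y0}-{y1}: lake absent")
            continue
        hit = (df["lake"] == lake) & (df["year"] >= y0) & (df["year"] <= y1)
        mask &= ~hit.to_numpy()
        details.append(f"{lake} {y0}-{y1}: removed {int(hit.sum())}")
    detail = "; ".join(details) if details else "no rules"
    return table.derive(df[mask], {"action": "apply_lake_exclusions", "detail": detail})


def assign_periods(
    table: CatchTable, periods: PeriodDefinition | None = None
) -> CatchTable:
    """Label records Pre/Post and drop those in neither period."""
    periods = periods or DEFAULT_PERIODS
    df = table.records.copy()
    labels = df["year"].map(periods.label)
    kept = df[labels.notna()].copy()
    kept["period"] = labels[labels.notna()].astype(str)
    n_pre = int((kept["period"] == "pre").sum())
    n_post = int((kept["period"] == "post").sum())
    detail = (
        f"before={periods.before} after={periods.after}; "
        f"pre={n_pre} post={n_post} dropped={len(df) - len(kept)}"
    )
    return table.derive(kept, {"action": "assign_periods", "detail": detail})


def write_canonical_csv(table: CatchTable, path: str | Path, log_path: str | Path | None = None) -> None:
    """Write the canonical CSV and, optionally, the plain-text filter log."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.records.to_csv(path, index=False)
    if log_path is not None:
        Path(log_path).write_text(table.filter_log() + "\n")
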