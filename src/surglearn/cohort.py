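"""Cohort data model, CSV I/O, target configuration and descriptive summaries.

A *cohort* is a chronologically ordered sequence of surgical cases.  Each case
carries a set of outcome metrics — the Oxford Shoulder Score (OSS, 0–48
points), the Constant Shoulder Score (CSS, 0–100 points), four range-of-motion
angles in degrees, and the operation time in minutes — plus any complication
events recorded for that patient.  Outcomes may be missing for individual
cases; missingness is preserved, never imputed.

Files are plain CSV (comma-separated, UTF-8, header row, decimal point):

* the cohort table with columns ``case_index, date, oss, css, flexion,
  extension, abduction, external_rotation, operation_time``;
* a long-format companion table for complications with columns
  ``case_index, description, severity, months_from_surgery, attributable,
  treatment``.

Target levels — the per-metric performance benchmarks the CUSUM charts compare
against — are configured in YAML or JSON and default to literature-based
levels for the functional outcomes, the cohort mean for operation time, and a
20 % complication probability.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "METRICS",
    "METRIC_RANGES",
    "Direction",
    "TargetSource",
    "TargetSpec",
    "ComplicationEvent",
    "CaseRecord",
    "MetricSummary",
    "CohortSummary",
    "CohortError",
    "DEFAULT_TARGETS",
    "load_cohort",
    "write_cohort",
    "load_complications",
    "write_complications",
    "metric_series",
    "summarize_cohort",
    "summarize_categorical",
    "load_targets",
]

#: Canonical metric identifiers, in reporting order.
METRICS: tuple[str, ...] = (
    "oss",
    "css",
    "flexion",
    "extension",
    "abduction",
    "external_rotation",
    "operation_time",
)

_ANGLES = ("flexion", "extension", "abduction", "external_rotation")

#: Valid closed ranges per metric; operation time has an open lower bound at 0.
METRIC_RANGES: dict[str, tuple[float, float]] = {
    "oss": (0.0, 48.0),
    "css": (0.0, 100.0),
    **{a: (0.0, 180.0) for a in _ANGLES},
    "operation_time": (0.0, math.inf),
}


class CohortError(ValueError):
    """Raised for malformed cohort tables or invalid configuration."""


class Direction(str, Enum):
    """Which side of the target counts as good performance."""

    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"


class TargetSource(str, Enum):
    """Provenance of a target level."""

    LITERATURE = "literature"
    COHORT_MEAN = "cohort_mean"
    COHORT_PROBABILITY = "cohort_probability"


@dataclass(frozen=True)
class TargetSpec:
    """A metric's target level and orientation.

    ``target`` is ``None`` for a ``cohort_mean`` source until it has been
    resolved against the observed series (see
    :func:`surglearn.cusum.resolve_cohort_mean`); configured numeric values
    for such targets are ignored by construction.
    """

    metric: str
    target: float | None
    direction: Direction
    source: TargetSource = TargetSource.LITERATURE

    def __post_init__(self) -> None:
        if self.source is TargetSource.COHORT_MEAN:
            # recomputed from the series before charting, never from config
            object.__setattr__(self, "target", None)
        elif self.target is None:
            raise CohortError(f"target for {self.metric!r} must be numeric")
        if self.metric in _ANGLES and self.target is not None and self.target < 0:
            raise CohortError(f"negative target for angle metric {self.metric!r}")

    @property
    def resolved(self) -> bool:
        return self.target is not None


@dataclass(frozen=True)
class ComplicationEvent:
    """One adverse event tied to a surgical case.

    ``attributable`` is False for events unrelated to the prosthesis placement
    (e.g. a post-operative fall); such events never enter rate computations or
    the binary CUSUM.  ``treatment`` is the structured treatment/outcome
    annotation used by the severity ruleset.
    """

    description: str
    severity: str
    months_from_surgery: float | None = None
    attributable: bool = True
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.severity not in ("minor", "major"):
            raise CohortError(
                f"severity must be 'minor' or 'major', got {self.severity!r}"
            )
        if self.months_from_surgery is not None and self.months_from_surgery < 0:
            raise CohortError("months_from_surgery must be non-negative")


@dataclass
class CaseRecord:
    """One surgical case in chronological order (``case_index`` is 1-based)."""

    case_index: int
    outcomes: dict[str, float | None] = field(default_factory=dict)
    complications: list[ComplicationEvent] = field(default_factory=list)
    date: str | None = None


def _validate_value(metric: str, value: float, row: int) -> None:
    lo, hi = METRIC_RANGES[metric]
    bad = value > hi or (value <= lo if metric == "operation_time" else value < lo)
    if bad:
        raise CohortError(
            f"row {row}, column {metric!r}: value {value} outside valid range"
        )


def _validate_order(records: Sequence[CaseRecord]) -> None:
    indices = [r.case_index for r in records]
    seen: set[int] = set()
    for ix in indices:
        if ix in seen:
            raise CohortError(f"duplicate case_index {ix}")
        seen.add(ix)
    if seen != set(range(1, len(records) + 1)):
        raise CohortError("case_index values must be contiguous from 1")


def load_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    complications: str | Path | None = None,
) -> list[CaseRecord]:
    """Read a cohort CSV into an ordered list of :class:`CaseRecord`.

    Parameters
    ----------
    path
        Cohort table; must contain a ``case_index`` column (or its mapped name)
        and any subset of the canonical metric columns.
    schema
        Optional mapping from canonical column name to the column name used in
        the file, e.g. ``{"oss": "oxford_score"}``.
    complications
        Optional path to the long-format complications CSV; events are
        attached to their cases.

    Missing outcome cells stay missing (``None``); they are never replaced by
    zero.  Duplicate or non-contiguous case indices raise :class:`CohortError`.
    """
    schema = dict(schema or {})
    colname = lambda canonical: schema.get(canonical, canonical)  # noqa: E731
    try:
        frame = pd.read_csv(path, comment="#")
    except (OSError, pd.errors.ParserError) as exc:
        raise CohortError(f"cannot read cohort file {path}: {exc}") from exc

    if colname("case_index") not in frame.columns:
        raise CohortError(f"missing required column {colname('case_index')!r}")

    records: list[CaseRecord] = []
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        raw = row[colname("case_index")]
        try:
            ix = int(raw)
        except (TypeError, ValueError) as exc:
            raise CohortError(
                f"row {pos}, column 'case_index': unparseable value {raw!r}"
            ) from exc
        outcomes: dict[str, float | None] = {}
        for metric in METRICS:
            col = colname(metric)
            if col not in frame.columns:
                continue
            cell = row[col]
            if pd.isna(cell):
                outcomes[metric] = None
                continue
            try:
                value = float(cell)
            except (TypeError, ValueError) as exc:
                raise CohortError(
                    f"row {pos}, column {metric!r}: unparseable value {cell!r}"
                ) from exc
            _validate_value(metric, value, pos)
            outcomes[metric] = value
        date_col = colname("date")
        date = None
        if date_col in frame.columns and not pd.isna(row[date_col]):
            date = str(row[date_col])
        records.append(CaseRecord(case_index=ix, outcomes=outcomes, date=date))

    _validate_order(records)
    records.sort(key=lambda r: r.case_index)

    if complications is not None:
        by_case = load_complications(complications)
        n = len(records)
        for ix in by_case:
            if not 1 <= ix <= n:
                raise CohortError(f"complication references unknown case {ix}")
        for rec in records:
            rec.complications = by_case.get(rec.case_index, [])
    return records


def write_cohort(records: Sequence[CaseRecord], path: str | Path) -> None:
    """Write the cohort table CSV (inverse of :func:`load_cohort`)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"case_index": rec.case_index}
        if rec.date is not None:
            row["date"] = rec.date
        for metric in METRICS:
            row[metric] = rec.outcomes.get(metric)
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)


def load_complications(path: str | Path) -> dict[int, list[ComplicationEvent]]:
    """Read the long-format complications CSV, grouped by case index."""
    try:
        frame = pd.read_csv(path, comment="#")
    except (OSError, pd.errors.ParserError) as exc:
        raise CohortError(f"cannot read complications file {path}: {exc}") from exc
    required = {"case_index", "description", "severity"}
    missing = required - set(frame.columns)
    if missing:
        raise CohortError(f"complications file missing columns {sorted(missing)}")

    out: dict[int, list[ComplicationEvent]] = {}
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            ix = int(row["case_index"])
        except (TypeError, ValueError) as exc:
            raise CohortError(
                f"row {pos}, column 'case_index': unparseable value"
            ) from exc
        months = None
        if "months_from_surgery" in frame.columns and not pd.isna(
            row["months_from_surgery"]
        ):
            months = float(row["months_from_surgery"])
        attributable = True
        if "attributable" in frame.columns and not pd.isna(row["attributable"]):
            attributable = str(row["attributable"]).strip().lower() in (
                "true",
                "1",
                "yes",
            )
        treatment = ""
        if "treatment" in frame.columns and not pd.isna(row["treatment"]):
            treatment = str(row["treatment"])
        event = ComplicationEvent(
            description=str(row["description"]),
            severity=str(row["severity"]).strip().lower(),
            months_from_surgery=months,
            attributable=attributable,
            treatment=treatment,
        )
        out.setdefault(ix, []).append(event)
    return out


def write_complications(records: Sequence[CaseRecord], path: str | Path) -> None:
    """Write all complication events of a cohort as a long-format CSV."""
    rows = []
    for rec in records:
        for ev in rec.complications:
            rows.append(
                {
                    "case_index": rec.case_index,
                    "description": ev.description,
                    "severity": ev.severity,
                    "months_from_surgery": ev.months_from_surgery,
                    "attributable": ev.attributable,
                    "treatment": ev.treatment,
                }
            )
    columns = [
        "case_index",
        "description",
        "severity",
        "months_from_surgery",
        "attributable",
        "treatment",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def metric_series(
    records: Sequence[CaseRecord], metric: str
) -> tuple[np.ndarray, np.ndarray]:
    """Extract a metric as ``(positions, values)`` over non-missing cases.

    Cases missing the metric are dropped from the series and the remaining
    cases are renumbered consecutively from 1, so every per-metric chart
    (CUSUM and trend scatter) shares one x-axis regardless of missingness.
    """
    if metric not in METRICS:
        raise CohortError(f"unknown metric {metric!r}")
    values = [
        rec.outcomes[metric]
        for rec in records
        if rec.outcomes.get(metric) is not None
    ]
    positions = np.arange(1, len(values) + 1)
    return positions, np.asarray(values, dtype=float)


# --------------------------------------------------------------------------
# descriptive summaries


@dataclass(frozen=True)
class MetricSummary:
    median: float
    q1: float
    q3: float
    n: int


@dataclass(frozen=True)
class CohortSummary:
    """Median/IQR per metric; metrics with no observed values are absent."""

    metrics: dict[str, MetricSummary]
    n_cases: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": m, "median": s.median, "iqr_low": s.q1, "iqr_high": s.q3, "n": s.n}
            for m, s in self.metrics.items()
        ]
        return pd.DataFrame(rows, columns=["metric", "median", "iqr_low", "iqr_high", "n"])


def summarize_cohort(
    records: Sequence[CaseRecord], quartile_method: str = "linear"
) -> CohortSummary:
    """Median and interquartile range per metric over non-missing values.

    ``quartile_method`` is any quantile interpolation accepted by
    :func:`numpy.quantile`; the default ``"linear"`` is the common type-7
    convention (linear interpolation between order statistics).
    """
    summaries: dict[str, MetricSummary] = {}
    for metric in METRICS:
        values = np.asarray(
            [
                rec.outcomes[metric]
                for rec in records
                if rec.outcomes.get(metric) is not None
            ],
            dtype=float,
        )
        if values.size == 0:
            continue  # flagged absent, never reported as zero
        q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method=quartile_method)
        summaries[metric] = MetricSummary(
            median=float(med), q1=float(q1), q3=float(q3), n=int(values.size)
        )
    return CohortSummary(metrics=summaries, n_cases=len(records))


def summarize_categorical(values: Iterable[object]) -> dict[object, tuple[int, float]]:
    """Counts and percentages of the non-missing denominator for one variable."""
    observed = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    n = len(observed)
    out: dict[object, tuple[int, float]] = {}
    for v in observed:
        count = out.get(v, (0, 0.0))[0] + 1
        out[v] = (count, 100.0 * count / n)
    return out


# --------------------------------------------------------------------------
# target configuration

#: Default target ledger: literature-based levels for functional outcomes,
#: cohort mean for operation time, 20 % complication probability.
DEFAULT_TARGETS: dict[str, TargetSpec] = {
    "oss": TargetSpec("oss", 34.5, Direction.HIGHER_BETTER),
    "css": TargetSpec("css", 50.0, Direction.HIGHER_BETTER),
    "flexion": TargetSpec("flexion", 105.0, Direction.HIGHER_BETTER),
    "extension": TargetSpec("extension", 40.0, Direction.HIGHER_BETTER),
    "abduction": TargetSpec("abduction", 90.0, Direction.HIGHER_BETTER),
    "external_rotation": TargetSpec("external_rotation", 15.0, Direction.HIGHER_BETTER),
    "operation_time": TargetSpec(
        "operation_time", None, Direction.LOWER_BETTER, TargetSource.COHORT_MEAN
    ),
    "complication": TargetSpec(
        "complication", 0.20, Direction.LOWER_BETTER, TargetSource.COHORT_PROBABILITY
    ),
}


def _parse_target_entry(metric: str, entry: Mapping[str, object]) -> TargetSpec:
    base = DEFAULT_TARGETS.get(metric)
    raw_direction = entry.get("direction", base.direction.value if base else None)
    try:
        direction = Direction(str(raw_direction))
    except ValueError as exc:
        raise CohortError(
            f"unknown direction {raw_direction!r} for metric {metric!r}"
        ) from exc
    raw_source = entry.get("source", base.source.value if base else "literature")
    try:
        source = TargetSource(str(raw_source))
    except ValueError as exc:
        raise CohortError(
            f"unknown source {raw_source!r} for metric {metric!r}"
        ) from exc
    target = entry.get("target", base.target if base else None)
    if target is not None:
        target = float(target)  # type: ignore[arg-type]
    return TargetSpec(metric=metric, target=target, direction=direction, source=source)


def load_targets(path: str | Path | None = None) -> dict[str, TargetSpec]:
    """Load the target-level ledger, merging overrides onto the defaults.

    With ``path`` absent (or an empty file) the shipped default ledger is
    returned.  The config is a YAML or JSON mapping from metric id to
    ``{target, direction, source}``; omitted keys inherit the default.
    """
    ledger = dict(DEFAULT_TARGETS)
    if path is None:
        return ledger
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, Mapping):
        raise CohortError("target config must be a mapping of metric -> settings")
    for metric, entry in data.items():
        if not isinstance(entry, Mapping):
            raise CohortError(f"target entry for {metric!r} must be a mapping")
        ledger[str(metric)] = _parse_target_entry(str(metric), entry)
    return ledger


def targets_to_frame(ledger: Mapping[str, TargetSpec]) -> pd.DataFrame:
    rows = [
        {
            "metric": spec.metric,
            "target": spec.target,
            "direction": spec.direction.value,
            "source": spec.source.value,
        }
        for spec in ledger.values()
    ]
    return pd.DataFrame(rows, columns=["metric", "target", "direction", "source"])


def with_target(spec: TargetSpec, target: float) -> TargetSpec:
    """Copy of *spec* carrying a resolved numeric target.

    Needed because a ``cohort_mean`` spec refuses configured targets by
    construction; resolution against the observed series goes through here.
    """
    new = dataclasses.replace(spec)
    object.__setattr__(new, "target", float(target))
    return new
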