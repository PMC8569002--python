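"""Cumulative-sum (CUSUM) performance charts against predefined targets.

The chart tracks a running sum of per-case deviations from a target level,
plotted against the chronological case number.  For a continuous metric the
per-case increment is the signed distance to the target, oriented so that
*up is good*:

    increment_k = d * (x_k - T),   d = +1 (higher is better) or -1 (lower)

i.e. the sum rises by ``|x_k - T|`` when the case outperforms the target and
falls by the same amount when it underperforms; an on-target case contributes
zero.  For the binary complication chart with expected event probability
``p0`` the increments are ``+p0`` for an event-free case and ``-(1 - p0)``
for a complicated case, which makes the chart drift-free exactly when events
occur at rate ``p0`` while preserving the down-is-worse orientation.

The sum starts at 0 before the first case; there is no holding barrier, no
reset, and no decision limit — these are monitoring charts read for their
shape (learning trough, consolidation rise, mastering plateau), not control
charts with alarm rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortError, Direction, TargetSource, TargetSpec, with_target

__all__ = [
    "CusumSeries",
    "continuous_cusum",
    "resolve_cohort_mean",
    "binary_cusum",
]


@dataclass(frozen=True)
class CusumSeries:
    """Per-case increments and running sums for one metric against one target."""

    metric: str
    target: TargetSpec
    case_positions: tuple[int, ...]
    values: tuple[float, ...]
    increments: tuple[float, ...]
    cumulative: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.case_positions)
        if not (len(self.values) == len(self.increments) == len(self.cumulative) == n):
            raise ValueError("case_positions, values, increments, cumulative must align")

    def __len__(self) -> int:
        return len(self.case_positions)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per case."""
        return pd.DataFrame(
            {
                "metric": self.metric,
                "case_position": list(self.case_positions),
                "value": list(self.values),
                "increment": list(self.increments),
                "cumulative": list(self.cumulative),
                "target": self.target.target,
            }
        )


def _build(
    metric: str,
    target: TargetSpec,
    positions: Sequence[int] | None,
    values: np.ndarray,
    increments: np.ndarray,
) -> CusumSeries:
    if positions is None:
        positions = range(1, len(values) + 1)
    return CusumSeries(
        metric=metric,
        target=target,
        case_positions=tuple(int(p) for p in positions),
        values=tuple(float(v) for v in values),
        increments=tuple(float(i) for i in increments),
        cumulative=tuple(float(c) for c in np.cumsum(increments)),
    )


def continuous_cusum(
    series: Sequence[float],
    target: TargetSpec,
    positions: Sequence[int] | None = None,
) -> CusumSeries:
    """CUSUM of a continuous metric against a resolved numeric target.

    Parameters
    ----------
    series
        Ordered outcome values, one per available case.
    target
        Resolved target spec; a still-unresolved ``cohort_mean`` target raises
        with a pointer to :func:`resolve_cohort_mean`.
    positions
        Case positions for the x-axis; defaults to ``1..n``.
    """
    values = np.asarray(series, dtype=float)
    if values.size == 0:
        raise CohortError("series must be non-empty")
    if not target.resolved:
        raise CohortError(
            f"target for {target.metric!r} has source 'cohort_mean' and is "
            "unresolved; call resolve_cohort_mean(series, spec) first"
        )
    d = 1.0 if target.direction is Direction.HIGHER_BETTER else -1.0
    increments = d * (values - float(target.target))
    return _build(target.metric, target, positions, values, increments)


def resolve_cohort_mean(series: Sequence[float], spec: TargetSpec) -> TargetSpec:
    """Resolve a ``cohort_mean`` target to the arithmetic mean of the series.

    Returns a new spec; the input spec is unmodified.
    """
    if spec.source is not TargetSource.COHORT_MEAN:
        raise CohortError(
            f"target for {spec.metric!r} has source {spec.source.value!r}, "
            "not 'cohort_mean'"
        )
    values = np.asarray([v for v in series if v is not None], dtype=float)
    if values.size == 0:
        raise CohortError("cannot resolve cohort mean of an empty series")
    return with_target(spec, float(values.mean()))


def binary_cusum(
    events: Sequence[bool],
    p0: float,
    positions: Sequence[int] | None = None,
    metric: str = "complication",
) -> CusumSeries:
    """CUSUM of binary adverse events against an expected probability ``p0``.

    An event-free case adds ``+p0``; a complicated case subtracts ``1 - p0``.
    Over ``n`` cases the sum is exactly ``p0 * n_false - (1 - p0) * n_true``,
    and with independent events at true rate ``p0`` the expected increment is
    zero — the chart is drift-free precisely at the target probability.
    """
    if not 0.0 < p0 < 1.0:
        raise CohortError(f"p0 must lie strictly in (0, 1), got {p0}")
    flags = np.asarray(events, dtype=bool)
    if flags.size == 0:
        raise CohortError("events must be non-empty")
    increments = np.where(flags, -(1.0 - p0), p0)
    spec = TargetSpec(
        metric, p0, Direction.LOWER_BETTER, TargetSource.COHORT_PROBABILITY
    )
    n = flags.size
    # telescoped running sum p0*k - #events<=k: one rounding per entry instead
    # of k accumulated ones, so long charts honour the count closed form tightly
    cumulative = p0 * np.arange(1, n + 1) - np.cumsum(flags)
    if positions is None:
        positions = range(1, n + 1)
    return CusumSeries(
        metric=metric,
        target=spec,
        case_positions=tuple(int(p) for p in positions),
        values=tuple(float(v) for v in flags),
        increments=tuple(float(i) for i in increments),
        cumulative=tuple(float(c) for c in cumulative),
    )
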