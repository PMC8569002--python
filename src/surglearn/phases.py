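"""Three-phase segmentation of a CUSUM chart: learning, consolidation, mastering.

A surgical learning curve read off a CUSUM chart has up to three phases: an
initial *learning* phase while performance sits below target (the chart
trends down), a *consolidation* phase as performance recovers toward and past
the target (the chart rises), and a final *mastering* phase where performance
holds a steady optimal level (the chart flattens).  Clinical reports usually
identify these boundaries visually; this module fixes explicit, reproducible
rules:

* the learning phase ends at the *global minimum* of the cumulative series
  (earliest case on ties — the conservative, shortest-learning-phase choice);
  a chart that never dips below zero has no learning phase (``learning_end =
  0``);
* mastering starts at the first case after the trough from which *every*
  subsequent full window of ``plateau_window`` cases has mean absolute
  increment at most ``plateau_tol`` — a sustained-flatness criterion, so a
  single quiet stretch followed by renewed drift does not count.

Both parameters are configurable and recorded alongside the output; the
defaults (window 10, tolerance 25 % of the chart's mean absolute increment)
suit 50-case cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortError
from .cusum import CusumSeries

__all__ = [
    "PhaseSegmentation",
    "CutoffSummary",
    "segment_phases",
    "summarize_cutoffs",
]

logger = logging.getLogger(__name__)

DEFAULT_PLATEAU_WINDOW = 10
#: Default plateau tolerance, as a fraction of the mean absolute increment.
DEFAULT_PLATEAU_FRACTION = 0.25


@dataclass(frozen=True)
class PhaseSegmentation:
    """Phase boundaries and per-case labels for one metric's CUSUM chart.

    ``learning_end`` is the case position of the last learning-phase case
    (0 when there is no learning phase); ``mastering_start`` is the first
    mastering-phase case, or ``None`` if no sustained plateau was found.
    """

    metric: str
    learning_end: int
    mastering_start: int | None
    labels: tuple[str, ...]
    plateau_window: int
    plateau_tol: float

    def __post_init__(self) -> None:
        if self.mastering_start is not None and self.learning_end >= self.mastering_start:
            raise ValueError("learning_end must precede mastering_start")


def segment_phases(
    cusum: CusumSeries,
    plateau_window: int = DEFAULT_PLATEAU_WINDOW,
    plateau_tol: float | None = None,
) -> PhaseSegmentation:
    """Segment a CUSUM series into learning / consolidation / mastering.

    Parameters
    ----------
    cusum
        The chart to segment (continuous or binary).
    plateau_window
        Length (in cases) of the rolling windows tested for flatness; ≥ 2.
    plateau_tol
        Flatness threshold on the windowed mean absolute increment, in the
        metric's units.  ``None`` uses 25 % of the chart's overall mean
        absolute increment.

    The segmentation is deterministic: equal inputs give equal outputs.
    """
    if len(cusum) == 0:
        raise CohortError("cannot segment an empty CUSUM series")
    if plateau_window < 2:
        raise CohortError("plateau_window must be at least 2")
    if plateau_tol is not None and plateau_tol < 0:
        raise CohortError("plateau_tol must be non-negative")

    cum = np.asarray(cusum.cumulative)
    inc = np.abs(np.asarray(cusum.increments))
    positions = cusum.case_positions
    n = len(positions)

    if plateau_tol is None:
        plateau_tol = DEFAULT_PLATEAU_FRACTION * float(inc.mean())

    # Learning phase: up to the global minimum of the running sum, provided the
    # chart actually dips below its starting level of 0.
    if cum.min() >= 0.0:
        learning_end = 0
        min_idx = -1  # no learning case
    else:
        min_idx = int(np.argmin(cum))  # argmin takes the earliest tie
        learning_end = positions[min_idx]

    # Mastering phase: earliest case after the trough from which every full
    # trailing window is flat.
    mastering_start: int | None = None
    if plateau_window > n:
        logger.warning(
            "plateau_window %d exceeds series length %d; mastering detection skipped",
            plateau_window,
            n,
        )
    else:
        window_means = np.convolve(inc, np.ones(plateau_window) / plateau_window, "valid")
        flat = window_means <= plateau_tol
        # suffix-all-flat: last run of consecutive True reaching the end
        suffix_start = None
        for j in range(len(flat) - 1, -1, -1):
            if not flat[j]:
                break
            suffix_start = j
        if suffix_start is not None:
            start_idx = max(suffix_start, min_idx + 1)
            if start_idx <= len(flat) - 1 and start_idx < n:
                mastering_start = positions[start_idx]

    labels = []
    for pos in positions:
        if pos <= learning_end:
            labels.append("learning")
        elif mastering_start is not None and pos >= mastering_start:
            labels.append("mastering")
        else:
            labels.append("consolidation")

    return PhaseSegmentation(
        metric=cusum.metric,
        learning_end=learning_end,
        mastering_start=mastering_start,
        labels=tuple(labels),
        plateau_window=plateau_window,
        plateau_tol=float(plateau_tol),
    )


@dataclass(frozen=True)
class CutoffSummary:
    """Per-metric cutoffs plus the across-metric median learning-phase length."""

    table: pd.DataFrame
    median_learning_end: float


def summarize_cutoffs(segmentations: Sequence[PhaseSegmentation]) -> CutoffSummary:
    """Tabulate learning/mastering cutoffs and their across-metric median."""
    if not segmentations:
        raise CohortError("need at least one segmentation to summarize")
    rows = [
        {
            "metric": seg.metric,
            "learning_end": seg.learning_end,
            "mastering_start": seg.mastering_start,
            "plateau_window": seg.plateau_window,
            "plateau_tol": seg.plateau_tol,
        }
        for seg in segmentations
    ]
    table = pd.DataFrame(
        rows,
        columns=["metric", "learning_end", "mastering_start", "plateau_window", "plateau_tol"],
    )
    median = float(np.median([seg.learning_end for seg in segmentations]))
    return CutoffSummary(table=table, median_learning_end=median)
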