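"""Linear trend fits of outcomes on case number (scatter-plot regressions).

Each outcome is regressed by ordinary least squares on its consecutive case
position — the same x-axis the CUSUM charts use — yielding slope (outcome
units per case), intercept and the coefficient of determination
``r² = 1 - SSE/SST``.  No inference (CIs, p-values) is attached: the fit is a
descriptive trend line, a complementary view to the CUSUM chart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import METRICS, CaseRecord, CohortError, metric_series

__all__ = ["RegressionFit", "fit_trend", "trend_report", "report_to_frame"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionFit:
    metric: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    degenerate: bool = False  # constant outcome: SST = 0, r² reported as 0


def fit_trend(
    positions: Sequence[int],
    values: Sequence[float],
    metric: str = "",
) -> RegressionFit:
    """Least-squares line of ``values`` on ``positions``.

    A constant outcome (zero total sum of squares) cannot support an r² and is
    reported with slope 0, ``r_squared = 0`` and the ``degenerate`` flag set,
    keeping reports machine-readable.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size:
        raise CohortError("positions and values must have equal length")
    if x.size < 2:
        raise CohortError("trend fit needs at least 2 cases")
    if np.any(np.diff(x) <= 0):
        raise CohortError("case positions must be strictly increasing")

    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return RegressionFit(metric, 0.0, float(y[0]), 0.0, int(x.size), True)

    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    sse = float(np.sum((y - (slope * x + intercept)) ** 2))
    r2 = 1.0 - sse / sst
    # clamp float dust at the boundaries; r² lives in [0, 1]
    r2 = min(1.0, max(0.0, r2))
    return RegressionFit(metric, slope, intercept, r2, int(x.size))


def trend_report(
    records: Sequence[CaseRecord], metrics: Sequence[str] | None = None
) -> list[RegressionFit]:
    """One fit per requested metric, in stable metric order.

    Metrics with fewer than 2 observed values are omitted with a warning.
    """
    if metrics is None:
        metrics = METRICS
    unknown = [m for m in metrics if m not in METRICS]
    if unknown:
        raise CohortError(f"unknown metrics {unknown}")
    fits: list[RegressionFit] = []
    for metric in metrics:
        positions, values = metric_series(records, metric)
        if values.size < 2:
            logger.warning(
                "metric %r has %d observation(s); omitted from trend report",
                metric,
                values.size,
            )
            continue
        fits.append(fit_trend(positions, values, metric))
    return fits


def report_to_frame(fits: Sequence[RegressionFit]) -> pd.DataFrame:
    rows = [
        {
            "metric": f.metric,
            "slope": f.slope,
            "intercept": f.intercept,
            "r_squared": f.r_squared,
            "n": f.n,
            "degenerate_flag": f.degenerate,
        }
        for f in fits
    ]
    return pd.DataFrame(
        rows, columns=["metric", "slope", "intercept", "r_squared", "n", "degenerate_flag"]
    )
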