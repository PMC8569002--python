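"""Synthetic surgical cohorts with an exponential learning process.

The generator emulates what a learning-curve analysis assumes about a real
sequential cohort: each outcome's expected value improves from a starting
level toward an asymptote with exponential time constant ``tau`` (in cases),

    mu_k    = asymptote + (start_level - asymptote) * exp(-(k - 1) / tau),

case-to-case dispersion shrinks on the same timescale,

    sigma_k = sd_end + (sd_start - sd_end) * exp(-(k - 1) / tau),

and the per-case complication probability decays from ``p_start`` to
``p_inf`` with time constant ``tau_p``.  Draws are Gaussian around ``mu_k``,
clipped to the metric's valid range (a rare event under sensible parameters),
and the complication indicator is Bernoulli(``p_k``).

Because the mean path is in closed form, the case at which the expected value
first beats a target — :func:`crossing_case` — is exact ground truth for
phase-recovery experiments: a segmentation method applied to simulated charts
can be scored against the case number the generator actually crossed its
target at.

Random-number contract: one ``numpy`` Generator per cohort, seeded once; for
each case the continuous metrics are drawn first, in the parameter set's key
order (one normal each), then one uniform for the complication indicator.
Identical parameters and seed give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort import (
    DEFAULT_TARGETS,
    METRIC_RANGES,
    METRICS,
    CaseRecord,
    CohortError,
    ComplicationEvent,
    Direction,
    TargetSpec,
)
from .cusum import continuous_cusum
from .phases import segment_phases

__all__ = [
    "MetricLearning",
    "LearningModelParams",
    "simulate_cohort",
    "crossing_case",
    "tau_for_crossing",
    "reference_params",
    "replicate_learning_ends",
]


@dataclass(frozen=True)
class MetricLearning:
    """Learning-process parameters for one continuous metric (metric units)."""

    start_level: float
    asymptote: float
    tau: float
    sd_start: float
    sd_end: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise CohortError("tau must be positive")
        if not self.sd_start >= self.sd_end >= 0:
            raise CohortError("need sd_start >= sd_end >= 0")

    def mean_at(self, k: int | np.ndarray) -> float | np.ndarray:
        decay = np.exp(-(np.asarray(k) - 1) / self.tau)
        return self.asymptote + (self.start_level - self.asymptote) * decay

    def sd_at(self, k: int | np.ndarray) -> float | np.ndarray:
        decay = np.exp(-(np.asarray(k) - 1) / self.tau)
        return self.sd_end + (self.sd_start - self.sd_end) * decay


@dataclass(frozen=True)
class LearningModelParams:
    """Full parameter set for one simulated cohort."""

    metrics: Mapping[str, MetricLearning]
    p_start: float
    p_inf: float
    tau_p: float
    n_cases: int
    seed: int

    def __post_init__(self) -> None:
        if self.tau_p <= 0:
            raise CohortError("tau_p must be positive")
        if not 0.0 <= self.p_inf <= self.p_start <= 1.0:
            raise CohortError("need 0 <= p_inf <= p_start <= 1")
        if self.n_cases < 1:
            raise CohortError("n_cases must be positive")
        for metric, ml in self.metrics.items():
            if metric not in METRICS:
                raise CohortError(f"unknown metric {metric!r}")
            direction = DEFAULT_TARGETS[metric].direction
            improving = (
                ml.asymptote >= ml.start_level
                if direction is Direction.HIGHER_BETTER
                else ml.asymptote <= ml.start_level
            )
            if not improving:
                raise CohortError(
                    f"{metric!r}: asymptote must lie on the improving side of "
                    "start_level for its direction"
                )

    def p_at(self, k: int | np.ndarray) -> float | np.ndarray:
        decay = np.exp(-(np.asarray(k) - 1) / self.tau_p)
        return self.p_inf + (self.p_start - self.p_inf) * decay

    def to_dict(self) -> dict:
        return {
            "metrics": {
                m: {
                    "start_level": ml.start_level,
                    "asymptote": ml.asymptote,
                    "tau": ml.tau,
                    "sd_start": ml.sd_start,
                    "sd_end": ml.sd_end,
                }
                for m, ml in self.metrics.items()
            },
            "p_start": self.p_start,
            "p_inf": self.p_inf,
            "tau_p": self.tau_p,
            "n_cases": self.n_cases,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "LearningModelParams":
        metrics = {
            str(m): MetricLearning(**entry) for m, entry in data["metrics"].items()
        }
        return cls(
            metrics=metrics,
            p_start=float(data["p_start"]),
            p_inf=float(data["p_inf"]),
            tau_p=float(data["tau_p"]),
            n_cases=int(data["n_cases"]),
            seed=int(data["seed"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "LearningModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def simulate_cohort(params: LearningModelParams) -> list[CaseRecord]:
    """Draw one cohort under the exponential learning model.

    Values are clipped to each metric's valid range (operation time to a
    1-minute floor, since it must be strictly positive).  A complicated case
    receives a single generic attributable event; severities are not modelled.
    """
    rng = np.random.default_rng(params.seed)
    records: list[CaseRecord] = []
    for k in range(1, params.n_cases + 1):
        outcomes: dict[str, float | None] = {}
        for metric, ml in params.metrics.items():
            value = float(ml.mean_at(k)) + float(ml.sd_at(k)) * rng.standard_normal()
            lo, hi = METRIC_RANGES[metric]
            if metric == "operation_time":
                value = max(value, 1.0)
            else:
                value = min(max(value, lo), hi)
            outcomes[metric] = value
        complications = []
        if rng.random() < float(params.p_at(k)):
            complications.append(
                ComplicationEvent(
                    description="simulated adverse event",
                    severity="minor",
                    attributable=True,
                    treatment="simulated",
                )
            )
        records.append(
            CaseRecord(case_index=k, outcomes=outcomes, complications=complications)
        )
    return records


def _crossing_ratio(
    ml: MetricLearning, target: float
) -> float:
    span = abs(ml.start_level - ml.asymptote)
    gap = abs(target - ml.asymptote)
    if not (gap < span and gap > 0):
        raise CohortError(
            "target must lie strictly between start_level and asymptote"
        )
    return span / gap


def crossing_case(params: LearningModelParams, metric: str, target: float) -> int:
    """Smallest case k whose noiseless mean beats *target*.

    Closed form: ``k = 1 + ceil(tau * ln(|start - asymptote| / |target -
    asymptote|))`` (with a tiny downward nudge inside the ceiling so exact
    integer products do not round up).  This is the generator's ground-truth
    learning cutoff.
    """
    ml = params.metrics[metric]
    ratio = _crossing_ratio(ml, target)
    return 1 + math.ceil(ml.tau * math.log(ratio) - 1e-9)


def tau_for_crossing(
    ml: MetricLearning, target: float, case: int
) -> float:
    """Time constant making :func:`crossing_case` equal *case* exactly.

    Solves the crossing relation with a half-case offset (``tau * ln(ratio) =
    case - 1.5``) so the ceiling lands on ``case - 1`` unambiguously.
    """
    if case < 2:
        raise CohortError("crossing case must be at least 2")
    ratio = _crossing_ratio(ml, target)
    return (case - 1.5) / math.log(ratio)


def reference_params(seed: int = 0, n_cases: int = 50) -> LearningModelParams:
    """Default 50-case parameter set for demos and tests.

    Asymptotes sit at outcome levels typical of fRSA in elderly patients
    (e.g. forward flexion settling near 105–110°, operation time near 125
    minutes); start levels and time constants are chosen so the noiseless
    mean path crosses each default target near case 20, and dispersions so
    that range clipping stays rare (< 1 % of draws).  The complication
    probability decays 0.5 → 0.1 with tau 10, giving a cohort-average rate
    near 18 %.
    """
    metrics = {
        "oss": MetricLearning(20.0, 37.0, 10.0, 7.0, 4.0),
        "css": MetricLearning(25.0, 59.0, 14.0, 14.0, 10.0),
        "flexion": MetricLearning(75.0, 110.0, 10.0, 25.0, 15.0),
        "extension": MetricLearning(20.0, 46.0, 13.0, 10.0, 7.0),
        "abduction": MetricLearning(60.0, 95.0, 10.0, 18.0, 12.0),
        "external_rotation": MetricLearning(6.0, 17.0, 10.0, 5.0, 4.0),
        "operation_time": MetricLearning(175.0, 125.0, 10.0, 30.0, 20.0),
    }
    return LearningModelParams(
        metrics=metrics,
        p_start=0.5,
        p_inf=0.1,
        tau_p=10.0,
        n_cases=n_cases,
        seed=seed,
    )


def replicate_learning_ends(
    params: LearningModelParams,
    metric: str,
    target: TargetSpec,
    n_replicates: int,
    seed: int,
) -> np.ndarray:
    """Learning-phase cutoffs recovered from *n_replicates* simulated cohorts.

    Each replicate draws a fresh cohort (seeds derived from *seed*), charts
    the metric's CUSUM against *target*, and records the global-minimum
    learning cutoff.  Used for phase-recovery and no-learning-null
    experiments.
    """
    seed_rng = np.random.default_rng(seed)
    out = np.empty(n_replicates, dtype=int)
    for i in range(n_replicates):
        rep = replace(params, seed=int(seed_rng.integers(0, 2**31 - 1)))
        cohort = simulate_cohort(rep)
        values = [rec.outcomes[metric] for rec in cohort]
        chart = continuous_cusum(values, target)
        out[i] = segment_phases(chart).learning_end
    return out
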