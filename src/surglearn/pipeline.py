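"""End-to-end analysis run: summaries, trends, CUSUM charts, phases, rates.

`run_analysis` orchestrates the full learning-curve analysis on either a
cohort loaded from CSV or a freshly simulated one, writing a bundle of tidy
CSV outputs (the primary, deterministic contract), chart images (secondary
artifacts), and a JSON manifest sufficient to re-run the analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering; never require a display
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    METRICS,
    CaseRecord,
    CohortError,
    TargetSource,
    load_cohort,
    load_targets,
    metric_series,
    summarize_cohort,
    targets_to_frame,
    write_cohort,
    write_complications,
)
from .complications import (
    ComplicationTable,
    complication_rate,
    events_to_binary_series,
)
from .cusum import CusumSeries, binary_cusum, continuous_cusum, resolve_cohort_mean
from .phases import (
    DEFAULT_PLATEAU_WINDOW,
    PhaseSegmentation,
    segment_phases,
    summarize_cutoffs,
)
from .simulate import reference_params, simulate_cohort
from .trend import RegressionFit, report_to_frame, trend_report

__all__ = ["RunConfig", "ReportBundle", "run_analysis", "render_charts"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run.

    Exactly one input mode is active: ``cohort_path`` set (analyze a file) or
    ``simulate`` true (draw the reference synthetic cohort with ``seed``).
    """

    out_dir: Path
    cohort_path: Path | None = None
    complications_path: Path | None = None
    simulate: bool = False
    n_cases: int = 50
    targets_path: Path | None = None
    plateau_window: int = DEFAULT_PLATEAU_WINDOW
    plateau_tol: float | None = None
    seed: int = 0
    make_charts: bool = True

    def __post_init__(self) -> None:
        if self.simulate == (self.cohort_path is not None):
            raise CohortError("exactly one input mode: cohort_path or simulate")


@dataclass
class ReportBundle:
    """Paths of everything an analysis run wrote."""

    out_dir: Path
    csv_paths: dict[str, Path] = field(default_factory=dict)
    chart_paths: list[Path] = field(default_factory=list)
    manifest_path: Path | None = None


def _continuous_charts(
    records: Sequence[CaseRecord], targets
) -> list[CusumSeries]:
    charts = []
    for metric in METRICS:
        positions, values = metric_series(records, metric)
        if values.size == 0:
            logger.warning("metric %r has no observations; skipped", metric)
            continue
        spec = targets[metric]
        if spec.source is TargetSource.COHORT_MEAN:
            spec = resolve_cohort_mean(values, spec)
        charts.append(continuous_cusum(values, spec, positions))
    return charts


def run_analysis(config: RunConfig) -> ReportBundle:
    """Run the full analysis and write the report bundle under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out)

    if config.simulate:
        params = reference_params(seed=config.seed, n_cases=config.n_cases)
        records = simulate_cohort(params)
        logger.info("simulated cohort: %d cases (seed %d)", len(records), config.seed)
    else:
        records = load_cohort(
            config.cohort_path, complications=config.complications_path
        )
        logger.info("loaded cohort: %d cases from %s", len(records), config.cohort_path)

    targets = load_targets(config.targets_path)

    def write(name: str, frame: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        bundle.csv_paths[name] = path

    write_cohort(records, out / "cohort.csv")
    bundle.csv_paths["cohort"] = out / "cohort.csv"
    write_complications(records, out / "complications.csv")
    bundle.csv_paths["complications"] = out / "complications.csv"

    summary = summarize_cohort(records)
    write("summary", summary.to_frame())
    write("targets", targets_to_frame(targets))

    fits = trend_report(records)
    write("trend", report_to_frame(fits))
    logger.info("trend fits: %d metrics", len(fits))

    charts = _continuous_charts(records, targets)
    segmentations: list[PhaseSegmentation] = []
    for chart in charts:
        write(f"cusum_{chart.metric}", chart.to_frame())
        segmentations.append(
            segment_phases(chart, config.plateau_window, config.plateau_tol)
        )

    events = events_to_binary_series(records)
    p0 = float(targets["complication"].target)
    binary = binary_cusum(events, p0)
    write("cusum_complication", binary.to_frame())
    segmentations.append(
        segment_phases(binary, config.plateau_window, config.plateau_tol)
    )
    logger.info("cusum charts: %d continuous + 1 binary", len(charts))

    cutoffs = summarize_cutoffs(segmentations)
    phase_table = cutoffs.table.copy()
    phase_table["median_learning_end"] = cutoffs.median_learning_end
    write("phases", phase_table)

    rates = complication_rate(ComplicationTable.from_cohort(records))
    rate_frame = rates.to_frame()
    tabulated = rates.any_pct / 100.0
    rate_frame["configured_p0"] = p0
    # tabulated rate and configured p0 are decoupled; flag disagreement
    rate_frame["p0_matches_tabulated"] = bool(abs(tabulated - p0) < 1e-12)
    write("complication_rates", rate_frame)

    if config.make_charts:
        try:
            bundle.chart_paths = render_charts(
                charts + [binary], fits, segmentations, out
            )
        except Exception:  # charts are secondary; CSVs must survive
            logger.exception("chart rendering failed; CSV outputs kept")

    manifest = {
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_cases": len(records),
        "outputs": sorted(p.name for p in bundle.csv_paths.values()),
        "versions": {
            "surglearn": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    bundle.manifest_path = out / "manifest.json"
    bundle.manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return bundle


def render_charts(
    series: Sequence[CusumSeries],
    fits: Sequence[RegressionFit],
    segmentations: Sequence[PhaseSegmentation],
    out_dir: Path,
) -> list[Path]:
    """Scatter + trend line and CUSUM chart per metric; deterministic names."""
    out_dir = Path(out_dir)
    fit_by_metric = {f.metric: f for f in fits}
    seg_by_metric = {s.metric: s for s in segmentations}
    paths: list[Path] = []

    for chart in series:
        metric = chart.metric
        x = np.asarray(chart.case_positions)

        fit = fit_by_metric.get(metric)
        if fit is not None:
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.scatter(x, chart.values, s=18, color="tab:blue")
            ax.plot(x, fit.intercept + fit.slope * x, color="tab:red")
            ax.set_xlabel("case number")
            ax.set_ylabel(metric)
            ax.set_title(f"{metric}: linear trend (R² = {fit.r_squared:.3f})")
            path = out_dir / f"scatter_{metric}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            paths.append(path)

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(x, chart.cumulative, marker="o", markersize=3, color="tab:blue")
        ax.axhline(0.0, color="grey", linewidth=0.8)
        seg = seg_by_metric.get(metric)
        if seg is not None:
            if seg.learning_end > 0:
                ax.axvline(seg.learning_end, color="tab:orange", linestyle="--",
                           label=f"learning end ({seg.learning_end})")
            if seg.mastering_start is not None:
                ax.axvline(seg.mastering_start, color="tab:green", linestyle="--",
                           label=f"mastering start ({seg.mastering_start})")
            if seg.learning_end > 0 or seg.mastering_start is not None:
                ax.legend(fontsize=8)
        target = chart.target.target
        ax.set_xlabel("case number")
        ax.set_ylabel("cumulative sum")
        ax.set_title(f"{metric}: CUSUM vs target {target:g}")
        path = out_dir / f"cusum_{metric}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
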