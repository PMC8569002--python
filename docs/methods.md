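# Methods

## The monitoring problem

A single surgeon performs a demanding procedure on a chronological series of
patients; the question is whether, and for how long, performance improves
with experience. The data are one row per case: two shoulder scores (OSS,
0–48 points; CSS, 0–100 points), four range-of-motion angles in degrees,
operation time in minutes, and complication events graded minor/major. A
learning effect has two faces — outcomes improving on average, and outcomes
becoming less variable — and the package provides one view for each: OLS
trend lines for the average, CUSUM charts against fixed targets for the
case-by-case consistency.

## CUSUM charts

For a continuous metric with resolved target `T` and direction `d` (+1 when
higher values are better, −1 when lower), the chart is the running sum of
signed deviations,

    S_0 = 0,   S_k = S_{k-1} + d * (x_k - T).

A case exactly on target contributes 0. The chart is unbounded: no holding
barrier at zero, no decision limits, no resets — these are descriptive
monitoring charts read for shape, not sequential tests with alarm rules
(risk-adjusted CUSUM, SPRT limits and V-masks are deliberately out of
scope). Targets come from a config ledger; the operation-time target has
source `cohort_mean` and is recomputed from the observed series at charting
time (a configured number for it is ignored by construction), which makes
its chart telescope to exactly 0 at the last case — a useful self-check.

For the binary complication chart with expected event probability `p0`
(default 0.20), an event-free case adds `+p0` and a complicated case adds
`-(1 - p0)`. These magnitudes make the expected increment exactly zero when
events truly occur at rate `p0`, so drift in either direction is
interpretable, and they preserve the down-is-worse orientation of the
continuous charts. Other conventions (±1 steps, log-likelihood increments)
differ only by an affine transform of the vertical axis; every shape-based
conclusion (trough location, phase boundaries) is invariant to that choice
for fixed `p0`. Numerically the binary running sum is computed in telescoped
form `p0*k - (#events up to k)` — one rounding per entry — so it honours the
count closed form `S_n = p0*n_free - (1-p0)*n_event` to ~1 ulp even for long
series.

Missing data: a case missing a metric is dropped from that metric's series
and the remaining cases are renumbered consecutively, so the CUSUM chart and
the trend scatter share one x-axis per metric. The case keeps its global
index for everything else.

## Phase segmentation

Clinical readings of these charts distinguish a *learning* phase (downward
trend while performance is below target), a *consolidation* phase (recovery
toward and past the target) and a *mastering* phase (steady optimal level).
Published analyses identify the boundaries by eye; this package fixes
explicit rules so the cutoffs are reproducible and testable:

* **learning end** = case position of the global minimum of `S_k`, earliest
  case on ties (the conservative choice: the shortest defensible learning
  phase). A chart that never goes below 0 has no learning phase
  (`learning_end = 0`).
* **mastering start** = earliest case after the trough from which *every*
  subsequent full window of `plateau_window` cases has mean |increment| ≤
  `plateau_tol`. Requiring every trailing window (not just one) prevents a
  transient quiet stretch followed by renewed drift from being called
  mastery. If no full window fits after the trough, detection is skipped
  with a warning, never an error.

Defaults: `plateau_window = 10` cases and `plateau_tol` = 25 % of the
chart's mean absolute increment. Both are free parameters — the mastering
notion has no canonical definition — and are recorded next to every output
row so a reader can see exactly what produced a cutoff. The per-metric
cutoffs are combined only as an across-metric median, reported as the
learning-phase length.

These rules are this package's definitions. On real data the trough of a
noisy CUSUM is itself noisy; the synthetic-recovery experiments below
quantify how tightly the trough tracks the true crossing under a known
generative model, which is the honest way to read any single-cohort cutoff.

## Trend fits

Each metric is regressed on its consecutive case position by ordinary least
squares (scipy's `linregress` behind the interface), reporting slope,
intercept and `r² = 1 - SSE/SST`. A constant outcome has `SST = 0`; rather
than emitting NaN the fit is flagged `degenerate` with `r² = 0`, keeping
reports machine-readable. No slope inference (CIs, p-values) is attached:
the line is a descriptive complement to the CUSUM chart.

## Complications

Severity follows a two-class rule: *minor* events need neither considerable
revision surgery nor long-term medication; *major* events require revision
surgery or long-term antibiotics, or compromise the surgical outcome. The
classifier is a declarative keyword ruleset (revision, decompression /
acromioplasty, open reduction, internal fixation, long-term antibiotics,
compromised outcome) applied to the structured treatment/outcome annotation
— auditable by inspection, not free-text inference. An unannotated event
returns `unclassified` for manual review; it is never silently minor.
Removal of a cerclage cable deliberately classifies minor: it is not
considerable revision surgery.

Rates are patient-level: a patient counts at most once per severity class,
and the overall rate counts patients with ≥ 1 attributable event. Events
not attributable to the prosthesis placement (post-operative falls) are
excluded everywhere. The packaged register of a 50-patient fRSA cohort
tabulates to 6 minor patients (12 %), 3 major (6 %), 9 attributable events
(18 % of patients overall); the binary-chart default `p0 = 0.20` is an
independently configured benchmark, not derived from that table, and the
pipeline flags when the tabulated rate and configured `p0` disagree. The
register's source listing carries no case numbers, so its `case_index`
column holds arbitrary distinct placeholders; only counts are meaningful.

## Synthetic cohorts

The generator encodes the learning structure the analysis assumes, with
closed-form ground truth. For each continuous metric,

    mu_k    = asymptote + (start - asymptote) * exp(-(k-1)/tau)
    sigma_k = sd_end + (sd_start - sd_end) * exp(-(k-1)/tau)
    x_k     = mu_k + sigma_k * eps_k,   eps_k ~ N(0,1),

clipped to the metric's valid range (operation time to a 1-minute floor);
the complication indicator is Bernoulli with `p_k = p_inf + (p_start -
p_inf) * exp(-(k-1)/tau_p)`. A smooth exponential family was chosen over
piecewise-linear alternatives because the case at which the mean path first
beats a target has a closed form,

    crossing = 1 + ceil(tau * ln(|start - asymptote| / |target - asymptote|)),

giving exact ground truth for recovery experiments (`tau_for_crossing`
inverts it with a half-case offset so the ceiling is unambiguous). Clipping
rather than resampling at the range bounds keeps the draw count fixed;
under the reference parameters clipping touches < 1 % of draws (asserted in
the suite, so the calibration stays honest).

Randomness: one numpy `default_rng(seed)` per cohort; per case, the
continuous metrics are drawn first in the parameter set's key order (one
standard normal each), then one uniform for the complication indicator.
Identical parameters and seed give bit-identical cohorts; bit-compatibility
across numpy versions or other implementations is not promised.

The reference parameter set models a 50-case fRSA cohort: asymptotes at
outcome levels typical for elderly fRSA patients (OSS 37, CSS 59, flexion
110° with target 105°, extension 46°, abduction 95°, external rotation 17°,
operation time falling 175 → 125 min), start levels and time constants set
so every literature-target metric crosses its target between cases 15 and
25 (the suite asserts this window), dispersions shrinking by roughly 30–40 %
over the series, and complication probability decaying 0.5 → 0.1 with
`tau_p = 10` (cohort-average rate ≈ 18 %). What the generator does *not*
model: case-mix covariates (fracture type, ASA class) driving outcomes,
missing values, severity structure of simulated complications, or
autocorrelated noise. Passing recovery tests therefore show that the
segmentation rules recover a known smooth learning signal under Gaussian
noise — not that any particular real cohort's cutoff is correct.

## Validation experiments and problem sizes

The suite and `scripts/acceptance.py` run, end to end:

* exact equivalence of the continuous engine with an independent
  element-wise loop on 1,000 random series (lengths 1–200, both
  orientations);
* the binary count closed form to ≤ 1e-12 and drift neutrality over 10⁵
  Bernoulli(`p0`) events (|z| < 3);
* trend fits vs. the normal equations to ≤ 1e-10 relative error, with exact
  `r² = 1` on integer-grid perfect lines;
* phase recovery: cohorts built to cross the flexion target at case
  c ∈ {10, 20, 30} (matched tau, default noise), 200 replicates each — the
  median recovered trough must land within ±5 of c in at least 2 of 3
  settings;
* a no-learning null (stationary at target): no single cutoff value may
  capture more than 50 % of 200 replicates — the segmentation must not
  hallucinate a learning phase from a driftless random walk;
* byte-identical demo bundles under a repeated seed.

200 replicates per recovery setting keep the whole suite under ~10 s while
giving the medians a standard error well inside the ±5 acceptance band.

## Known limitations

* The learning-end rule is the global CUSUM minimum; on nearly flat charts
  the trough position has high variance, which the null experiment
  quantifies but cannot remove.
* Target levels drive everything; a mis-set target shifts the trough
  systematically. The operation-time chart, targeted at the cohort's own
  mean, measures consistency relative to the surgeon's own average, not
  against an external benchmark.
* Chart images are secondary artifacts and excluded from the byte-level
  determinism guarantee (font rasterisation and library versions may vary);
  the CSV outputs are the contract.
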