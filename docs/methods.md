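# Methods

`pilitrack` quantifies surface ("twitching") motility of single cells from
2-D tracking data, and the retraction kinetics of the type IV adhesion pili
that power it, as observed in live-cell imaging of *Sulfolobus* at high
temperature.  Because no raw movies or track tables are distributed with
the package, every stage is exercised against a mechanistic simulator with
known ground truth.  This note records the models, the estimators, the
numerical choices, and what the synthetic data can and cannot establish.

## Track statistics

A track is a time-ordered sequence of positions (µm) sampled at a fixed
frame interval (default 1 s over a 5-minute window, i.e. 300 frames).  Gaps
are retained as missing frames; nothing is interpolated, since interpolation
would fabricate positions that metrics would then average over.

Per track we compute:

* **Net displacement** `d = |r_N − r_1|` — the start-to-end distance, the
  "track displacement" of standard tracking software.  A track with
  `d < 2 µm` is classified **non-motile**: over five minutes such a cell has
  moved by less than 1.5 cell diameters and is, at this resolution,
  wobbling in place.
* **Path length** `s = Σ |r_{i+1} − r_i|` over observed points.
* **Persistence (confinement) ratio** `p = d / s ∈ [0, 1]` — 1 for straight
  monotone motion, near 0 for confined wandering.  Note the field also uses
  "directionality ratio" time-courses and mean-cosine persistence measures;
  we use the confinement ratio, which is what common tracking GUIs report
  under this name, and define `p = 0` when `s = 0`.
* **All-pairs MSD**: for every lag τ = k·Δt,
  `MSD(τ) = mean over all pairs (i, j) with t_j − t_i = τ of |r_j − r_i|²`.
  All ordered pairs are used, not just consecutive windows; pair counts are
  recorded per lag, and lags with no pairs (gaps) are omitted.
* **α, the anomalous-diffusion exponent**: the unweighted OLS slope of
  log MSD vs log τ.  α ≈ 1 indicates a random walk, α = 2 ballistic motion,
  α ≪ 1 a tethered/confined cell.  The fit is restricted to lags ≤ 25 % of
  the track duration (configurable): long-lag MSD values average very few
  pairs and are strongly correlated, so including them mostly adds noise.
  The restriction matters — α is a fit, not a property, and the fit range
  is part of the definition.  Translating, rotating, or uniformly rescaling
  a track provably leaves α unchanged (rescaling shifts log MSD by a
  constant), which the test suite asserts.

Classification: `non_motile` if `d < 2 µm`; `roller` if `d ≥ 10 µm` *and*
`p ≥ 0.5` (a detached cell dragged in a near-straight path by convection
flow); otherwise `motile`.  Diffusion class from α: subdiffusive below 0.5,
superdiffusive above 1.2, diffusive between, undefined when α cannot be
fitted (fewer than two usable lags).

## Replicate-aware statistics

The statistical unit is the biological replicate, never the cell.  For each
group, per-replicate means are computed over cells; the reported group mean
and SEM are the mean and SEM **of the replicate means** (the "SuperPlot"
convention).  Group comparison is a one-way fixed-effects ANOVA on the
replicate means followed by Tukey's HSD using the single pooled
within-group variance and the studentized-range distribution
(`scipy.stats.studentized_range`); the test suite pins the result on a
fixed 3-group fixture to values frozen from R's `aov` + `TukeyHSD`.
Cell-level testing is deliberately not offered: hundreds of cells per
movie are not independent observations, and treating them as such inflates
significance.  SEM is reported as undefined (not 0) with a single
replicate.  A zero pooled variance makes Tukey p-values undefined; this is
flagged, not silently converted.

Displacement histograms use half-open bins `[a, b)` and require the 2 µm
classification threshold to be a bin edge, so the sub-threshold fraction
read off the histogram always equals the classifier's non-motile fraction.

## Retraction kinetics

Pilus length vs time traces (µm vs s, default 0.5 s sampling as in
fluorescence imaging of labelled fibres) are scanned for retraction events:
the trace is smoothed with a 3-frame centred moving average, maximal
strictly-decreasing runs of the smoothed trace are taken, and runs whose
raw endpoint drop is ≥ 0.5 µm become events.  Plateaus split runs, so two
drops separated by a pause are two events.  Event endpoints are read off
the **raw** trace; the speed is the endpoint estimate
`v = (L_ini − L_final) / (t_final − t_ini)`, reported as a positive
magnitude (the length difference is negative as literally written; the
measured quantity is a speed).  On noiseless linear traces this recovers
the generating speed exactly, which the suite asserts for several speeds;
with noise the estimator is unbiased to within Monte-Carlo error.  When a
noisy trace fragments into several runs, the largest-drop ("principal")
event is the per-trace measurement.

The smoothing window of 3 is not incidental: the difference of two
consecutive 3-frame means is `(x_{i+3} − x_i)/3`, so during a genuine
retraction at ≥ 0.3 µm/s sampled at 0.5 s the smoothed trace is decreasing
with overwhelming probability at realistic noise (σ ≈ 0.05 µm), while flat
stretches fragment into sub-threshold runs and are discarded.

Speed-vs-initial-length association uses Pearson correlation with a
two-sided p (Spearman available as an option); zero variance in either
variable is an explicit error, not a NaN.  The replicate-aware mean speed
follows the same SuperPlot convention as the track statistics.

## The simulator

The generator is mechanistic, not phenomenological: twitching is produced
by the same pilus cycle believed to produce it in cells.

**Twitcher.**  Pili nucleate as a Poisson process (default 0.0263 s⁻¹, at
most 3 attached at once), each with a uniformly random direction and a
length drawn from a truncated normal (mean 2.5, sd 0.7, hard cap 14 µm —
the longest fibres observed).  The tip anchors; the fibre retracts at a
per-pilus speed from a truncated normal supported on [0.3, 2] µm/s
(mean parameter 0.3 — retraction speed does not depend on length).  With
one attached pilus the cell moves toward the anchor at the retraction
speed, arriving exactly when the fibre is fully retracted; with several it
moves toward the equal-weight centroid of the anchors at the mean of the
active speeds (tug-of-war).  On completion of each retraction the cell
takes a single backward recoil step (0.3 µm with probability 0.3) — the
slip seen when surface attachment is lost.  Dynamics are integrated at 5
substeps per frame; positions are sampled each frame with isotropic
Gaussian localisation noise (σ = 0.058 µm).  The nucleation rate and
length distribution are free calibration parameters — live imaging does
not report per-cell pilus counts or nucleation rates — and are flagged as
such; they were fixed once by the calibration below.

**Tethered.**  Isotropic Gaussian wobble (σ = 0.05 µm) about a fixed point.

**Roller.**  After an exponential dwell, straight constant-velocity motion
in a random direction.  At ~0.1 µm/s this reproduces detached cells riding
convection flow (long, persistence ≈ 1 tracks); at ~0.008 µm/s it doubles
as a slow residual creep of loosely held cells.

Reproducibility: one root seed; cohort track *i* uses
`np.random.default_rng([seed, i + 1])` and mode assignment uses stream
`[seed, 0]`, so cohorts are bit-identical for identical arguments
regardless of iteration order.

### Preset calibration

The packaged presets (WT, darlJ, dupsE, dupsE_darlJ, daapF, daapB) were
calibrated once by a coarse grid search on small cohorts against the
published cohort summary statistics (mean displacement, mean persistence
ratio, percentage of sub-2 µm tracks at N ≈ 200), then frozen.  Two
calibration findings shaped the presets and deserve a record:

* **The non-motile fraction is not the tethered fraction.**  A twitcher
  whose mean net displacement is ~6 µm still ends within 2 µm of its start
  in ~8 % of runs (the return probability of a random walk with that mean
  range is essentially fixed by the mean, whatever the step structure).
  The WT tethered fraction is therefore 0.04, not ~0.12: tightly tethered
  cells plus returning twitchers jointly produce the ~12 % sub-2 µm
  fraction.  Classification is by displacement, as in the source assay,
  and displacement does not reveal mechanism.
* **The pilus-mutant cohort requires a mixture.**  For the
  adhesion-pilus-deficient phenotype, the printed pair (mean displacement
  1.49 µm, yet only 46 % of tracks below 2 µm) cannot be produced by any
  single wobble amplitude: a Rayleigh-like displacement distribution with
  mean 1.49 µm puts ~76 % of its mass below 2 µm.  The observed pair
  forces a left-skewed mixture — a tightly wobbling population (40 %,
  displacement ≈ 0.1 µm) plus a population concentrated just above 2 µm,
  modelled as slow creep at 0.008 ± 0.001 µm/s (60 %).  Physically this
  reads as: about half the mutant cells are anchored, the rest drift
  almost imperceptibly (≈ 2.4 µm over 5 min, 1.5 cell diameters), e.g. on
  residual adhesion plus convection.

Cohort statistics at N = 200 have appreciable sampling noise (sd ≈ 0.25 µm
on the mean displacement, ≈ 2.4 points on the sub-2 µm percentage), so the
validation harness averages a handful of independently seeded cohorts of
the stated size; the per-cohort conditions are never changed.

### What the simulator does not capture

Real DIC movies contain out-of-focus cells, debris, cell-cell contacts,
division, drift, and detection dropouts; cells have extent and shape; pili
bend and can fail to attach; convection flow is spatially structured.  The
simulator has none of this, so passing tests demonstrate correctness of
the estimators and pipeline on data that satisfies the model's
assumptions — not robustness to everything a microscope produces.  The
imaging stage (below) restores one real-world failure mode, tracking
noise, by construction.

## Imaging closure

To test the statistics against tracking noise rather than perfect
coordinates, simulated cohorts can be laid out on a grid, rendered as
movies (cells as isotropic Gaussian blobs, sd = half the 0.8 µm cell
radius, additive Gaussian background at a chosen SNR), re-detected
(Gaussian smoothing, global mean + k·sd threshold, connected components,
intensity-weighted centroids; touching blobs may merge — a documented
limitation of global thresholding), and re-linked (greedy nearest
neighbour, accepting links up to 2 µm per elapsed frame, bridging gaps up
to 2 frames).  Greedy linking is sufficient at these densities and is
trivially auditable; it will fail when inter-cell spacing approaches the
per-frame step, which is why the layout grid spacing defaults to 25–30 µm.
Pixel convention: (0,0) µm is the centre of pixel (0,0).  The closure
criterion — group mean displacement from re-tracked movies within 10 % of
the ground-truth value at SNR 10 — passes with margin; the suite runs it
on a 9–12 cell field to keep runtime in seconds.

## Degenerate inputs and tie-breaks

Tracks with fewer than two points are rejected by every metric, not
scored.  A stationary track has persistence 0 by convention and an
undefined α.  MSD lags with zero pairs are omitted; lags with MSD = 0 are
dropped from the log-log fit.  Event detection requires ≥ 3 samples.
Histogram values exactly on an edge fall in the right-hand bin; values at
or beyond the last edge are not counted.  All thresholds live in
`AnalysisConfig` and are echoed into run manifests by the CLI.

## Known limitations

* The confinement-ratio reading of "persistence" is a definition choice;
  directionality-ratio variants would give different numbers.
* α from a 75-lag OLS fit has sd ≈ 0.15 per track; per-track α values are
  meaningful in distribution, not individually.
* The endpoint speed estimator has a small negative bias (< 2 %) on noisy
  traces whose run boundaries are themselves noise-selected; this is far
  inside the validation tolerance but would matter for σ ≫ 0.05 µm.
* The darlJ preset reproduces the near-total loss of the tethered
  population but its sub-2 µm fraction (~8 %, the twitcher floor) sits
  above the published 4.2 %; within this mechanism the floor cannot be
  lowered without raising mean displacement out of range.
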