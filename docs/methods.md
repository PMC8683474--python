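# Methods

This note documents the models, estimators, defaults and numerical choices
behind erythrokit, and what the synthetic-data tests do and do not show
about real data.

## Synthetic data: what is emulated

The generators produce the study conditions the estimators are meant for,
each with truth columns so recovery is checkable without re-deriving truth.

**Noise family.**  Cytometry-type measurements (areas, channel intensities,
cell counts) are positive and right-skewed, and the analysis pipeline
log-normalizes them; all multiplicative noise is therefore lognormal with
unit median and a stated CV.  CBC analytes (MCV, hemoglobin, …) are
approximately symmetric on their natural scale and receive additive
Gaussian noise, split into a between-subject SD (a latent subject level)
and a within-subject SD (sampling noise).

**Beads.**  Six certified diameters (2.0–14.3 μm), 2000 events per size by
default, 5% area CV.  The systematic mask bias is modelled as a *rim
dilation* — the measured radius is d/2 + rim with rim = 0.5 μm — rather
than an additive area offset, so the fitted degree-2 polynomial has
non-trivial linear and constant terms and the inversion is genuinely
exercised.  A configurable fraction of events (default 1% in the analysis
drivers) is replaced by gross outliers uniform over 5–10× the group mean,
which the 3-SD filter must remove.

**Erythroid event tables.**  A stage mixture; per stage: lognormal
diameters, Gaussian offsets clipped to [0, 0.5], lognormal marker
intensities.  Default stage diameters use the observed medians for
EpoR-rescued vs survival-only-rescued erythroblasts (7.5 vs 6.7 μm) and
reticulocytes (5.6 μm).  Enucleated stages get Draq5 totals at 2% of the
nucleated default, i.e. a ~50-fold mode separation on the log scale.

**Timer model.**  The histone–fluorescent-timer construct is modelled with
constant synthesis rate k, total content doubling over one cycle
(k = H₀/T), and a sharp blue→red conversion at protein age τ (default
1.5 h, within the reported 1–2 h maturation window).  A cell of age a then
shows B/(B+R) = min(a, τ)/(T + a).  The cycling-age density is
f(a) = (2 ln2/T)·2^(−a/T) on [0, T] (every division creates two age-zero
cells), with mean T(1/ln2 − 1).  The true maturation kinetics of the timer
are not specified to this level anywhere we could rely on; the sharp-
conversion model is this package's documented convention, and the relative-
cycle-length estimator is exact only under it.

**CBC cohort.**  The default design mirrors intervention study #1: 25
treated / 9 placebo subjects, 4 baseline weeks, 3 treatment weeks, 5
follow-up weeks, weekly sampling.  Treatment effects are piecewise-linear
in time — the simplest shape that reproduces the qualitative time courses:
hemoglobin +5% during treatment only; reticulocytes +40% during treatment,
dipping to −25% after cessation; MCV +4 fL and RDW-SD +3 fL developing over
treatment and persisting through follow-up.

**What the generators do not emulate:** instrument-level image physics
(PSF, shot noise), spillover/compensation, debris and doublets beyond the
uniform gross-outlier model, non-erythroid contamination, subject dropout,
and any pharmacokinetics of Epo (production effects are specified directly
as fold-change time courses).  Passing recovery tests therefore shows the
estimators are correct *under these models*, not that they are robust to
every artifact of real acquisitions.

## Morphometry

**Outlier filter.**  Single pass: mean and SD computed once (optionally on
logs), events outside mean ± k·SD dropped, no re-estimation.  On Gaussian
data the removed fraction converges to 2Φ(−k) ≈ 0.27% at k = 3.

**Calibration inverse.**  The quadratic is inverted on its increasing
branch, d = (−c₁ + √(c₁² − 4c₂(c₀ − area)))/(2c₂).  The trusted domain is
the bead range padded 10% per side; the fit must be strictly increasing
there (checked on a 512-point grid) or fitting fails naming the offending
interval.  Areas mapping outside the domain are still inverted but flagged
— extrapolation is never silent.

**Mask features.**  Centroids are intensity-weighted within each mask
(scikit-image regionprops); the delta centroid and derived offset are
invariant under translation, 90° rotation and global intensity rescaling,
and converge to the continuous-geometry truth at rate ∝ pixel size.  When
no calibration is supplied, diameters fall back to the equivalent-disc
relation 2√(area/π); every output records which path produced it.

**Reticulocyte gate.**  1-D two-means on log total Draq5 with deterministic
initialisation at the 25/75th percentiles; threshold = midpoint of the two
centres, so labels are invariant to global gain.  The separation score is
the centre distance in pooled within-cluster SDs.  A two-means split of a
single Gaussian yields ≈ 2.65 by construction (cluster means at ±0.80σ,
within-SD 0.60σ); the unreliability floor is set at 4.0, between that
degenerate value and the ≥ 10 of a genuine nucleated/enucleated mixture.
The gate still returns labels when flagged, and the threshold can be
overridden.

**Quantile conventions.**  Quintile edges are the reference sample's
20/40/60/80th percentiles (linear interpolation); values equal to an edge
go to the *lower* bin, deterministically.  Composite two-channel bins use
quantile edges pooled across all samples; empty composite bins are
reported missing (NaN), never zero.  The composite bin count k = 5 by
default and is configurable.  MFI means the *median* fluorescence
intensity by default, with the mean behind a flag.

## Kinetics

**Growth fits** are OLS on log2 counts — chosen over a direct nonlinear
exponential fit because the error model is multiplicative and the CI on the
slope transforms exactly to the doubling-time scale: doubling time = 1/slope
with CI endpoints (1/hi, 1/lo).  Coverage is nominal (93–97% over 200
replicates at 10% count CV in the test suite).  A non-positive slope
reports an infinite doubling time with a warning instead of failing.

**BrdU gating.**  The BrdU threshold is the KDE valley between the two
largest log-BrdU modes, accepted only when the valley density is below half
of both flanking peak densities; otherwise the distribution is treated as
unimodal background and the threshold falls back to its 99.5th percentile
(so an S-free table yields f_S ≤ 0.5%).  DNA 2N/4N centres are KDE maxima
of the BrdU-negative events, the 2N peak being the lower of the two
dominant modes; ties break toward the lower mode.  G1 vs G2/M assignment is
by distance to the nearer centre.

**Timer inversion.**  The mapping T ↦ median B/(B+R) at fixed τ is
computed by quadrature (weighted median of the ratio over a dense age grid)
and inverted by Brent's method on [1.01τ, 1000τ], where it is monotone
decreasing.  Ratios outside the attainable range raise an error naming the
range.  The first-order reciprocal shortcut (median ratio ∝ 1/T) is
retained for comparison and agrees within 15% for T ∈ [4τ, 16τ].

**Ergodic durations.**  Occupancy counts normalised to 1.  The steady-state
flux argument gives occupancy *proportional* to dwell time (a crowded stage
is a slow stage); that is the reading implemented, matching the discrete-
event snapshot generator, which is its independent oracle.

## The MCV simulator

A deterministic conveyor of age cohorts of width dt (default 0.25 d):
each step a cohort of size baseline_rate·fold(t)·dt enters at volume
v₀·multiplier(t), every cohort ages one bin, cohorts older than L leave.
A cohort's birth multiplier scales its entire volume-age trajectory.
Defaults v₀ = 106 fL, v₁ = 74 fL, L = 120 d (human), linear decline —
giving steady-state MCV 90 fL, volume SD (v₀−v₁)/√12 ≈ 9.2 fL.  The
exponential decline option decays at rate 3/L and is affinely corrected to
hit v₁ at L exactly.

The reported `rdw_sd` is the SD of the simulated volume distribution in fL.
Hematology analyzers report RDW-SD as the width of the volume histogram at
20% of its modal height, which differs by a model-dependent factor; the
simulated SD is the right object for within-model comparisons, which is all
the package uses it for.

Numerical notes: burn-in must cover at least one lifespan so the output
starts from steady state; with the default grid, halving dt changes MCV by
< 0.2% everywhere (grid-convergence test).  Mass is conserved exactly:
total count = baseline_rate·L under constant production.  An independent
quadrature oracle — MCV(t) as the fold-weighted integral of v(t−b) over
birth times b ∈ (t−L, t] — agrees with the conveyor at the pulse peak to
0.5%.

The package-level claim the scenario comparison establishes: with the birth
multiplier pinned at 1, any bounded production pulse produces an MCV
excursion that is bounded (by the age-redistribution extreme) and transient
(gone within one lifespan of pulse end, and *below* baseline during a
post-pulse production dip); any multiplier > 1 strictly exceeds it in both
peak and duration.  A persistent MCV elevation therefore cannot be an
age-composition artifact.

## Intervention statistics

Baseline correction subtracts each subject's mean baseline (time < 0) per
analyte; fractional change divides by it.  Group comparisons use per-
timepoint Welch tests on baseline-corrected values with Benjamini–Hochberg
adjustment across timepoints.  This deliberately replaces a linear mixed-
effects model with subject random intercepts: the baseline subtraction
absorbs the random intercept, and the per-timepoint contrasts answer the
same question the mixed model's time-by-treatment contrasts would, at the
cost of ignoring residual within-subject correlation across timepoints.
Type-I error of the full procedure is verified ≤ 5% on null panels.

Correlations between analytes default to pooling all (subject, time)
samples; a per-subject scope (mean within-subject r, p via Fisher-z) is
available, since pooled correlations mix within- and between-subject
variation.  Welch tests from group summaries use the unequal-variance
statistic with Welch–Satterthwaite df and match full-data Welch tests
exactly when the summaries come from the same samples.  The degenerate
zero-noise case (identical groups, zero variance) is defined as p = 1.

## Problem sizes

Default analysis sizes: 2000 events per bead size; 50,000 events per
erythroid table (matching the per-sample acquisition depth of the imaging
experiments); 10-point growth curves over 26 h; 20,000-event BrdU tables;
30,000-event timer tables; 100,000 cells in the ergodic snapshot; 0.25–0.5 d
simulation grids over 200 d horizons.  These sizes put every recovery test
comfortably inside its tolerance while keeping the whole suite and the
acceptance script in the seconds-to-a-minute range.

## Known limitations

* The timer maturation model (sharp conversion at τ) is a convention;
  relative cycle lengths from real timer data depend on the true maturation
  kinetics.
* The reticulocyte gate is 1-D (log total Draq5); the visual 2-D gate
  (mean vs total) can separate populations the 1-D projection merges.
* The MCV model has a fixed lifespan by default; random senescence spread
  is available but off, and no hemoglobin-content (MCH/MCHC) modelling is
  attempted.
* Per-timepoint contrasts are not a mixed model; p-values at different
  timepoints are correlated through shared subjects, which BH does not
  exploit.
* The human-study benchmarks that require subject-level source data are out
  of reach of the synthetic panels; the statistics are validated by
  construction-and-recovery instead.
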