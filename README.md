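# erythrokit

Quantitative tools for studying how erythropoietin-receptor (EpoR) signaling
shapes erythroblast cell cycles and red-cell size — imaging-flow-cytometry
morphometry, cell-cycle kinetics estimators, an age-structured red-cell
population model of MCV/RDW, and statistics for placebo-controlled CBC
intervention studies.  Everything runs on seeded synthetic data with known
ground truth, so every estimator in the pipeline is scored by parameter
recovery.

## Who this is for

Erythropoiesis labs quantifying imaging-flow-cytometry experiments (bead
size calibration, nuclear morphology, reticulocyte gating), and anyone
asking the population-level question the package's simulator settles: does
an Epo-driven shift toward younger circulating red cells *alone* explain a
persistent rise in mean corpuscular volume (MCV), or does it require cells
to be born larger?

## The core quantities

* **Bead calibration.** Imaging cytometers report biased mask areas.  A
  degree-2 polynomial, area = c₀ + c₁d + c₂d², is fitted to acquisitions of
  polystyrene beads of certified diameter d ∈ {2.0, 3.4, 5.1, 7.4, 9.96,
  14.3} μm (3-SD outlier filter per bead group), then inverted on its
  increasing branch to turn cell areas into diameters.
* **Nuclear offset.** For each cell, Δ is the distance between the
  intensity-weighted centroids of the cell image and the nucleus image; the
  nuclear offset Δ / cell diameter is a dimensionless measure of nuclear
  eccentricity that increases with erythroblast maturation and is
  independent of cell size.  Offset quintile edges computed on a reference
  (saline) sample transfer maturation staging to treated samples.
* **Cycle kinetics.**  Doubling times from log2-linear least squares with
  t-based 95% CIs; S-phase speed as the BrdU median fluorescence intensity
  of S-gated cells after a 30-min pulse (inversely related to S-phase
  duration); cell-cycle length from a histone H2B–fluorescent-timer: blue
  fluorescence B converts to red R with maturation time τ ≈ 1.5 h, so the
  per-cell ratio B/(B+R) under the steady-state cycling-age density
  f(a) = (2 ln2/T)·2^(−a/T) is a monotone-decreasing function of cycle
  length T, which the package inverts numerically.
* **Ergodic stage durations.**  At steady state, snapshot occupancy of a
  maturation stage is proportional to the time cells spend in it, so
  relative durations are occupancy fractions.
* **MCV simulator.**  A conveyor of age cohorts with fixed lifespan L =
  120 d and volume declining from v₀ = 106 fL at release to v₁ = 74 fL at
  death (steady-state MCV (v₀+v₁)/2 = 90 fL, volume SD (v₀−v₁)/√12).
  Production pulses re-weight the age distribution; a birth-volume
  multiplier models cells released larger.  Only the latter sustains an
  elevated MCV beyond one lifespan after the pulse.

## Worked example

```python
import numpy as np
from erythrokit import synthetic as syn, morphometry as mm, kinetics as kin

# calibrate from synthetic beads and size two erythroblast populations
beads = syn.gen_bead_events(syn.BeadSpec(rim_bias=0.0), seed=31)
cal = mm.fit_bead_calibration(beads)
events = syn.gen_erythroid_events(
    [syn.StageSpec("epor", 0.5, 7.5), syn.StageSpec("bclxl", 0.5, 6.7)],
    50_000, seed=32)
d, _ = mm.area_to_diameter(cal, events["bf_area"].to_numpy(), warn=False)
print(np.round(np.median(d[events["stage"] == "epor"]), 2))   # 7.49
print(np.round(np.median(d[events["stage"] == "bclxl"]), 2))  # 6.69

# doubling time with 95% CI from a noisy growth curve
growth = syn.gen_growth_series(
    syn.GrowthTruth(doubling_time=6.1, count_cv=0.05),
    np.linspace(0, 26, 10), seed=61)
fit = kin.fit_exponential_growth(growth["time_h"], growth["count"])
print(round(fit.doubling_time, 2), [round(float(c), 2) for c in fit.ci95])
# 5.93 [5.65, 6.24]
```

The first block recovers the generator's median diameters (7.5 and 6.7 μm)
through the full calibration round trip; the second recovers the true
doubling time (6.1 h) inside its 95% confidence interval.

## Analysis drivers

The numbered scripts under `analysis/` run the study end to end, each
printing what it found and writing tables to `results/`:

1. `01_simulate_fixtures.py` — generate all synthetic inputs
2. `02_bead_calibration.py` — calibration fit quality and round-trip error
3. `03_morphometry_staging.py` — offset recovery, reticulocyte gate,
   quintile staging transfer
4. `04_cycle_kinetics.py` — doubling times, S-phase speed, timer ratios,
   ergodic durations
5. `05_mcv_simulation.py` — null vs birth-size MCV scenarios
6. `06_human_study_stats.py` — baseline-corrected contrasts and correlations

A thin CLI (`erythrokit --help`) exposes the individual computations for
ad-hoc use on CSV inputs.

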