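"""Seeded generators for every synthetic input the pipeline consumes.

Each generator returns a table (or arrays) carrying *ground-truth* columns
alongside the simulated measurements, so downstream estimators can be scored
by parameter recovery without re-deriving the truth.  All generators are
deterministic given (spec, seed): repeat calls produce bit-identical output.

Measurement noise on cytometry-type quantities (areas, intensities) is
multiplicative lognormal throughout: these quantities are positive and
right-skewed, and the analysis pipeline log-normalizes them.  Complete-blood-
count analytes, which are approximately symmetric on their natural scale,
receive additive Gaussian noise instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BeadSpec",
    "StageSpec",
    "GrowthTruth",
    "FTTruth",
    "EffectProfile",
    "CohortDesign",
    "gen_bead_events",
    "gen_erythroid_events",
    "gen_image_pair",
    "gen_growth_series",
    "gen_brdu_dna",
    "gen_ft_events",
    "ft_age_density",
    "sample_cycling_age",
    "gen_snapshot",
    "gen_cbc_panel",
    "study1_design",
    "default_stage_panel",
    "MANUFACTURER_BEAD_DIAMETERS",
]

#: Manufacturer-certified polystyrene bead diameters (μm) used for the
#: imaging-flow-cytometry size calibration.
MANUFACTURER_BEAD_DIAMETERS = (2.0, 3.4, 5.1, 7.4, 9.96, 14.3)

_CHANNELS = ("ter119", "cd71", "hcd4", "gfp", "fsc", "draq5")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit median and the given CV."""
    if cv < 0:
        raise ValueError("coefficient of variation must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# bead calibration fixtures


@dataclass(frozen=True)
class BeadSpec:
    """Synthetic calibration-bead acquisition.

    Parameters
    ----------
    diameters :
        Manufacturer bead diameters in μm; strictly positive and distinct.
    n_per_bead :
        Events acquired per bead size.
    area_cv :
        Coefficient of variation of the multiplicative lognormal noise on
        measured areas.
    outlier_frac :
        Fraction of events per group replaced by gross outliers (debris,
        doublets), drawn uniformly over 5–10x the group mean area.
    rim_bias :
        Systematic mask-dilation rim (μm) added to the bead radius before
        rasterized area is computed; models the mask bias the degree-2
        calibration is meant to absorb.
    pixel_size :
        μm per pixel; measured areas are reported in px².
    """

    diameters: tuple = MANUFACTURER_BEAD_DIAMETERS
    n_per_bead: int = 2000
    area_cv: float = 0.05
    outlier_frac: float = 0.0
    rim_bias: float = 0.5
    pixel_size: float = 0.5

    def validate(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        if d.size < 1 or np.any(d <= 0):
            raise ValueError("bead diameters must be strictly positive")
        if len(set(self.diameters)) != d.size:
            raise ValueError("bead diameters must be distinct")
        if not (0 <= self.outlier_frac < 0.5):
            raise ValueError("outlier_frac must lie in [0, 0.5)")
        if self.area_cv < 0:
            raise ValueError("area_cv must be >= 0")
        if self.n_per_bead <= 0:
            raise ValueError("n_per_bead must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def gen_bead_events(spec: BeadSpec, seed: int) -> pd.DataFrame:
    """Simulate per-event bead areas for the size-calibration experiment.

    The noiseless measured area of a bead of diameter ``d`` is
    ``π (d/2 + rim_bias)² / pixel_size²`` (px²); lognormal noise of CV
    ``area_cv`` multiplies it, and ``outlier_frac`` of each group is replaced
    by gross outliers uniform over 5–10x the group's mean area.

    Returns a table with columns ``sample_id, bead_index, true_diameter,
    area, is_outlier``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    frames = []
    for i, d in enumerate(spec.diameters):
        r_eff = d / 2.0 + spec.rim_bias
        base_area = math.pi * r_eff**2 / spec.pixel_size**2
        area = base_area * _lognormal_factor(rng, spec.area_cv, spec.n_per_bead)
        is_outlier = np.zeros(spec.n_per_bead, dtype=bool)
        n_out = int(round(spec.outlier_frac * spec.n_per_bead))
        if n_out:
            idx = rng.choice(spec.n_per_bead, size=n_out, replace=False)
            group_mean = float(np.mean(area))
            area[idx] = rng.uniform(5.0 * group_mean, 10.0 * group_mean, size=n_out)
            is_outlier[idx] = True
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": "beads",
                    "bead_index": i,
                    "true_diameter": d,
                    "area": area,
                    "is_outlier": is_outlier,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# erythroid event tables


@dataclass(frozen=True)
class StageSpec:
    """One maturational stage of the synthetic erythroid population.

    ``mean_offset`` is the stage's nuclear offset (delta centroid / cell
    diameter, dimensionless, in [0, 0.5]); ``marker_means`` are per-channel
    lognormal medians (a.u.) for ter119/cd71/hcd4/gfp/fsc/draq5.  Enucleated
    stages receive background-level Draq5 totals regardless of the draq5
    entry.
    """

    name: str
    fraction: float
    mean_diameter: float
    diameter_cv: float = 0.08
    mean_offset: float = 0.1
    offset_sd: float = 0.02
    nucleated: bool = True
    marker_means: dict = field(default_factory=dict)
    marker_cv: float = 0.3

    def validate(self) -> None:
        if not self.name:
            raise ValueError("stage name must be non-empty")
        if not (0 <= self.fraction <= 1):
            raise ValueError("stage fraction must lie in [0, 1]")
        if self.mean_diameter <= 0:
            raise ValueError("mean_diameter must be positive")
        if not (0 <= self.mean_offset <= 0.5):
            raise ValueError("mean_offset must lie in [0, 0.5]")
        if self.offset_sd < 0 or self.diameter_cv < 0:
            raise ValueError("spreads must be >= 0")


_DEFAULT_MARKERS = {
    "ter119": 500.0,
    "cd71": 800.0,
    "hcd4": 300.0,
    "gfp": 200.0,
    "fsc": 1000.0,
    "draq5": 5000.0,
}

#: Draq5 total for enucleated cells, as a fraction of the nucleated default.
_DRAQ5_BACKGROUND_FRACTION = 0.02


def default_stage_panel() -> list:
    """Three-stage default emulating a 48-h erythroid culture.

    Two nucleated erythroblast stages at the median diameters observed with
    and without EpoR signalling (7.5 vs 6.7 μm) and one enucleated
    reticulocyte stage.  Offsets increase with maturation.
    """
    return [
        StageSpec("early_ebl", 0.40, 7.5, 0.08, 0.08, 0.02),
        StageSpec("late_ebl", 0.40, 6.7, 0.08, 0.20, 0.03),
        StageSpec("retic", 0.20, 5.6, 0.09, 0.0, 0.0, nucleated=False),
    ]


def gen_erythroid_events(
    stages: list,
    n: int,
    seed: int,
    pixel_size: float = 0.5,
    sample_id: str = "sample",
    area_noise_cv: float = 0.02,
) -> pd.DataFrame:
    """Simulate a per-event cytometry feature table for a stage mixture.

    Stage truth, true diameter and true nuclear offset are recorded per
    event.  Measured bright-field area derives from the true diameter
    (equivalent disc, px²) with small lognormal measurement noise; a CD71
    fluorescence area correlated with it is included so the CD71→brightfield
    mapping can be exercised.  Nucleus centroids are displaced from the cell
    centroid by offset·diameter in a random direction.  Enucleated stages
    receive background-level Draq5 totals.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    fractions = np.array([s.fraction for s in stages], dtype=float)
    for s in stages:
        s.validate()
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("stage fractions must sum to 1")

    rng = np.random.default_rng(seed)
    stage_idx = rng.choice(len(stages), size=n, p=fractions)

    diam = np.empty(n)
    offset = np.empty(n)
    nucleated = np.empty(n, dtype=bool)
    channels = {ch: np.empty(n) for ch in _CHANNELS}
    stage_names = np.empty(n, dtype=object)

    for i, s in enumerate(stages):
        m = stage_idx == i
        k = int(m.sum())
        if k == 0:
            continue
        diam[m] = s.mean_diameter * _lognormal_factor(rng, s.diameter_cv, k)
        offset[m] = np.clip(rng.normal(s.mean_offset, s.offset_sd, size=k), 0.0, 0.5)
        nucleated[m] = s.nucleated
        stage_names[m] = s.name
        for ch in _CHANNELS:
            median = s.marker_means.get(ch, _DEFAULT_MARKERS[ch])
            if ch == "draq5" and not s.nucleated:
                median = _DEFAULT_MARKERS["draq5"] * _DRAQ5_BACKGROUND_FRACTION
            channels[ch][m] = median * _lognormal_factor(rng, s.marker_cv, k)

    bf_area = (
        math.pi * (diam / 2.0) ** 2 / pixel_size**2
        * _lognormal_factor(rng, area_noise_cv, n)
    )
    # CD71 fluorescence area correlates linearly with brightfield area
    cd71_area = (0.85 * bf_area + 20.0) * _lognormal_factor(rng, area_noise_cv, n)

    theta = rng.uniform(0, 2 * math.pi, size=n)
    cx = rng.uniform(20, 40, size=n)
    cy = rng.uniform(20, 40, size=n)
    delta_px = offset * diam / pixel_size

    nuc_area_px = math.pi * (0.65 * diam / 2.0) ** 2 / pixel_size**2
    draq5_total = channels["draq5"]
    draq5_mean = np.where(nucleated, draq5_total / nuc_area_px, draq5_total / bf_area)

    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "stage": stage_names,
            "true_diameter": diam,
            "true_offset": offset,
            "true_nucleated": nucleated,
            "bf_area": bf_area,
            "cd71_area": cd71_area,
            "cell_centroid_x": cx,
            "cell_centroid_y": cy,
            "nuc_centroid_x": cx + delta_px * np.cos(theta),
            "nuc_centroid_y": cy + delta_px * np.sin(theta),
            "draq5_mean": draq5_mean,
            "draq5_total": draq5_total,
            "ter119": channels["ter119"],
            "cd71": channels["cd71"],
            "hcd4": channels["hcd4"],
            "gfp": channels["gfp"],
            "fsc": channels["fsc"],
        }
    )


# ---------------------------------------------------------------------------
# rasterized cell / nucleus image pairs


def gen_image_pair(
    diameter: float,
    nuc_diameter: float,
    offset: float,
    pixel_size: float,
    seed: int,
    noise_sd: float = 0.0,
):
    """Rasterize a concentric-or-offset disc pair (cell + nucleus).

    The nucleus centre is displaced from the cell centre by
    ``offset * diameter`` (μm) in a seeded random direction; both centres get
    a seeded sub-pixel jitter so the rasterization error is exercised.
    Returns ``(cell_mask, nuc_mask, cell_img, nuc_img, truth)`` where truth
    holds the exact continuous-geometry centroids (μm), areas (μm²) and delta
    centroid (μm).

    Raises ``ValueError`` if the nucleus is not strictly inside the cell.
    """
    if not (0 < nuc_diameter < diameter):
        raise ValueError("need 0 < nuc_diameter < diameter")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if offset * diameter + nuc_diameter / 2.0 > diameter / 2.0 + 1e-12:
        raise ValueError("nucleus escapes the cell boundary")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")

    rng = np.random.default_rng(seed)
    n_px = int(math.ceil(diameter / pixel_size * 1.5)) + 4
    centre = n_px * pixel_size / 2.0
    jitter = rng.uniform(-0.5, 0.5, size=2) * pixel_size
    cell_c = np.array([centre, centre]) + jitter
    theta = rng.uniform(0, 2 * math.pi)
    delta = offset * diameter
    nuc_c = cell_c + delta * np.array([math.cos(theta), math.sin(theta)])

    # pixel-centre coordinates in μm
    coords = (np.arange(n_px) + 0.5) * pixel_size
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    cell_mask = ((xx - cell_c[0]) ** 2 + (yy - cell_c[1]) ** 2) <= (diameter / 2) ** 2
    nuc_mask = ((xx - nuc_c[0]) ** 2 + (yy - nuc_c[1]) ** 2) <= (nuc_diameter / 2) ** 2

    cell_img = cell_mask.astype(float)
    nuc_img = nuc_mask.astype(float)
    if noise_sd > 0:
        cell_img = np.clip(cell_img + rng.normal(0, noise_sd, cell_img.shape), 0, None)
        nuc_img = np.clip(nuc_img + rng.normal(0, noise_sd, nuc_img.shape), 0, None)

    truth = {
        "cell_centroid": tuple(cell_c),
        "nuc_centroid": tuple(nuc_c),
        "cell_area": math.pi * (diameter / 2) ** 2,
        "nuc_area": math.pi * (nuc_diameter / 2) ** 2,
        "delta_centroid": delta,
        "nuclear_offset": offset,
        "diameter": diameter,
        "nuc_diameter": nuc_diameter,
        "pixel_size": pixel_size,
    }
    return cell_mask, nuc_mask, cell_img, nuc_img, truth


def save_image_pair(directory, prefix, cell_mask, nuc_mask, truth) -> None:
    """Write a mask pair as 8-bit label PNGs plus a truth-JSON sidecar."""
    import json
    from pathlib import Path

    from skimage.io import imsave

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    imsave(directory / f"{prefix}_cell.png",
           (np.asarray(cell_mask) > 0).astype(np.uint8), check_contrast=False)
    imsave(directory / f"{prefix}_nuc.png",
           (np.asarray(nuc_mask) > 0).astype(np.uint8), check_contrast=False)
    (directory / f"{prefix}_truth.json").write_text(
        json.dumps({k: list(v) if isinstance(v, tuple) else v
                    for k, v in truth.items()}, indent=2)
    )


# ---------------------------------------------------------------------------
# growth curves


@dataclass(frozen=True)
class GrowthTruth:
    """Exponential growth ground truth: ``count(t) = n0 · 2^(t/doubling_time)``."""

    n0: float = 1.0
    doubling_time: float = 6.1
    count_cv: float = 0.1

    def validate(self) -> None:
        if self.n0 <= 0 or self.doubling_time <= 0:
            raise ValueError("n0 and doubling_time must be positive")
        if self.count_cv < 0:
            raise ValueError("count_cv must be >= 0")


def gen_growth_series(truth: GrowthTruth, times, seed: int) -> pd.DataFrame:
    """Noisy exponential growth counts at the given times (hours)."""
    truth.validate()
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted and nonnegative")
    rng = np.random.default_rng(seed)
    counts = truth.n0 * 2.0 ** (t / truth.doubling_time)
    counts = counts * _lognormal_factor(rng, truth.count_cv, t.size)
    return pd.DataFrame(
        {"time_h": t, "count": counts, "rel_count": counts / counts[0]}
    )


# ---------------------------------------------------------------------------
# BrdU / DNA bivariate cell-cycle data


def gen_brdu_dna(
    fractions,
    s_speed: float,
    n: int,
    seed: int,
    dna_cv: float = 0.05,
    brdu_background: float = 1.0,
    brdu_scale: float = 30.0,
) -> pd.DataFrame:
    """Simulate a 30-min BrdU pulse / DNA-content bivariate table.

    DNA content is Gaussian at 2N for G1, uniform on (2N, 4N) for S and
    Gaussian at 4N for G2/M (2N ≡ 2.0 a.u.).  BrdU is lognormal background
    for non-S cells and lognormal with median ``brdu_scale * s_speed`` for S
    cells, so the intra-S median scales linearly with the DNA synthesis rate.
    """
    f = np.asarray(fractions, dtype=float)
    if f.size != 3 or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be 3 nonnegative values summing to 1")
    if n <= 0:
        raise ValueError("n must be positive")
    if s_speed <= 0:
        raise ValueError("s_speed must be positive")
    rng = np.random.default_rng(seed)
    phase_idx = rng.choice(3, size=n, p=f)
    phases = np.array(["G1", "S", "G2M"], dtype=object)[phase_idx]

    dna = np.empty(n)
    g1 = phase_idx == 0
    s = phase_idx == 1
    g2 = phase_idx == 2
    dna[g1] = rng.normal(2.0, 2.0 * dna_cv, size=int(g1.sum()))
    dna[s] = rng.uniform(2.0, 4.0, size=int(s.sum()))
    dna[g2] = rng.normal(4.0, 4.0 * dna_cv, size=int(g2.sum()))

    brdu = brdu_background * _lognormal_factor(rng, 0.4, n)
    brdu[s] = brdu_scale * s_speed * _lognormal_factor(rng, 0.3, int(s.sum()))

    return pd.DataFrame({"dna": dna, "brdu": brdu, "true_phase": phases})


# ---------------------------------------------------------------------------
# H2B fluorescent-timer events


@dataclass(frozen=True)
class FTTruth:
    """Fluorescent-timer ground truth.

    ``T`` is the cell-cycle length (h) and ``tau`` the blue→red maturation
    time of the timer protein (h, default 1.5 within the reported 1–2 h
    range).  The package's timer model: histone-timer synthesis at constant
    rate k with total content doubling over one cycle (k = H0/T), sharp
    colour conversion at protein age tau.  A cell of age ``a`` then shows
    blue = k·min(a, tau) and total = H0 + k·a, so B/(B+R) = min(a, tau)/(T + a).
    """

    T: float = 6.0
    tau: float = 1.5
    noise_cv: float = 0.05

    def validate(self) -> None:
        if not (0 < self.tau < self.T):
            raise ValueError("need 0 < tau < T")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def ft_age_density(a, T: float):
    """Steady-state cycling-age density f(a) = (2 ln2 / T) · 2^(−a/T), a ∈ [0, T].

    A steadily cycling population is enriched for young cells because every
    division creates two age-zero cells; f integrates to 1 on [0, T] and has
    mean T·(1/ln2 − 1).
    """
    a = np.asarray(a, dtype=float)
    out = (2.0 * math.log(2.0) / T) * 2.0 ** (-a / T)
    return np.where((a >= 0) & (a <= T), out, 0.0)


def sample_cycling_age(rng: np.random.Generator, T: float, size: int) -> np.ndarray:
    """Inverse-CDF sampling of the steady-state cycling-age density."""
    u = rng.uniform(0, 1, size=size)
    # CDF F(a) = 2 (1 − 2^{−a/T});  F⁻¹(u) = −T log2(1 − u/2)
    return -T * np.log2(1.0 - u / 2.0)


def gen_ft_events(truth: FTTruth, n: int, seed: int) -> pd.DataFrame:
    """Simulate per-cell blue/red fluorescent-timer intensities.

    Ages are drawn from the steady-state cycling-age density; blue and red
    follow the timer model in :class:`FTTruth` with independent lognormal
    noise of CV ``noise_cv`` on each channel.
    """
    truth.validate()
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    age = sample_cycling_age(rng, truth.T, n)
    h0 = 1.0
    k = h0 / truth.T
    blue = k * np.minimum(age, truth.tau)
    total = h0 + k * age
    red = total - blue
    blue = blue * _lognormal_factor(rng, truth.noise_cv, n)
    red = red * _lognormal_factor(rng, truth.noise_cv, n)
    return pd.DataFrame({"blue": blue, "red": red, "true_age": age})


# ---------------------------------------------------------------------------
# ergodic snapshot of a multi-stage process


def gen_snapshot(durations, n: int, seed: int) -> np.ndarray:
    """Discrete-event snapshot occupancy of a sequential multi-stage process.

    ``n`` cells enter stage 1 at a constant rate (arrival times uniform over
    a window four times the total transit time, i.e. burn-in ≥ 3·Σdurations)
    and advance deterministically after each stage's duration.  Returns the
    per-stage occupancy counts of cells still in transit at the final
    snapshot; occupancy fractions converge to durations/Σdurations.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0 or np.any(d <= 0):
        raise ValueError("durations must be positive")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    total = float(d.sum())
    window = 4.0 * total
    arrival = rng.uniform(0.0, window, size=n)
    age = window - arrival  # age of each cell at the snapshot
    in_transit = age < total
    edges = np.concatenate([[0.0], np.cumsum(d)])
    stage = np.searchsorted(edges, age[in_transit], side="right") - 1
    return np.bincount(stage, minlength=d.size)


# ---------------------------------------------------------------------------
# human-style CBC intervention panels


@dataclass(frozen=True)
class EffectProfile:
    """Piecewise-linear treatment-effect time course for one analyte.

    ``breakpoints`` is a sequence of (day, effect) pairs; the effect is
    linearly interpolated between them and equals the neutral value (0 for
    additive, 1 for multiplicative) outside their span.
    """

    breakpoints: tuple
    mode: str = "additive"  # or "multiplicative"

    def value_at(self, day) -> np.ndarray:
        day = np.asarray(day, dtype=float)
        neutral = 0.0 if self.mode == "additive" else 1.0
        if not self.breakpoints:
            return np.full(day.shape, neutral)
        xs = np.array([b[0] for b in self.breakpoints], dtype=float)
        ys = np.array([b[1] for b in self.breakpoints], dtype=float)
        return np.interp(day, xs, ys, left=neutral, right=ys[-1])

    def apply(self, baseline, day):
        eff = self.value_at(day)
        if self.mode == "additive":
            return baseline + eff
        if self.mode == "multiplicative":
            return baseline * eff
        raise ValueError(f"unknown effect mode {self.mode!r}")


@dataclass(frozen=True)
class CohortDesign:
    """Design of a placebo-controlled CBC intervention study.

    ``analyte_baselines`` maps analyte name → (mean, between_subject_sd,
    within_subject_sd); ``treatment_effects`` maps analyte name →
    :class:`EffectProfile` applied to treated subjects only.
    """

    n_treated: int = 25
    n_placebo: int = 9
    baseline_weeks: int = 4
    treatment_weeks: int = 3
    followup_weeks: int = 5
    sampling_interval: int = 7
    analyte_baselines: dict = field(default_factory=dict)
    treatment_effects: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_treated <= 0 or self.n_placebo <= 0:
            raise ValueError("subject counts must be positive")
        for wk in (self.baseline_weeks, self.treatment_weeks, self.followup_weeks):
            if wk <= 0:
                raise ValueError("study durations must be positive")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if not self.analyte_baselines:
            raise ValueError("analyte_baselines must be non-empty")

    def timepoints(self) -> np.ndarray:
        """Sampling days; negative days are baseline, treatment starts day 0."""
        iv = self.sampling_interval
        baseline = np.arange(-self.baseline_weeks * 7, 0, iv)
        post = np.arange(iv, (self.treatment_weeks + self.followup_weeks) * 7 + 1, iv)
        return np.concatenate([baseline, post]).astype(float)


def study1_design(
    mcv_effect_fl: float = 4.0,
    retic_peak_fold: float = 1.4,
    retic_dip_fold: float = 0.75,
    hgb_peak_fold: float = 1.05,
    rdw_effect_fl: float = 3.0,
    within_sd_scale: float = 1.0,
) -> CohortDesign:
    """Default cohort mirroring intervention study #1.

    25 treated / 9 placebo subjects, 4 baseline weeks, 3 treatment weeks of
    Epo, 5 follow-up weeks, weekly sampling.  Treated subjects show:
    hemoglobin up ~5% during treatment, reticulocytes up during treatment
    then dipping below baseline after cessation, and MCV (and RDW-SD) rising
    during treatment and persisting through follow-up.
    """
    t_end = 21.0  # treatment period, days
    f_end = t_end + 35.0
    return CohortDesign(
        analyte_baselines={
            "MCV": (90.0, 3.0, 0.8 * within_sd_scale),
            "RDW_SD": (42.0, 2.5, 0.7 * within_sd_scale),
            "retic": (50.0, 8.0, 4.0 * within_sd_scale),
            "hemoglobin": (14.5, 0.8, 0.25 * within_sd_scale),
        },
        treatment_effects={
            "MCV": EffectProfile(
                ((0.0, 0.0), (t_end, mcv_effect_fl), (f_end, mcv_effect_fl)),
                mode="additive",
            ),
            "RDW_SD": EffectProfile(
                ((0.0, 0.0), (t_end, rdw_effect_fl), (f_end, rdw_effect_fl)),
                mode="additive",
            ),
            "retic": EffectProfile(
                (
                    (0.0, 1.0),
                    (7.0, retic_peak_fold),
                    (t_end, retic_peak_fold),
                    (t_end + 7.0, retic_dip_fold),
                    (t_end + 21.0, retic_dip_fold),
                    (f_end, 1.0),
                ),
                mode="multiplicative",
            ),
            "hemoglobin": EffectProfile(
                (
                    (0.0, 1.0),
                    (7.0, hgb_peak_fold),
                    (t_end, hgb_peak_fold),
                    (t_end + 14.0, 1.0),
                ),
                mode="multiplicative",
            ),
        },
    )


def gen_cbc_panel(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Simulate a subject × timepoint × analyte CBC panel (long format).

    Each subject gets a latent per-analyte baseline (population mean plus a
    between-subject Gaussian deviation); observations add within-subject
    Gaussian noise.  Treated subjects receive the design's effect profiles
    from day 0 on; placebo subjects receive noise only.  Truth columns:
    ``true_baseline`` (latent subject level) and ``true_effect`` (the applied
    effect on the analyte's natural scale).
    """
    design.validate()
    rng = np.random.default_rng(seed)
    days = design.timepoints()
    rows = []
    groups = ["treated"] * design.n_treated + ["placebo"] * design.n_placebo
    for si, group in enumerate(groups):
        subject = f"S{si + 1:03d}"
        for analyte, (mean, between_sd, within_sd) in design.analyte_baselines.items():
            latent = mean + rng.normal(0.0, between_sd)
            clean = np.full(days.shape, latent)
            if group == "treated" and analyte in design.treatment_effects:
                profile = design.treatment_effects[analyte]
                post = days >= 0
                clean = clean.copy()
                clean[post] = profile.apply(latent, days[post])
            values = clean + rng.normal(0.0, within_sd, size=days.size)
            for day, value, cl in zip(days, values, clean):
                rows.append(
                    {
                        "subject_id": subject,
                        "group": group,
                        "time_days": float(day),
                        "analyte": analyte,
                        "value": float(value),
                        "true_baseline": latent,
                        "true_effect": float(cl - latent),
                    }
                )
    return pd.DataFrame(rows)
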