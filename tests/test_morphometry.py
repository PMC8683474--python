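"""Morphometry pipeline: filtering, calibration, offsets, gating, staging."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from erythrokit import morphometry as mm
from erythrokit import synthetic as syn


class TestFilterOutliers:
    def test_constant_vector_removes_nothing(self):
        kept, frac = mm.filter_outliers(np.full(100, 7.0), k=3)
        assert kept.all() and frac == 0.0

    def test_gaussian_tail_fraction_matches_two_phi(self, rng):
        x = rng.normal(size=100_000)
        _, frac = mm.filter_outliers(x, k=3)
        expected = 2 * stats.norm.sf(3)  # ≈ 0.27%
        assert abs(frac - expected) < 3 * math.sqrt(expected / 100_000)

    def test_injected_gross_outliers_removed_per_group(self):
        spec = syn.BeadSpec(outlier_frac=0.01, n_per_bead=10_000)
        df = syn.gen_bead_events(spec, seed=21)
        for _, grp in df.groupby("true_diameter"):
            kept, frac = mm.filter_outliers(grp["area"], k=3, log_scale=True)
            assert 0.005 < frac < 0.02
            # every flagged truth outlier must be among the removed
            assert not (grp["is_outlier"].to_numpy() & kept).any()

    def test_rejects_empty_and_nonpositive_log_input(self):
        with pytest.raises(ValueError):
            mm.filter_outliers([])
        with pytest.raises(ValueError):
            mm.filter_outliers([1.0, -1.0], log_scale=True)


class TestBeadCalibration:
    def test_noiseless_fit_recovers_exact_quadratic(self):
        spec = syn.BeadSpec(area_cv=0.0, rim_bias=0.0, pixel_size=1.0,
                            n_per_bead=50)
        cal = mm.fit_bead_calibration(syn.gen_bead_events(spec, seed=0))
        assert cal.c2 == pytest.approx(math.pi / 4, abs=1e-6)
        assert cal.c0 == pytest.approx(0.0, abs=1e-6)
        assert cal.c1 == pytest.approx(0.0, abs=1e-6)
        assert cal.r2 == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_with_rim_bias_within_two_percent(self, bead_events,
                                                         bead_calibration):
        d, _ = mm.area_to_diameter(
            bead_calibration, bead_events["area"].to_numpy(), warn=False
        )
        med = pd.Series(d).groupby(bead_events["true_diameter"].to_numpy()).median()
        for true_d, est in med.items():
            assert abs(est / true_d - 1) < 0.02

    def test_requires_three_distinct_diameters(self):
        spec = syn.BeadSpec(diameters=(2.0, 5.0), n_per_bead=50)
        with pytest.raises(ValueError, match="3 distinct"):
            mm.fit_bead_calibration(syn.gen_bead_events(spec, seed=0))

    def test_non_monotone_fit_names_offending_interval(self):
        # areas decreasing with diameter force a non-monotone quadratic
        rows = []
        for d, a in [(2.0, 100.0), (5.0, 50.0), (10.0, 10.0)]:
            rows.append(pd.DataFrame({
                "true_diameter": d, "area": np.full(20, a) * (1 + 1e-3 * np.arange(20)),
            }))
        with pytest.raises(ValueError, match="non-monotone"):
            mm.fit_bead_calibration(pd.concat(rows, ignore_index=True))


class TestAreaToDiameter:
    def test_pure_disc_inversion(self):
        cal = mm.BeadCalibration(0.0, 0.0, math.pi / 4, 1.0, (1.0, 20.0))
        d, ex = mm.area_to_diameter(cal, [25 * math.pi / 4])
        assert d[0] == pytest.approx(5.0, abs=1e-12)
        assert not ex[0]

    @settings(deadline=None, derandomize=True)
    @given(
        c0=st.floats(-50, 50),
        c1=st.floats(0, 20),
        c2=st.floats(0.1, 10),
        d=st.floats(1.0, 20.0),
    )
    def test_round_trip_is_algebraically_exact(self, c0, c1, c2, d):
        cal = mm.BeadCalibration(c0, c1, c2, 1.0, (1.0, 20.0))
        est, _ = mm.area_to_diameter(cal, cal.forward([d]), warn=False)
        assert abs(est[0] - d) < 1e-9 * max(1.0, d)

    def test_extrapolation_is_flagged_and_warned(self):
        cal = mm.BeadCalibration(0.0, 0.0, math.pi / 4, 1.0, (2.0, 10.0))
        with pytest.warns(UserWarning, match="extrapolated"):
            _, ex = mm.area_to_diameter(cal, [cal.forward(50.0)])
        assert ex[0]

    def test_calibrated_erythroblast_medians_match_truth(self, bead_calibration):
        stages = [
            syn.StageSpec("epor", 0.5, 7.5, 0.08, 0.08, 0.02),
            syn.StageSpec("bclxl", 0.5, 6.7, 0.08, 0.20, 0.03),
        ]
        # erythroid areas share the bead pixel grid (0.5 μm/px) but have no
        # rim bias, so invert with a rim-free calibration
        spec = syn.BeadSpec(rim_bias=0.0)
        cal = mm.fit_bead_calibration(syn.gen_bead_events(spec, seed=31))
        events = syn.gen_erythroid_events(stages, 50_000, seed=32)
        d, _ = mm.area_to_diameter(cal, events["bf_area"].to_numpy(), warn=False)
        med = pd.Series(d).groupby(events["stage"].to_numpy()).median()
        assert abs(med["epor"] / 7.5 - 1) < 0.02
        assert abs(med["bclxl"] / 6.7 - 1) < 0.02


class TestMaskFeatures:
    def test_concentric_pair_has_zero_offset(self):
        cm, nm, ci, ni, _ = syn.gen_image_pair(10.0, 6.0, 0.0, 0.25, seed=0)
        f = mm.mask_features(cm, nm, ci, ni, pixel_size=0.25)
        assert f.delta_centroid < 0.25  # within one pixel of exact zero
        assert f.nuc_area <= f.cell_area

    @pytest.mark.parametrize("offset", [0.05, 0.1, 0.2, 0.3])
    def test_offset_recovered_within_pixel_resolution(self, offset):
        diameter, px = 10.0, 0.25
        cm, nm, ci, ni, truth = syn.gen_image_pair(diameter, 6.0 if offset <= 0.2 else 3.0,
                                                   offset, px, seed=int(offset * 100))
        f = mm.mask_features(cm, nm, ci, ni, pixel_size=px)
        assert abs(f.delta_centroid - truth["delta_centroid"]) < px
        assert abs(f.nuclear_offset - offset) < px / diameter

    def test_rigid_motion_and_gain_invariance(self):
        cm, nm, ci, ni, _ = syn.gen_image_pair(10.0, 6.0, 0.2, 0.25, seed=5)
        base = mm.mask_features(cm, nm, ci, ni, pixel_size=0.25)
        pad = [(3, 0), (5, 0)]
        shifted = [np.pad(a, pad)[: a.shape[0] + 3, : a.shape[1] + 5]
                   for a in (cm, nm, ci, ni)]
        rotated = [np.rot90(a) for a in (cm, nm, ci, ni)]
        scaled = (cm, nm, ci * 7.0, ni * 3.0)
        for imgs in (shifted, rotated, scaled):
            f = mm.mask_features(imgs[0], imgs[1], imgs[2], imgs[3], pixel_size=0.25)
            assert f.delta_centroid == pytest.approx(base.delta_centroid, abs=1e-9)
            assert f.nuclear_offset == pytest.approx(base.nuclear_offset, abs=1e-9)

    def test_offset_invariant_to_finer_rasterization(self):
        results = {}
        for px in (0.4, 0.1):
            cm, nm, ci, ni, _ = syn.gen_image_pair(10.0, 6.0, 0.15, px, seed=9)
            results[px] = mm.mask_features(cm, nm, ci, ni, pixel_size=px)
        assert abs(results[0.1].nuclear_offset - 0.15) < 0.1 / 10.0
        assert abs(results[0.4].nuclear_offset - 0.15) < 0.4 / 10.0

    def test_empty_or_mismatched_masks_rejected(self):
        cm, nm, *_ = syn.gen_image_pair(10.0, 6.0, 0.1, 0.5, seed=1)
        with pytest.raises(ValueError):
            mm.mask_features(cm, np.zeros_like(nm))
        with pytest.raises(ValueError):
            mm.mask_features(cm[:-1], nm)


class TestCd71Mapping:
    def test_identity_mapping_recovered(self):
        df = pd.DataFrame({"cd71_area": np.linspace(10, 100, 60)})
        df["bf_area"] = df["cd71_area"]
        slope, intercept, r, _ = mm.map_cd71_to_bf_area(df)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(1.0)

    def test_noisy_linear_map_slope_recovered(self, rng):
        cd71 = rng.uniform(50, 300, size=5_000)
        bf = (1.2 * cd71 + 50) * rng.lognormal(0, 0.02, size=5_000)
        df = pd.DataFrame({"cd71_area": cd71, "bf_area": bf})
        slope, *_ = mm.map_cd71_to_bf_area(df)
        assert 1.18 < slope < 1.22

    def test_imputed_areas_feed_calibration_within_three_percent(self):
        spec = syn.BeadSpec(rim_bias=0.0)
        cal = mm.fit_bead_calibration(syn.gen_bead_events(spec, seed=41))
        events = syn.gen_erythroid_events(
            [syn.StageSpec("s", 1.0, 7.5, 0.08, 0.1, 0.02)], 20_000, seed=42
        )
        events = events.copy()
        hide = np.zeros(len(events), dtype=bool)
        hide[::3] = True
        events.loc[hide, "bf_area"] = np.nan
        *_, imputed = mm.map_cd71_to_bf_area(events)
        d, _ = mm.area_to_diameter(cal, imputed[hide], warn=False)
        assert abs(np.median(d) / 7.5 - 1) < 0.03

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"cd71_area": np.full(60, 5.0),
                           "bf_area": np.arange(60.0)})
        with pytest.raises(ValueError, match="degenerate|constant"):
            mm.map_cd71_to_bf_area(df)


class TestReticGate:
    def test_mixture_labels_agree_with_truth(self, erythroid_events):
        gate = mm.gate_reticulocytes(erythroid_events)
        truth = ~erythroid_events["true_nucleated"].to_numpy()
        agreement = (gate.labels == truth).mean()
        assert gate.bimodal
        assert agreement >= 0.99

    def test_gain_change_leaves_labels_unchanged(self, erythroid_events):
        gate = mm.gate_reticulocytes(erythroid_events)
        boosted = erythroid_events.assign(
            draq5_total=erythroid_events["draq5_total"] * 2.0
        )
        gate2 = mm.gate_reticulocytes(boosted)
        assert np.array_equal(gate.labels, gate2.labels)

    def test_unimodal_sample_flagged_unreliable(self):
        events = syn.gen_erythroid_events(
            [syn.StageSpec("nuc", 1.0, 7.0, 0.05, 0.1, 0.02)], 2_000, seed=51
        )
        with pytest.warns(UserWarning, match="unreliable"):
            gate = mm.gate_reticulocytes(events)
        assert not gate.bimodal

    def test_too_few_events_rejected(self, erythroid_events):
        with pytest.raises(ValueError):
            mm.gate_reticulocytes(erythroid_events.head(50))


class TestQuintileStaging:
    def test_reference_splits_into_equal_bins(self):
        ref = np.arange(1.0, 101.0)
        staging = mm.quintile_stage(ref, {"ref": ref})
        counts = staging.per_bin_summaries.set_index("bin")["count"]
        assert counts.tolist() == [20, 20, 20, 20, 20]

    def test_edge_values_assigned_to_lower_bin(self):
        edges = np.array([1.0, 2.0, 3.0, 4.0])
        bins = mm.assign_quintile(edges, [1.0, 2.0, 3.0, 4.0, 4.5, 0.5])
        assert bins.tolist() == [1, 2, 3, 4, 5, 1]

    def test_epo_shift_raises_median_diameter_in_every_bin(self):
        saline_stages = [
            syn.StageSpec("a", 0.5, 7.0, 0.06, 0.08, 0.03),
            syn.StageSpec("b", 0.5, 6.0, 0.06, 0.22, 0.04),
        ]
        epo_stages = [  # same offsets, uniformly larger cells
            syn.StageSpec("a", 0.5, 7.7, 0.06, 0.08, 0.03),
            syn.StageSpec("b", 0.5, 6.8, 0.06, 0.22, 0.04),
        ]
        saline = syn.gen_erythroid_events(saline_stages, 20_000, seed=61,
                                          sample_id="saline")
        epo = syn.gen_erythroid_events(epo_stages, 20_000, seed=62,
                                       sample_id="epo")
        staging = mm.quintile_stage(
            saline["true_offset"].to_numpy(),
            {
                "saline": saline["true_offset"].to_numpy(),
                "epo": epo["true_offset"].to_numpy(),
            },
            {
                "saline": saline["true_diameter"].to_numpy(),
                "epo": epo["true_diameter"].to_numpy(),
            },
        )
        piv = staging.per_bin_summaries.pivot(
            index="bin", columns="sample_id", values="median_feature"
        )
        assert (piv["epo"] > piv["saline"]).all()

    def test_empty_query_omitted_with_warning(self):
        ref = np.linspace(0, 1, 100)
        with pytest.warns(UserWarning, match="empty"):
            staging = mm.quintile_stage(ref, {"ok": ref, "bad": np.array([])})
        assert set(staging.assignments) == {"ok"}


class TestCompositeQuantileRatio:
    def _samples(self, seed, shift=1.0):
        stages = [syn.StageSpec("s", 1.0, 7.0 * shift, 0.08, 0.1, 0.02)]
        return syn.gen_erythroid_events(stages, 5_000, seed=seed)

    def test_identical_samples_give_unit_ratios(self):
        df = self._samples(71)
        out = mm.composite_quantile_ratio(
            {"a": df, "b": df.copy(), "ref": df.copy()}, reference="ref"
        )
        for sid in ("a", "b"):
            mat = out[sid]
            np.testing.assert_allclose(mat[np.isfinite(mat)], 1.0)

    def test_pooled_edges_split_pooled_events_evenly(self):
        dfs = {f"s{i}": self._samples(80 + i) for i in range(3)}
        out = mm.composite_quantile_ratio(dfs, reference="s0", k=5)
        edges_a, _ = out["_edges"]
        pooled = np.concatenate([d["hcd4"].to_numpy() for d in dfs.values()])
        shares = np.diff(
            np.searchsorted(np.sort(pooled), edges_a).tolist() + [pooled.size],
            prepend=0,
        ) / pooled.size
        assert np.all(np.abs(shares - 0.2) < 0.01)

    def test_diameter_driven_by_one_channel_is_flat_along_other(self, rng):
        def build(seed):
            r = np.random.default_rng(seed)
            n = 8_000
            cha = r.lognormal(5, 0.5, n)
            chb = r.lognormal(5, 0.5, n)
            return pd.DataFrame({
                "hcd4": cha, "gfp": chb,
                # diameter depends on chB rank only
                "true_diameter": 6.0 + 2.0 * (stats.rankdata(chb) / n),
            })

        samples = {"ref": build(1), "x": build(2)}
        out = mm.composite_quantile_ratio(samples, reference="ref", k=4)
        means = out["_means"]["x"]
        # within each chB column, means barely vary across chA rows
        col_spread = np.nanmax(means, axis=0) - np.nanmin(means, axis=0)
        col_level = np.nanmean(means, axis=0)
        assert np.all(col_spread / col_level < 0.05)

    def test_missing_reference_rejected(self):
        df = self._samples(99)
        with pytest.raises(ValueError, match="reference"):
            mm.composite_quantile_ratio({"a": df}, reference="zzz")


class TestExpressionSizeResponse:
    def test_monotone_relation_gives_perfect_rho(self, rng):
        e = rng.uniform(1, 100, size=500)
        d = 5 + 0.01 * e
        table, rho, p = mm.expression_size_response(e, d, n_bins=5)
        assert rho == pytest.approx(1.0)
        assert len(table) == 5

    def test_independent_expression_rarely_significant(self):
        hits = 0
        runs = 50
        for s in range(runs):
            r = np.random.default_rng(1000 + s)
            e = r.lognormal(5, 0.5, 2_000)
            d = r.normal(7, 0.5, 2_000)
            _, _, p = mm.expression_size_response(e, d, n_bins=6)
            hits += p > 0.05
        assert hits >= int(0.9 * runs)

    def test_constant_expression_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mm.expression_size_response(np.full(100, 2.0), np.arange(100.0),
                                        n_bins=4)
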