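"""Tests of the synthetic calf phantom and cohort generator."""

import numpy as np
import pytest

from calfmolli.phantom import (CohortConfig, PhantomConfig,
                               PhantomConfigError, generate_cohort,
                               generate_phantom, simulate_ir_signal)
from calfmolli.roi import ARTERIES, MUSCLE_COMPARTMENTS


class TestSignalModel:
    def test_long_ti_limit_is_A(self):
        assert simulate_ir_signal(1e9, 1000.0, 2000.0, 1200.0) == pytest.approx(1000.0)

    def test_zero_ti_is_A_minus_B(self):
        assert simulate_ir_signal(0.0, 1000.0, 2000.0, 1200.0) == pytest.approx(-1000.0)

    def test_magnitude_at_one_time_constant(self):
        # |1000 - 2000 e^{-1}| evaluated independently
        expected = abs(1000.0 - 2000.0 * 0.36787944117144233)
        got = simulate_ir_signal(1200.0, 1000.0, 2000.0, 1200.0, magnitude=True)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(264.24111765711533, rel=1e-12)

    def test_nonpositive_t1_rejected(self):
        with pytest.raises(ValueError):
            simulate_ir_signal(100.0, 1.0, 2.0, 0.0)


class TestGeneratePhantom:
    def test_uniform_noiseless_voxels_follow_regional_model(self):
        cfg = PhantomConfig(grid_size=64, pixel_spacing_mm=3.0,
                            noise_sigma=0.0, noise_model="none",
                            heterogeneity="uniform")
        pre, post, regions, truth = generate_phantom(cfg)
        post_map = cfg.resolved_t1_post()
        for name in MUSCLE_COMPARTMENTS + ARTERIES:
            mask = regions[name]
            A = cfg.A_of(name)
            for i, t in enumerate(pre.ti_ms):
                expect = abs(simulate_ir_signal(t, A, cfg.inv_efficiency * A,
                                                cfg.region_t1_pre[name]))
                assert np.max(np.abs(pre.frames[i][mask] - expect)) == 0.0
                expect_post = abs(simulate_ir_signal(t, A, cfg.inv_efficiency * A,
                                                     post_map[name]))
                assert np.max(np.abs(post.frames[i][mask] - expect_post)) == 0.0

    def test_seed_determinism(self):
        cfg = PhantomConfig(grid_size=64, pixel_spacing_mm=3.0, seed=9)
        out1 = generate_phantom(cfg)
        out2 = generate_phantom(cfg)
        np.testing.assert_array_equal(out1[0].frames, out2[0].frames)
        np.testing.assert_array_equal(out1[1].frames, out2[1].frames)

    def test_masks_are_disjoint_and_nonempty(self):
        _, _, regions, truth = generate_phantom(
            PhantomConfig(grid_size=64, pixel_spacing_mm=3.0))
        total = np.zeros(regions[MUSCLE_COMPARTMENTS[0]].shape, dtype=int)
        for name in MUSCLE_COMPARTMENTS + ARTERIES:
            assert regions[name].any()
            total += regions[name]
        assert total.max() == 1
        # areas match the voxel count times the pixel area
        for name in MUSCLE_COMPARTMENTS:
            assert truth.areas_mm2[name] == pytest.approx(regions[name].sum() * 9.0)

    def test_rician_background_mean(self):
        """Background (A=0) magnitude mean equals the Rician small-signal
        limit sigma*sqrt(pi/2) within 3 standard errors."""
        sigma = 5.0
        cfg = PhantomConfig(grid_size=128, pixel_spacing_mm=1.48,
                            noise_sigma=sigma, noise_model="rician", seed=2)
        pre, _, regions, _ = generate_phantom(cfg)
        leg_any = np.zeros(pre.shape, dtype=bool)
        for m in regions.labels.values():
            leg_any |= m
        bg = pre.frames[0][~leg_any]
        assert bg.size > 10_000
        expected_mean = sigma * np.sqrt(np.pi / 2)
        expected_sd = sigma * np.sqrt(2 - np.pi / 2)
        se = expected_sd / np.sqrt(bg.size)
        assert abs(bg.mean() - expected_mean) < 3 * se

    def test_gaussian_noise_mean_converges_to_clean_signal(self):
        """Mean over replicates of a gaussian-noise voxel approaches the
        noiseless value (3-SE band at 10^4 draws)."""
        rng = np.random.default_rng(4)
        sigma, n = 20.0, 10_000
        clean = simulate_ir_signal(1440.0, 1000.0, 1950.0, 1700.0)
        draws = clean + rng.normal(0, sigma, n)
        assert abs(draws.mean() - clean) < 3 * sigma / np.sqrt(n)

    def test_textured_truth_is_ecv_consistent(self):
        _, _, _, truth = generate_phantom(
            PhantomConfig(grid_size=64, pixel_spacing_mm=3.0))
        for name in MUSCLE_COMPARTMENTS:
            num = 1 / truth.region_t1_post[name] - 1 / truth.region_t1_pre[name]
            den = 1 / truth.blood_t1_post_ms - 1 / truth.blood_t1_pre_ms
            ecv = (1 - truth.hematocrit) * num / den
            assert truth.region_ecv[name] == pytest.approx(ecv, rel=1e-12)

    def test_post_contrast_below_native_everywhere_in_truth(self):
        _, _, _, truth = generate_phantom(
            PhantomConfig(grid_size=64, pixel_spacing_mm=3.0))
        for name in truth.region_t1_pre:
            assert truth.region_t1_post[name] < truth.region_t1_pre[name]

    def test_invalid_configs_rejected(self):
        with pytest.raises(PhantomConfigError):
            PhantomConfig(ti_list_ms=(90.0, 90.0, 240.0, 756.0))
        with pytest.raises(PhantomConfigError):
            PhantomConfig(inv_efficiency=2.5)
        with pytest.raises(PhantomConfigError):
            PhantomConfig(noise_sigma=-1.0)
        with pytest.raises(PhantomConfigError):
            PhantomConfig(hematocrit=1.4)
        with pytest.raises(PhantomConfigError):
            PhantomConfig(region_t1_post={**PhantomConfig().resolved_t1_post(),
                                          "AM": 5000.0})


class TestGenerateCohort:
    def test_group_sizes_and_labels(self):
        cfg = CohortConfig(n_pad=0, n_control=3, grid_size=32,
                           pixel_spacing_mm=6.0, bilateral=False, seed=0)
        bundles, table = generate_cohort(cfg)
        assert len(bundles) == 3
        assert all(b.group == "control" for b in bundles)
        assert (table["group"] == "control").all()

    def test_ground_truth_table_determinism(self):
        cfg = CohortConfig(n_pad=3, n_control=3, grid_size=32,
                           pixel_spacing_mm=6.0, bilateral=False, seed=12)
        _, t1 = generate_cohort(cfg)
        _, t2 = generate_cohort(cfg)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_configured_medians_are_hit_by_balanced_sampling(self):
        """The sample median of generated ground truth equals the
        configured group median (balanced-quantile draws)."""
        cfg = CohortConfig(n_pad=50, n_control=50, grid_size=32,
                           pixel_spacing_mm=6.0, bilateral=False, seed=7)
        _, table = generate_cohort(cfg)
        for grp in ("pad", "control"):
            sub = table[table["group"] == grp]
            for comp in ("AM", "SM"):
                configured = cfg.anchors[grp]["ecv"][comp][0]
                assert sub[f"ecv_{comp}"].median() == pytest.approx(
                    configured, abs=1e-9)
            configured_t1 = cfg.anchors[grp]["t1_pre"]["AM"][0]
            assert sub["t1pre_AM"].median() == pytest.approx(configured_t1, abs=1e-6)

    def test_disease_direction_of_covariates(self):
        cfg = CohortConfig(n_pad=20, n_control=20, grid_size=32,
                           pixel_spacing_mm=6.0, bilateral=False, seed=3)
        _, table = generate_cohort(cfg)
        pad = table[table["group"] == "pad"]
        ctl = table[table["group"] == "control"]
        assert pad["abi_rest"].mean() < ctl["abi_rest"].mean()
        assert pad["pwt_s"].mean() < ctl["pwt_s"].mean()
        assert np.isnan(ctl["cot_s"]).all() and np.isfinite(pad["cot_s"]).all()
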