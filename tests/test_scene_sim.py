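"""Trial simulator: stratification, biomass calibration, canopy model."""

import numpy as np
import pytest

from agbsat.raster import zonal_means
from agbsat.scene_sim import (
    BiomassDistribution,
    CanopyModelParams,
    TrialDesign,
    canopy_reflectance,
    gradient_trial,
    render_scene,
    sample_trial,
    simulate,
)


class TestSampleTrial:
    def test_default_counts_and_bounds(self, default_design, default_dist):
        plots = sample_trial(default_design, default_dist, seed=3)
        assert len(plots) == 96
        high = [p for p in plots if p.high_density]
        assert len(high) == 47
        assert all(p.treatment.high_nitrogen for p in high)
        agb = np.array([p.agb_kg_per_m2 for p in high])
        assert agb.min() >= 1.5 and agb.max() <= 4.5

    def test_unit_identity_kg_per_plot(self, default_plots):
        # 9 m x 3 m plots: kg/m2 * 27 = kg/plot, exactly
        for p in default_plots:
            assert p.agb_kg_per_m2 * 27.0 == pytest.approx(
                p.agb_kg_per_plot, abs=0, rel=1e-12
            )

    def test_no_high_density_requested(self, default_dist):
        design = TrialDesign(n_high_density=0)
        plots = sample_trial(design, default_dist, seed=1)
        assert sum(p.high_density for p in plots) == 0

    def test_threshold_selector(self, default_dist):
        design = TrialDesign(selector="threshold")
        plots = sample_trial(design, default_dist, seed=5)
        for p in plots:
            assert p.high_density == (p.agb_kg_per_m2 >= 3.0)

    def test_deterministic_per_seed(self, default_design, default_dist):
        a = sample_trial(default_design, default_dist, seed=9)
        b = sample_trial(default_design, default_dist, seed=9)
        assert [p.agb_kg_per_m2 for p in a] == [p.agb_kg_per_m2 for p in b]
        assert [p.treatment for p in a] == [p.treatment for p in b]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_high_density": 97},
            {"plot_width_m": 0.0},
            {"selector": "nope"},
        ],
    )
    def test_invalid_design(self, kwargs):
        with pytest.raises(ValueError):
            TrialDesign(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lower": 4.5, "upper": 1.5},
            {"sd": 0.0},
            {"mean": 5.0},
        ],
    )
    def test_invalid_distribution(self, kwargs):
        with pytest.raises(ValueError):
            BiomassDistribution(**kwargs)


class TestBiomassCalibration:
    def test_truncated_moments_match_over_seeds(self, default_design,
                                                default_dist):
        """Mean of 200 sample means/sds within +-0.05 of the targets."""
        means, sds = [], []
        for seed in range(200):
            plots = sample_trial(default_design, default_dist, seed=seed)
            agb = np.array(
                [p.agb_kg_per_m2 for p in plots if p.high_density]
            )
            means.append(agb.mean())
            sds.append(agb.std(ddof=1))
        assert np.mean(means) == pytest.approx(3.37, abs=0.05)
        assert np.mean(sds) == pytest.approx(0.7075, abs=0.05)


class TestCanopyModel:
    def test_zero_agb_gives_soil(self, default_canopy):
        assert np.allclose(
            canopy_reflectance(default_canopy, 0.0),
            default_canopy.soil_reflectance,
        )

    def test_large_agb_reaches_asymptote(self, default_canopy):
        rho = canopy_reflectance(default_canopy, 1e3)
        assert np.allclose(
            rho, default_canopy.asymptotic_reflectance, atol=1e-6
        )

    def test_monotone_and_bounded(self, default_canopy):
        grid = np.linspace(0, 6, 61)
        curves = np.stack([canopy_reflectance(default_canopy, a) for a in grid])
        assert ((curves >= 0) & (curves <= 1)).all()
        diffs = np.diff(curves, axis=0)
        # each band moves monotonically from soil toward its asymptote
        assert (np.sign(diffs) == np.sign(diffs[0])).all()

    def test_red_sensitivity_declines_with_agb(self, default_canopy):
        """Finite-difference |d rho_red / d agb| smaller at 4 than at 1."""
        i_red = 4
        h = 1e-4

        def slope(a):
            up = canopy_reflectance(default_canopy, a + h)[i_red]
            dn = canopy_reflectance(default_canopy, a - h)[i_red]
            return abs(up - dn) / (2 * h)

        assert slope(4.0) < slope(1.0)

    def test_negative_agb_rejected(self, default_canopy):
        with pytest.raises(ValueError):
            canopy_reflectance(default_canopy, -0.1)

    def test_red_must_saturate_first(self):
        params = CanopyModelParams()
        bad_k = list(params.extinction)
        bad_k[4] = 0.05  # red slower than NIR
        with pytest.raises(ValueError):
            CanopyModelParams(extinction=tuple(bad_k))


class TestRenderScene:
    def test_noiseless_pixels_equal_closed_form(self, default_dist):
        design = TrialDesign(n_plots=6, n_high_density=3, n_blocks=1)
        params = CanopyModelParams(pixel_noise_sd=0.0, plot_noise_cv=0.0)
        plots = sample_trial(design, default_dist, seed=2)
        scene = render_scene(plots, params, design, seed=2)
        table = zonal_means(scene.raster, scene.features)
        for p in plots:
            expected = canopy_reflectance(params, p.agb_kg_per_m2)
            got = table.bands.loc[p.plot_id].to_numpy()
            assert np.allclose(got, expected, atol=1e-6)

    def test_equal_agb_equal_expected_means(self, default_dist):
        design = TrialDesign(n_plots=4, n_high_density=0, n_blocks=1)
        params = CanopyModelParams(pixel_noise_sd=0.0, plot_noise_cv=0.0)
        plots = sample_trial(design, default_dist, seed=4)
        for p in plots:
            p.agb_kg_per_m2 = 2.5
        scene = render_scene(plots, params, design, seed=4)
        table = zonal_means(scene.raster, scene.features)
        vals = table.bands.to_numpy()
        assert np.allclose(vals, vals[0], atol=1e-6)

    def test_zonal_mean_within_clt_bound(self, default_dist):
        """Plot means deviate from the closed form by < 3 sd / sqrt(n_pix)."""
        design = TrialDesign(n_plots=8, n_high_density=4, n_blocks=1)
        sd = 0.02
        params = CanopyModelParams(pixel_noise_sd=sd, plot_noise_cv=0.0)
        plots = sample_trial(design, default_dist, seed=6)
        scene = render_scene(plots, params, design, seed=6)
        table = zonal_means(scene.raster, scene.features)
        px = design.pixel_size_m / design.supersample
        n_pix = (design.plot_width_m / px) * (design.plot_length_m / px)
        bound = 3 * sd / np.sqrt(n_pix)
        for p in plots:
            expected = canopy_reflectance(params, p.agb_kg_per_m2)
            got = table.bands.loc[p.plot_id].to_numpy()
            assert np.abs(got - expected).max() < bound * 1.5

    def test_overlapping_plots_rejected(self, default_dist, default_canopy):
        design = TrialDesign(n_plots=2, n_high_density=0, n_blocks=1)
        plots = sample_trial(design, default_dist, seed=1)
        plots[1].geometry = plots[0].geometry
        with pytest.raises(ValueError, match="overlap"):
            render_scene(plots, default_canopy, design, seed=1)

    def test_simulate_reproducible(self):
        design = TrialDesign(n_plots=12, n_high_density=6, n_blocks=2)
        a = simulate(design, seed=5)
        b = simulate(design, seed=5)
        assert np.array_equal(a.raster.values, b.raster.values)
        assert a.truth.equals(b.truth)

    def test_gradient_trial_spans_range(self):
        scene = gradient_trial(n_plots=40, seed=1)
        agb = scene.truth.agb_kg_per_m2
        assert len(scene.truth) == 40
        assert agb.min() >= 0.5 and agb.max() <= 4.5
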