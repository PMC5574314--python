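import numpy as np
import pytest

from mitometrics.errors import ConfigError, InfeasibleSceneError, PlacementError
from mitometrics.synthetic import (
    RoGFPSeriesParams,
    SceneParams,
    _apply_noise,
    _place_rods,
    _render_rods_3d,
    generate_bead_stack,
    generate_jc1_stack,
    generate_mitotracker_image,
    generate_rogfp1_series,
    ratio_from_oxd,
)


def small_params(**kw):
    defaults = dict(cell_area=250.0, n_mitochondria=8, pixel_size_xy=0.1, seed=42)
    defaults.update(kw)
    return SceneParams(**defaults)


class TestSceneParams:
    def test_nonpositive_physical_parameter_rejected(self):
        with pytest.raises(ConfigError):
            SceneParams(pixel_size_xy=0.0)
        with pytest.raises(ConfigError):
            SceneParams(psf_fwhm_z=-1.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ConfigError):
            SceneParams(n_mitochondria=-1)


class TestBeadStack:
    def test_noise_free_fwhm_matches_request_within_half_pixel(self):
        stack, positions = generate_bead_stack(0.4, 1.4, 1, noise_level=0, seed=0)
        zc = int(round(positions[0][0] / 0.25))
        yc = int(round(positions[0][1] / 0.08))
        xc = int(round(positions[0][2] / 0.08))
        profile = stack[zc, yc, :] - stack[zc, yc, :5].mean()
        above = np.flatnonzero(profile >= profile.max() / 2)
        width_um = (above[-1] - above[0] + 1) * 0.08
        assert abs(width_um - 0.4) <= 0.08 / 2 + 0.08  # half pixel + discretization

    def test_zero_beads(self):
        stack, positions = generate_bead_stack(0.4, 1.4, 0, noise_level=0, seed=0)
        assert positions.shape == (0, 3)
        assert np.ptp(stack) == 0  # background only

    def test_seed_determinism(self):
        a, pa = generate_bead_stack(0.4, 1.4, 9, noise_level=100, seed=5)
        b, pb = generate_bead_stack(0.4, 1.4, 9, noise_level=100, seed=5)
        assert np.array_equal(a, b) and np.array_equal(pa, pb)

    def test_too_small_image_raises_placement_error(self):
        with pytest.raises(PlacementError):
            generate_bead_stack(0.4, 1.4, 100, shape=(9, 40, 40))


class TestJC1Stack:
    def test_truth_lists_exactly_n_particles(self):
        _, _, truth = generate_jc1_stack(small_params(noise_level=0, n_mitochondria=10))
        assert len(truth.particles) == 10
        assert len(truth.decoys) == 0

    def test_preblur_ratio_by_construction(self):
        # render without blur/noise: green*200/red equals the per-rod truth everywhere
        params = small_params()
        rng = np.random.default_rng(0)
        allowed = np.zeros((80, 80), dtype=bool)
        allowed[10:70, 10:70] = True
        ratios = np.array([140.0, 260.0])
        rods, _ = _place_rods(
            allowed, np.array([20.0, 15.0]), ratios, np.array([0.8, 1.2]), 2.0, 5.0, rng
        )
        green, red = _render_rods_3d((5, 80, 80), rods, np.zeros(2), 0.2, 0.1, 0.25)
        signal = red > 0
        np.testing.assert_allclose(
            np.unique(np.round(green[signal] * 200 / red[signal], 6)), np.sort(ratios)
        )

    def test_seed_determinism(self):
        p = small_params(noise_level=150)
        g1, r1, t1 = generate_jc1_stack(p)
        g2, r2, t2 = generate_jc1_stack(p)
        assert np.array_equal(g1, g2) and np.array_equal(r1, r2)
        assert np.array_equal(t1.cell_mask, t2.cell_mask)
        for a, b in zip(t1.particles, t2.particles):
            assert a.length == b.length and a.ratio == b.ratio

    def test_truth_consistency(self):
        _, _, truth = generate_jc1_stack(small_params())
        per_particle = sum(truth.particle_area(p) for p in truth.particles)
        assert per_particle == pytest.approx(truth.true_total_mito_area)
        assert truth.true_total_mito_area <= truth.true_cell_area
        for p in truth.particles:
            assert truth.cell_mask[p.pixels[:, 0], p.pixels[:, 1]].all()

    def test_infeasible_scene_errors(self):
        with pytest.raises(InfeasibleSceneError):
            generate_jc1_stack(small_params(cell_area=30.0, n_mitochondria=40))

    def test_channel_geometry_registered(self):
        green, red, _ = generate_jc1_stack(small_params())
        assert green.shape == red.shape

    def test_decoy_injection(self):
        _, _, truth = generate_jc1_stack(
            SceneParams(cell_area=700.0, n_mitochondria=5, pixel_size_xy=0.1,
                        seed=3, decoys=True)
        )
        kinds = {d.kind: d.expected_status for d in truth.decoys}
        assert kinds == {
            "border": "excluded_truncated",
            "fused": "excluded_ramified",
            "pixel": "excluded_size",
            "oversized": "excluded_size",
        }


class TestNoiseModel:
    def test_variance_grows_with_mean(self):
        rng = np.random.default_rng(0)
        low = _apply_noise(np.full((200, 200), 0.1), 100.0, rng)
        rng = np.random.default_rng(0)
        high = _apply_noise(np.full((200, 200), 1.0), 100.0, rng)
        assert high.var() > 5 * low.var()  # shot-noise-like: var ~ mean

    def test_zero_noise_level_is_identity(self):
        img = np.random.default_rng(1).uniform(size=(10, 10))
        out = _apply_noise(img, 0.0, np.random.default_rng(0))
        assert np.array_equal(out, img)


class TestMitoTracker:
    def test_noise_free_integrated_intensity_matches_truth(self):
        image, truth = generate_mitotracker_image(small_params(noise_level=0))
        background = np.median(image[~truth.cell_mask])
        integrated = (image[truth.cell_mask] - background).sum()
        assert integrated == pytest.approx(truth.mito_integrated_intensity, rel=1e-6)

    def test_linearity_of_integrated_truth(self):
        # doubling per-rod intensity doubles the recorded truth (same geometry/seed)
        image1, t1 = generate_mitotracker_image(small_params(noise_level=0))
        image2 = image1 * 2.0
        background = np.median(image2[~t1.cell_mask])
        doubled = (image2[t1.cell_mask] - background).sum()
        assert doubled == pytest.approx(2 * t1.mito_integrated_intensity, rel=1e-6)

    def test_seed_determinism(self):
        p = small_params(noise_level=80)
        a, _ = generate_mitotracker_image(p)
        b, _ = generate_mitotracker_image(p)
        assert np.array_equal(a, b)


class TestRoGFPSeries:
    def test_oxd_zero_gives_r_red_baseline(self):
        p = RoGFPSeriesParams(true_oxd=0.0, r_red=0.6, r_ox=1.4)
        f395, f470, labels = generate_rogfp1_series(p)
        base = labels == "baseline"
        ratio = f395[base].mean() / f470[base].mean()
        assert ratio == pytest.approx(0.6, rel=1e-9)

    def test_oxd_one_gives_r_ox_baseline(self):
        p = RoGFPSeriesParams(true_oxd=1.0, r_red=0.6, r_ox=1.4)
        f395, f470, labels = generate_rogfp1_series(p)
        base = labels == "baseline"
        assert f395[base].mean() / f470[base].mean() == pytest.approx(1.4, rel=1e-9)

    def test_oxd_half_unit_instrument_factor_gives_midpoint(self):
        p = RoGFPSeriesParams(true_oxd=0.5, r_red=0.6, r_ox=1.4, instrument_factor=1.0)
        f395, f470, labels = generate_rogfp1_series(p)
        base = labels == "baseline"
        assert f395[base].mean() / f470[base].mean() == pytest.approx(1.0, rel=1e-9)

    def test_epoch_plateaus(self):
        p = RoGFPSeriesParams(true_oxd=0.3, r_red=0.5, r_ox=1.2, instrument_factor=1.5)
        f395, f470, labels = generate_rogfp1_series(p)
        for name, expected in (("oxidant", 1.2), ("reductant", 0.5)):
            sel = labels == name
            assert f395[sel].mean() / f470[sel].mean() == pytest.approx(expected, rel=1e-9)
        # instrument factor encoded in the 470 nm epoch levels
        i_f = f470[labels == "oxidant"].mean() / f470[labels == "reductant"].mean()
        assert i_f == pytest.approx(1.5, rel=1e-9)

    def test_invalid_endpoint_order_rejected(self):
        with pytest.raises(ConfigError, match="r_red"):
            RoGFPSeriesParams(r_red=1.4, r_ox=0.6)

    def test_ratio_from_oxd_endpoints(self):
        assert ratio_from_oxd(0.0, 0.6, 1.4, 2.0) == pytest.approx(0.6)
        assert ratio_from_oxd(1.0, 0.6, 1.4, 2.0) == pytest.approx(1.4)
        assert ratio_from_oxd(0.5, 0.6, 1.4, 1.0) == pytest.approx(1.0)

    def test_seed_determinism(self):
        p = RoGFPSeriesParams(noise_sd=0.05, seed=9)
        a = generate_rogfp1_series(p)
        b = generate_rogfp1_series(p)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
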