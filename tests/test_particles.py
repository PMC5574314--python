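import numpy as np
import pytest

from mitometrics.errors import ConfigError, DataError, MeasurementError
from mitometrics.particles import (
    EXCLUDED_RAMIFIED,
    EXCLUDED_SIZE,
    EXCLUDED_TRUNCATED,
    RETAINED,
    PipelineConfig,
    collapse_planes,
    deconvolve,
    filter_particles,
    measure_particles,
    run_particle_pipeline,
    select_focal_plane,
    skeleton_length_and_branches,
    threshold_mask,
)
from mitometrics.psf import PSFEstimate, FWHM_FACTOR
from mitometrics.ratiometrics import RatioImage, compute_ratio
from mitometrics.synthetic import SceneParams, generate_jc1_stack
from scipy import ndimage

from .conftest import make_stack


def uniform_ratio_image(shape, value=150.0):
    return RatioImage(
        values=np.full(shape, value), invalid_mask=np.zeros(shape, dtype=bool)
    )


class TestPipelineConfig:
    def test_size_window_order_enforced(self):
        with pytest.raises(ConfigError):
            PipelineConfig(min_area=5.0, max_area=1.0)

    def test_unknown_threshold_method_rejected(self):
        with pytest.raises(ConfigError):
            PipelineConfig(threshold_method="magic")


class TestDeconvolve:
    def make_blurred_point(self, psf):
        img = np.zeros((15, 41, 41))
        img[7, 20, 20] = 1000.0
        sigma = psf.sigma_pixels(0.08, 0.25)
        blurred = ndimage.gaussian_filter(img, sigma) + 0.1
        return make_stack(blurred, blurred)

    def test_zero_iterations_returns_input(self, nominal_psf):
        stack = self.make_blurred_point(nominal_psf)
        assert deconvolve(stack, nominal_psf, 0) is stack

    def test_peak_increases(self, nominal_psf):
        stack = self.make_blurred_point(nominal_psf)
        restored = deconvolve(stack, nominal_psf, 20)
        assert restored.green.max() > stack.green.max()

    def test_nonnegative_output(self, nominal_psf, rng):
        noisy = rng.poisson(5.0, size=(9, 30, 30)).astype(float)
        restored = deconvolve(make_stack(noisy, noisy), nominal_psf, 10)
        assert restored.green.min() >= 0 and restored.red.min() >= 0

    def test_flux_conserved_within_one_percent(self, nominal_psf):
        stack = self.make_blurred_point(nominal_psf)
        restored = deconvolve(stack, nominal_psf, 20)
        assert restored.green.sum() == pytest.approx(stack.green.sum(), rel=0.01)

    def test_subvoxel_psf_rejected(self):
        tiny = PSFEstimate.from_sigma(0.01, 0.01)
        stack = make_stack(np.ones((5, 10, 10)), np.ones((5, 10, 10)))
        with pytest.raises(ConfigError, match="one voxel"):
            deconvolve(stack, tiny, 5)


class TestSelectFocalPlane:
    def test_brightest_plane_selected(self):
        data = np.ones((6, 5, 5))
        data[4] = 3.0
        assert select_focal_plane(make_stack(data, data)) == 4

    def test_single_plane_stack(self):
        data = np.ones((1, 5, 5))
        assert select_focal_plane(make_stack(data, data)) == 0

    def test_tie_breaks_to_lower_index(self):
        data = np.ones((10, 5, 5))
        data[3] = data[7] = 2.0
        assert select_focal_plane(make_stack(data, data)) == 3

    def test_empty_stack_errors(self):
        with pytest.raises(DataError):
            select_focal_plane(make_stack(np.empty((0, 5, 5)), np.empty((0, 5, 5))))


class TestCollapsePlanes:
    def test_constant_stack_collapses_to_same_value(self):
        data = np.full((10, 6, 6), 4.5)
        collapsed = collapse_planes(make_stack(data, data), center=5, half_window=2)
        assert np.all(collapsed.green == 4.5)
        assert collapsed.ndim == 2

    def test_half_window_zero_returns_center_plane(self):
        data = np.arange(5 * 4 * 4, dtype=float).reshape(5, 4, 4)
        collapsed = collapse_planes(make_stack(data, data), center=2, half_window=0)
        np.testing.assert_array_equal(collapsed.green, data[2])

    def test_window_exceeding_bounds_errors(self):
        data = np.ones((10, 4, 4))
        with pytest.raises(DataError, match="shift the window center"):
            collapse_planes(make_stack(data, data), center=1, half_window=2)

    def test_mean_not_max(self):
        data = np.zeros((5, 4, 4))
        data[2] = 10.0
        collapsed = collapse_planes(make_stack(data, data), center=2, half_window=2)
        assert np.all(collapsed.green == 2.0)


class TestThresholdMask:
    def test_two_level_image_split_exactly(self):
        img = np.full((20, 20), 10.0)
        img[5:9, 5:15] = 1000.0
        mask = threshold_mask(make_stack(img / 2, img / 2))
        expected = np.zeros((20, 20), dtype=bool)
        expected[5:9, 5:15] = True
        np.testing.assert_array_equal(mask, expected)

    def test_single_blob_detected(self):
        img = np.full((30, 30), 5.0)
        img[10:13, 20:24] = 800.0
        mask = threshold_mask(make_stack(img, img))
        assert mask.sum() == 12
        assert mask[10:13, 20:24].all()

    def test_constant_image_errors(self):
        with pytest.raises(DataError, match="constant"):
            threshold_mask(make_stack(np.ones((5, 5)), np.ones((5, 5))))


class TestFilterParticles:
    config = PipelineConfig()

    def test_border_component_truncated(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[0:4, 10:14] = True
        _, records = filter_particles(mask, self.config, pixel_size=0.08)
        assert records[0].status == EXCLUDED_TRUNCATED

    def test_single_pixel_excluded_by_size(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[15, 15] = True
        _, records = filter_particles(mask, self.config, pixel_size=0.08)
        assert records[0].status == EXCLUDED_SIZE  # 0.0064 µm² < 0.1 µm²

    def test_oversized_blob_excluded_by_size(self):
        mask = np.zeros((100, 100), dtype=bool)
        yy, xx = np.mgrid[0:100, 0:100]
        mask[(yy - 50) ** 2 + (xx - 50) ** 2 <= 40**2] = True  # ~32 µm² at 0.08
        _, records = filter_particles(mask, self.config, pixel_size=0.08)
        assert records[0].status == EXCLUDED_SIZE

    def test_interior_rod_retained(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[20:25, 10:40] = True
        _, records = filter_particles(mask, self.config, pixel_size=0.08)
        assert records[0].status == RETAINED

    def test_crossing_rods_ramified(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[28:33, 10:50] = True
        mask[10:50, 28:33] = True
        _, records = filter_particles(mask, self.config, pixel_size=0.08)
        assert records[0].status == EXCLUDED_RAMIFIED

    def test_partition_invariant(self):
        rng = np.random.default_rng(3)
        mask = ndimage.binary_dilation(rng.uniform(size=(80, 80)) > 0.97)
        labels, records = filter_particles(mask, self.config, pixel_size=0.08)
        assert len(records) == labels.max()
        assert all(r.status in {RETAINED, EXCLUDED_RAMIFIED, EXCLUDED_SIZE,
                                EXCLUDED_TRUNCATED} for r in records)

    def test_empty_mask_returns_empty_list(self):
        labels, records = filter_particles(
            np.zeros((10, 10), dtype=bool), self.config, pixel_size=0.08
        )
        assert records == []


class TestMeasureParticles:
    config = PipelineConfig()

    def measure_rod(self, mask, pixel_size=0.08, ratio_value=150.0):
        labels, records = filter_particles(mask, self.config, pixel_size)
        measure_particles(records, labels, uniform_ratio_image(mask.shape, ratio_value),
                          pixel_size)
        return records

    def test_rod_length_recovered(self):
        # sharp rectangle corners make the medial axis overshoot slightly;
        # capsule-shaped objects (the real morphology) recover within a pixel
        mask = np.zeros((50, 60), dtype=bool)
        mask[20:25, 10:40] = True  # 30 x 5 pixels
        (record,) = self.measure_rod(mask)
        assert record.length == pytest.approx(30 * 0.08, abs=2 * 0.08)

    def test_uniform_ratio_recovered(self):
        mask = np.zeros((50, 60), dtype=bool)
        mask[20:25, 10:40] = True
        (record,) = self.measure_rod(mask, ratio_value=212.5)
        assert record.mean_ratio == pytest.approx(212.5)

    def test_area_from_pixel_count(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:20, 10:20] = True  # 100 pixels
        (record,) = self.measure_rod(mask)
        assert record.area == pytest.approx(100 * 0.08**2)  # 0.64 µm²

    def test_fully_invalid_component_raises(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:14, 10:30] = True
        labels, records = filter_particles(mask, self.config, 0.08)
        ratio = RatioImage(values=np.full((40, 40), np.nan),
                           invalid_mask=np.ones((40, 40), dtype=bool))
        with pytest.raises(MeasurementError):
            measure_particles(records, labels, ratio, 0.08)


class TestSkeletonLength:
    def test_straight_rod(self):
        mask = np.zeros((20, 50), dtype=bool)
        mask[8:13, 5:45] = True  # 40 px long
        length, branches = skeleton_length_and_branches(mask)
        assert length == pytest.approx(40.0, abs=1.5)
        assert branches == 0

    def test_cross_has_branches(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[28:33, 10:50] = True
        mask[10:50, 28:33] = True
        _, branches = skeleton_length_and_branches(mask)
        assert branches >= 1

    def test_single_pixel(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        length, branches = skeleton_length_and_branches(mask)
        assert length == pytest.approx(2.0, abs=1.0)  # twice the EDT radius
        assert branches == 0


@pytest.fixture(scope="module")
def scene():
    params = SceneParams(cell_area=500.0, n_mitochondria=25, pixel_size_xy=0.1,
                         length_mean=2.4, length_sd=0.7, noise_level=200, seed=17)
    green, red, truth = generate_jc1_stack(params)
    stack = make_stack(green, red, 0.1, 0.25)
    psf = PSFEstimate.from_sigma(0.4 / FWHM_FACTOR, 1.4 / FWHM_FACTOR, 24)
    result = run_particle_pipeline(stack, psf, PipelineConfig(deconvolution_iterations=6))
    return params, truth, result


class TestEndToEndRecovery:
    def test_count_recovered(self, scene):
        params, truth, result = scene
        assert len(result.retained) == len(truth.particles) == 25

    def test_mean_length_recovered(self, scene):
        params, truth, result = scene
        measured = np.mean([r.length for r in result.retained])
        true_mean = np.mean([p.length for p in truth.particles])
        assert measured == pytest.approx(true_mean, rel=0.10)

    def test_mean_ratio_recovered(self, scene):
        params, truth, result = scene
        measured = np.mean([r.mean_ratio for r in result.retained])
        true_mean = np.mean([p.ratio for p in truth.particles])
        assert measured == pytest.approx(true_mean, rel=0.05)

    def test_partition_of_components(self, scene):
        _, _, result = scene
        assert len(result.records) == result.labels.max()

    def test_noise_free_per_particle_ratio_within_5_percent(self):
        params = SceneParams(cell_area=400.0, n_mitochondria=12, pixel_size_xy=0.1,
                             noise_level=0, ratio_sd=60.0, seed=23)
        green, red, truth = generate_jc1_stack(params)
        stack = make_stack(green, red, 0.1, 0.25)
        psf = PSFEstimate.from_sigma(0.4 / FWHM_FACTOR, 1.4 / FWHM_FACTOR, 24)
        result = run_particle_pipeline(stack, psf, PipelineConfig(deconvolution_iterations=6))
        assert len(result.retained) == 12
        matched = 0
        for record in result.retained:
            truth_match = min(
                truth.particles,
                key=lambda p: np.hypot(p.centroid[0] - record.centroid[0],
                                       p.centroid[1] - record.centroid[1]),
            )
            assert record.mean_ratio == pytest.approx(truth_match.ratio, rel=0.05)
            matched += 1
        assert matched == 12

    def test_decoys_rejected_with_correct_reasons(self):
        params = SceneParams(cell_area=900.0, n_mitochondria=10, pixel_size_xy=0.08,
                             noise_level=200, seed=5, decoys=True)
        green, red, truth = generate_jc1_stack(params)
        stack = make_stack(green, red, 0.08, 0.25)
        psf = PSFEstimate.from_sigma(0.4 / FWHM_FACTOR, 1.4 / FWHM_FACTOR, 24)
        result = run_particle_pipeline(stack, psf, PipelineConfig(deconvolution_iterations=8))
        statuses = [r.status for r in result.records]
        assert statuses.count(RETAINED) == 10
        assert statuses.count(EXCLUDED_TRUNCATED) == 1
        assert statuses.count(EXCLUDED_RAMIFIED) == 1
        assert statuses.count(EXCLUDED_SIZE) == 2  # lone pixel + oversized blob
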