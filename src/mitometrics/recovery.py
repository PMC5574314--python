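"""Parameter-recovery cohorts: simulate → analyze → summarize, end to end.

These helpers drive the full pipeline over cohorts of synthetic cells (or
redox series) and report recovered cohort statistics against the generator
parameters.  They are the work-horses of the acceptance benchmarks and are
deliberately free of any hard-coded expected values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .particles import PipelineConfig, run_particle_pipeline
from .psf import FWHM_FACTOR, PSFEstimate
from .ratiometrics import ChannelStack
from .redox import quantify_trace, compute_ratio_trace
from .synthetic import RoGFPSeriesParams, SceneParams, generate_jc1_stack, generate_rogfp1_series


def nominal_psf(fwhm_xy: float = 0.4, fwhm_z: float = 1.4) -> PSFEstimate:
    """Analytic PSF for a known acquisition configuration."""
    return PSFEstimate.from_sigma(fwhm_xy / FWHM_FACTOR, fwhm_z / FWHM_FACTOR, 24)


@dataclass
class CohortResult:
    """Recovered per-cell statistics for one simulated cohort."""

    true_counts: list[int]
    retained_counts: list[int]
    cell_areas: list[float]
    lengths: list[float]  # pooled retained particle lengths, µm
    ratios: list[float]  # pooled retained particle mean ratios

    @property
    def mean_retained_count(self) -> float:
        return float(np.mean(self.retained_counts))

    @property
    def mean_true_count(self) -> float:
        return float(np.mean(self.true_counts))

    @property
    def mean_length(self) -> float:
        return float(np.mean(self.lengths))

    @property
    def mean_density_count(self) -> float:
        return float(np.mean(np.asarray(self.retained_counts) / np.asarray(self.cell_areas)))


def simulate_cell_cohort(
    n_cells: int,
    count_mean: float,
    count_sd: float,
    cell_area: float,
    length_mean: float,
    length_sd: float,
    seed: int,
    pixel_size_xy: float = 0.12,
    n_planes: int = 7,
    noise_level: float = 200.0,
    deconvolution_iterations: int = 5,
    min_gap: float = 0.6,
    psf: PSFEstimate | None = None,
) -> CohortResult:
    """Simulate ``n_cells`` scenes and run the full particle pipeline on each.

    Per-cell mitochondrion counts are drawn from N(count_mean, count_sd)
    truncated at 1 (``count_sd = 0`` fixes the count).  Rods are interior and
    non-overlapping, so retained counts are directly comparable to truth.
    """
    psf = psf or nominal_psf()
    config = PipelineConfig(deconvolution_iterations=deconvolution_iterations)
    rng = np.random.default_rng(seed)
    result = CohortResult([], [], [], [], [])
    for i in range(n_cells):
        if count_sd > 0:
            count = max(int(round(rng.normal(count_mean, count_sd))), 1)
        else:
            count = int(round(count_mean))
        params = SceneParams(
            cell_area=cell_area,
            n_mitochondria=count,
            length_mean=length_mean,
            length_sd=length_sd,
            pixel_size_xy=pixel_size_xy,
            n_planes=n_planes,
            noise_level=noise_level,
            min_gap=min_gap,
            seed=int(rng.integers(2**31)),
        )
        green, red, truth = generate_jc1_stack(params)
        stack = ChannelStack(green, red, pixel_size_xy, params.z_step)
        out = run_particle_pipeline(stack, psf, config)
        result.true_counts.append(len(truth.particles))
        result.retained_counts.append(len(out.retained))
        result.cell_areas.append(truth.true_cell_area)
        result.lengths.extend(r.length for r in out.retained)
        result.ratios.extend(r.mean_ratio for r in out.retained)
    return result


def solve_two_point_calibration(
    r_a: float, oxd_a: float, r_b: float, oxd_b: float
) -> tuple[float, float]:
    """Endpoint ratios (r_red, r_ox) consistent with two (ratio, OxD) pairs.

    Assumes a unit instrument factor, for which the ratio is linear in OxD:
    R = OxD * r_ox + (1 - OxD) * r_red.
    """
    a = np.array([[1.0 - oxd_a, oxd_a], [1.0 - oxd_b, oxd_b]])
    r_red, r_ox = np.linalg.solve(a, np.array([r_a, r_b]))
    return float(r_red), float(r_ox)


@dataclass
class RedoxCohortResult:
    baseline_ratios: list[float]
    oxds: list[float]

    @property
    def mean_baseline_ratio(self) -> float:
        return float(np.mean(self.baseline_ratios))

    @property
    def mean_oxd(self) -> float:
        return float(np.mean(self.oxds))


def simulate_redox_cohort(
    n_series: int,
    true_oxd: float,
    r_red: float,
    r_ox: float,
    instrument_factor: float = 1.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> RedoxCohortResult:
    """Simulate redox series and recover baseline ratio + OxD per cell."""
    rng = np.random.default_rng(seed)
    result = RedoxCohortResult([], [])
    for _ in range(n_series):
        params = RoGFPSeriesParams(
            true_oxd=true_oxd,
            r_red=r_red,
            r_ox=r_ox,
            instrument_factor=instrument_factor,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        f395, f470, labels = generate_rogfp1_series(params)
        mask = np.ones(params.frame_shape, dtype=bool)
        trace = compute_ratio_trace(f395, f470, mask, labels, params.frame_rate_hz)
        _, state, r_base = quantify_trace(trace)
        result.baseline_ratios.append(r_base)
        result.oxds.append(state.oxd)
    return result
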