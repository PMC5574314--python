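"""End-to-end orchestration: simulate → psf → segment → morphometry → redox → compare.

A single YAML config drives every stage; each run directory receives the
stage tables plus a machine-readable provenance record (config hash, seed,
library versions).  Runs are deterministic for a fixed config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, MitometricsError
from .io import cell_table, particle_table, write_psf_json
from .morphometry import compute_cell_metrics
from .particles import RETAINED, PipelineConfig, run_particle_pipeline
from .psf import estimate_psf
from .ratiometrics import ChannelStack
from .redox import compute_ratio_trace, quantify_trace
from .stats import compare_groups, size_ratio_correlation
from .synthetic import (
    RoGFPSeriesParams,
    SceneParams,
    generate_bead_stack,
    generate_jc1_stack,
    generate_rogfp1_series,
)

log = logging.getLogger(__name__)

_REQUIRED = {"psf": dict, "groups": dict, "redox": dict}


def validate_config(config: dict) -> dict:
    """Schema check; raises :class:`ConfigError` naming the offending field."""
    if not isinstance(config, dict):
        raise ConfigError("run config must be a mapping")
    for key, kind in _REQUIRED.items():
        if key not in config:
            raise ConfigError(f"run config is missing required section {key!r}")
        if not isinstance(config[key], kind):
            raise ConfigError(f"section {key!r} must be a mapping")
    if not config["groups"]:
        raise ConfigError("section 'groups' must define at least one group")
    for group, section in config["groups"].items():
        if not isinstance(section, dict) or "n_cells" not in section:
            raise ConfigError(f"groups.{group} is missing required field 'n_cells'")
    return config


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: dict, out: str | Path, seed: int = 0) -> Path:
    """Execute all stages into ``out``; returns the run directory.

    Partial failures leave completed stage outputs in place and write an
    ``error_manifest.json`` before re-raising.
    """
    validate_config(config)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    try:
        psf = _stage_psf(config["psf"], out, seed)
        completed.append("psf")
        particles_df, cells_df = _stage_cohort(config, psf, out, seed)
        completed.append("segment+morphometry")
        redox_df = _stage_redox(config["redox"], config["groups"], out, seed)
        completed.append("redox")
        _stage_compare(particles_df, cells_df, redox_df, out)
        completed.append("compare")
    except MitometricsError as exc:
        (out / "error_manifest.json").write_text(
            json.dumps({"completed": completed, "error": str(exc)}, indent=2)
        )
        raise
    provenance = {
        "config_sha256": _config_hash(config),
        "seed": seed,
        "completed": completed,
        "versions": _versions(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out


def _versions() -> dict:
    import scipy
    import skimage

    return {
        "mitometrics": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
    }


def _stage_psf(section: dict, out: Path, seed: int):
    stack, positions = generate_bead_stack(
        fwhm_xy=section.get("fwhm_xy", 0.4),
        fwhm_z=section.get("fwhm_z", 1.4),
        n_beads=section.get("n_beads", 9),
        noise_level=section.get("noise_level", 0.0),
        pixel_size_xy=section.get("pixel_size_xy", 0.08),
        z_step=section.get("z_step", 0.25),
        seed=seed,
    )
    psf = estimate_psf(
        stack, positions,
        pixel_size_xy=section.get("pixel_size_xy", 0.08),
        z_step=section.get("z_step", 0.25),
    )
    write_psf_json(out / "psf.json", psf)
    return psf


def _stage_cohort(config: dict, psf, out: Path, seed: int):
    pipe_cfg = PipelineConfig(**config.get("pipeline", {}))
    scene_defaults = config.get("scene", {})
    particle_rows: list[pd.DataFrame] = []
    cell_rows = []
    cell_labels = []
    for g_index, (group, section) in enumerate(config["groups"].items()):
        overrides = {k: v for k, v in section.items() if k != "n_cells"}
        for i in range(section["n_cells"]):
            params = SceneParams(**{**scene_defaults, **overrides})
            params = replace(params, seed=seed * 100003 + g_index * 1009 + i)
            green, red, truth = generate_jc1_stack(params)
            stack = ChannelStack(green, red, params.pixel_size_xy, params.z_step)
            result = run_particle_pipeline(stack, psf, pipe_cfg)
            table = particle_table(result.records)
            table.insert(0, "cell", f"{group}-{i}")
            table.insert(0, "group", group)
            particle_rows.append(table)
            metrics = compute_cell_metrics(
                truth.cell_mask, result.mask, result.records, params.pixel_size_xy
            )
            cell_rows.append(metrics)
            cell_labels.append(f"{group}-{i}")
    particles_df = pd.concat(particle_rows, ignore_index=True)
    cells_df = cell_table(cell_rows, cell_labels)
    cells_df.insert(0, "group", [label.rsplit("-", 1)[0] for label in cell_labels])
    particles_df.to_csv(out / "particles.csv", index=False)
    cells_df.to_csv(out / "cells.csv", index=False)
    return particles_df, cells_df


def _stage_redox(section: dict, groups: dict, out: Path, seed: int) -> pd.DataFrame:
    rows = []
    for g_index, group in enumerate(groups):
        oxd = section.get("true_oxd", {}).get(group, 0.4) if isinstance(
            section.get("true_oxd"), dict
        ) else section.get("true_oxd", 0.4)
        for i in range(section.get("n_cells", 5)):
            params = RoGFPSeriesParams(
                true_oxd=oxd,
                r_red=section.get("r_red", 0.6),
                r_ox=section.get("r_ox", 1.4),
                instrument_factor=section.get("instrument_factor", 1.0),
                noise_sd=section.get("noise_sd", 0.01),
                seed=seed * 7919 + g_index * 1013 + i,
            )
            f395, f470, labels = generate_rogfp1_series(params)
            mask = np.ones(params.frame_shape, dtype=bool)
            trace = compute_ratio_trace(f395, f470, mask, labels, params.frame_rate_hz)
            cal, state, r_base = quantify_trace(trace)
            rows.append(
                {
                    "group": group,
                    "cell": f"{group}-{i}",
                    "r_baseline": r_base,
                    "r_red": cal.r_red,
                    "r_ox": cal.r_ox,
                    "instrument_factor": cal.instrument_factor,
                    "oxd_percent": state.oxd * 100.0,
                    "e_mv": state.e_mv,
                }
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "redox.csv", index=False)
    return frame


def _stage_compare(
    particles: pd.DataFrame, cells: pd.DataFrame, redox: pd.DataFrame, out: Path
) -> pd.DataFrame:
    groups = list(cells["group"].unique())
    rows = []
    if len(groups) >= 2:
        a, b = groups[0], groups[1]

        def compare(frame, column, min_n=2):
            xa = frame.loc[frame["group"] == a, column].dropna().to_numpy()
            xb = frame.loc[frame["group"] == b, column].dropna().to_numpy()
            if xa.size < min_n or xb.size < min_n:
                return
            res = compare_groups(xa, xb)
            rows.append(
                {
                    "quantity": column,
                    "group_a": a, "group_b": b,
                    "mean_a": xa.mean(), "mean_b": xb.mean(),
                    "t": res.t, "p": res.p, "stars": res.stars,
                }
            )

        for column in ("cell_area", "total_mito_area", "particle_count", "density_count"):
            compare(cells, column)
        retained = particles[particles["status"] == RETAINED]
        for column in ("length_um", "mean_ratio"):
            compare(retained, column)
        compare(redox, "oxd_percent")
        lengths = retained["length_um"].dropna().to_numpy()
        ratios = retained["mean_ratio"].dropna().to_numpy()
        if lengths.size >= 3 and np.ptp(lengths) > 0 and np.ptp(ratios) > 0:
            rows.append(
                {
                    "quantity": "length_ratio_correlation",
                    "group_a": "all", "group_b": "all",
                    "mean_a": size_ratio_correlation(lengths, ratios),
                    "mean_b": np.nan, "t": np.nan, "p": np.nan, "stars": "",
                }
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "comparisons.csv", index=False)
    return frame
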