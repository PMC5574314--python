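"""File I/O: TIFF stacks, particle/cell tables, PSF reports, truth sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import DataError
from .morphometry import CellMetrics
from .particles import ParticleRecord
from .psf import PSFEstimate
from .ratiometrics import ChannelStack, RatioImage
from .synthetic import GroundTruth


def write_channel_stack(path: str | Path, stack: ChannelStack) -> None:
    """Write a dual-channel stack as one multi-series TIFF (axis order czyx/cyx)."""
    data = np.stack([stack.green, stack.red]).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack", planarconfig="separate",
                     metadata={
        "pixel_size_xy": stack.pixel_size_xy, "z_step": stack.z_step,
        "channels": ["green", "red"],
    })


def read_channel_stack(
    path: str | Path, pixel_size_xy: float | None = None, z_step: float | None = None
) -> ChannelStack:
    """Read a dual-channel TIFF written by :func:`write_channel_stack`.

    Physical calibration is taken from the TIFF metadata unless overridden.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.shape[0] != 2:
        raise DataError(f"expected 2 channels in {path}, found shape {data.shape}")
    return ChannelStack(
        green=data[0],
        red=data[1],
        pixel_size_xy=pixel_size_xy or float(meta.get("pixel_size_xy", 0.08)),
        z_step=z_step or float(meta.get("z_step", 0.25)),
    )


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_ratio_image(path: str | Path, ratio: RatioImage) -> None:
    """Ratio values (32-bit float) and validity mask as a two-page TIFF."""
    pages = np.stack([
        np.nan_to_num(ratio.values, nan=0.0).astype(np.float32),
        ratio.invalid_mask.astype(np.float32),
    ])
    tifffile.imwrite(path, pages, photometric="minisblack",
                     metadata={"scaling": ratio.scaling})


def particle_table(records: list[ParticleRecord]) -> pd.DataFrame:
    """One row per connected component, all statuses included."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "status": [r.status for r in records],
            "area_um2": [r.area for r in records],
            "length_um": [r.length for r in records],
            "mean_ratio": [r.mean_ratio for r in records],
            "centroid_y_um": [r.centroid[0] for r in records],
            "centroid_x_um": [r.centroid[1] for r in records],
        }
    )


def cell_table(metrics: list[CellMetrics], labels: list[str] | None = None) -> pd.DataFrame:
    frame = pd.DataFrame([m.to_dict() for m in metrics])
    if labels is not None:
        frame.insert(0, "cell", labels)
    return frame


def write_psf_json(path: str | Path, psf: PSFEstimate) -> None:
    Path(path).write_text(json.dumps(psf.to_dict(), indent=2))


def read_psf_json(path: str | Path) -> PSFEstimate:
    return PSFEstimate(**json.loads(Path(path).read_text()))


def write_truth_sidecar(directory: str | Path, truth: GroundTruth, scene_params: dict) -> None:
    """Truth sidecar: particle CSV plus scene-parameter JSON plus cell mask TIFF."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "centroid_y_um": p.centroid[0],
            "centroid_x_um": p.centroid[1],
            "orientation_rad": p.orientation,
            "length_um": p.length,
            "ratio": p.ratio,
            "area_um2": truth.particle_area(p),
        }
        for p in truth.particles
    ]
    pd.DataFrame(rows).to_csv(directory / "truth_particles.csv", index=False)
    sidecar = dict(scene_params)
    sidecar.update(
        true_cell_area=truth.true_cell_area,
        true_total_mito_area=truth.true_total_mito_area,
        mito_integrated_intensity=truth.mito_integrated_intensity,
        n_decoys=len(truth.decoys),
    )
    (directory / "truth_scene.json").write_text(json.dumps(sidecar, indent=2, default=float))
    tifffile.imwrite(directory / "cell_mask.tif", truth.cell_mask.astype(np.uint8))
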