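"""Per-cell morphometry: cell area, mitochondrial mass, density, stain intensity.

"Mass" here is the area of the collapsed-plane particle mask (µm²), which is
how mitochondrial content is reported; a voxel count is also carried where a
3-D mask is supplied.  Density is reported in both conventions — retained
particle count per µm² and dimensionless area fraction — since either
normalization can be meant by "content per cell size".
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .errors import DataError
from .particles import RETAINED, ParticleRecord


@dataclass
class CellMetrics:
    """All per-cell quantities for one analyzed cell."""

    cell_area: float  # µm²
    total_mito_area: float  # µm²
    particle_count: int  # retained particles
    density_count: float  # particles / µm²
    density_area: float  # dimensionless area fraction
    mitotracker_norm: float | None = None  # intensity / µm²

    def __post_init__(self) -> None:
        if self.total_mito_area > self.cell_area * (1 + 1e-9):
            raise DataError("mitochondrial area cannot exceed cell area")
        if min(self.cell_area, self.total_mito_area, self.particle_count) < 0:
            raise DataError("cell metrics must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def cell_area(cell_mask: np.ndarray, pixel_size: float) -> float:
    """Area of a single connected cell region in µm²."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise DataError("empty cell mask")
    _, n_components = ndimage.label(cell_mask, structure=np.ones((3, 3), dtype=int))
    if n_components != 1:
        raise DataError(f"cell mask must be one connected region, found {n_components}")
    return float(cell_mask.sum()) * pixel_size**2


def total_mito_mass(mito_mask: np.ndarray, pixel_size: float) -> float:
    """Total above-threshold area inside the cell, in µm².

    Includes components excluded from single-particle statistics (aggregates
    still contribute to mass).
    """
    return float(np.asarray(mito_mask, dtype=bool).sum()) * pixel_size**2


def density(mass_or_count: float, cell_area_um2: float) -> float:
    """Quotient normalization of any per-cell quantity by cell area."""
    if cell_area_um2 <= 0:
        raise DataError("cell area must be positive for normalization")
    return mass_or_count / cell_area_um2


def mitotracker_normalized_intensity(
    image: np.ndarray, cell_mask: np.ndarray, pixel_size: float
) -> float:
    """Background-subtracted integrated stain intensity per µm² of cell.

    Background is the median intensity outside the cell mask(s); the mask may
    not cover the whole image.
    """
    image = np.asarray(image, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if image.shape != cell_mask.shape:
        raise DataError("image and cell mask must share geometry")
    if not cell_mask.any():
        raise DataError("empty cell mask")
    outside = ~cell_mask
    if not outside.any():
        raise DataError("cell mask covers the whole image; no background estimate")
    background = float(np.median(image[outside]))
    integrated = float((image[cell_mask] - background).sum())
    return integrated / (float(cell_mask.sum()) * pixel_size**2)


def compute_cell_metrics(
    cell_mask: np.ndarray,
    mito_mask: np.ndarray,
    records: list[ParticleRecord],
    pixel_size: float,
    mitotracker_image: np.ndarray | None = None,
) -> CellMetrics:
    """Assemble the full per-cell metrics row.

    ``mito_mask`` is restricted to the cell region before mass computation.
    ``density_count * cell_area == particle_count`` holds exactly.
    """
    area = cell_area(cell_mask, pixel_size)
    mask_in_cell = np.asarray(mito_mask, dtype=bool) & np.asarray(cell_mask, dtype=bool)
    mass = total_mito_mass(mask_in_cell, pixel_size)
    count = sum(1 for r in records if r.status == RETAINED)
    tracker = (
        mitotracker_normalized_intensity(mitotracker_image, cell_mask, pixel_size)
        if mitotracker_image is not None
        else None
    )
    return CellMetrics(
        cell_area=area,
        total_mito_area=mass,
        particle_count=count,
        density_count=density(count, area),
        density_area=density(mass, area),
        mitotracker_norm=tracker,
    )
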