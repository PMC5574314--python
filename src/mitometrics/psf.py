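"""Point-spread-function characterization from sub-resolution bead stacks.

Beads far below the diffraction limit image as the system PSF; fitting a
Gaussian-plus-offset model to averaged axis profiles yields the operational
lateral and axial resolution as FWHM values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError, FitError

log = logging.getLogger(__name__)

#: FWHM of a Gaussian of unit standard deviation: 2*sqrt(2*ln 2).
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class PSFEstimate:
    """Measured resolution of one acquisition configuration."""

    fwhm_xy: float
    fwhm_z: float
    sigma_xy: float
    sigma_z: float
    n_beads_used: int

    def __post_init__(self) -> None:
        if self.fwhm_xy <= 0 or self.fwhm_z <= 0:
            raise DataError("FWHM values must be positive")
        if self.n_beads_used < 1:
            raise DataError("at least one bead is required")

    @classmethod
    def from_sigma(cls, sigma_xy: float, sigma_z: float, n_beads_used: int = 1) -> "PSFEstimate":
        return cls(
            fwhm_xy=FWHM_FACTOR * sigma_xy,
            fwhm_z=FWHM_FACTOR * sigma_z,
            sigma_xy=sigma_xy,
            sigma_z=sigma_z,
            n_beads_used=n_beads_used,
        )

    def sigma_pixels(self, pixel_size_xy: float, z_step: float) -> tuple[float, float, float]:
        """(sigma_z, sigma_y, sigma_x) in pixel units for a (z, y, x) stack."""
        return (self.sigma_z / z_step, self.sigma_xy / pixel_size_xy, self.sigma_xy / pixel_size_xy)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BeadProfiles:
    """Background-subtracted 1-D intensity profiles through one bead."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray


def _recenter(profile: np.ndarray) -> np.ndarray:
    """Shift a profile so the center of mass of its top 20% sits at the middle.

    Integer shift only; sub-pixel position is absorbed by the Gaussian fit.
    Rolling wraps the far tail, which is flat after background subtraction.
    """
    top = profile >= profile.max() * 0.8
    idx = np.arange(profile.size)
    weights = np.where(top, profile, 0.0)
    if weights.sum() <= 0:
        return profile
    com = float((idx * weights).sum() / weights.sum())
    shift = int(round(profile.size // 2 - com))
    return np.roll(profile, shift)


def _subtract_background(profile: np.ndarray, n_edge: int = 2) -> np.ndarray:
    """Remove the baseline estimated from the outermost samples."""
    edges = np.concatenate([profile[:n_edge], profile[-n_edge:]])
    return profile - float(np.mean(edges))


def extract_bead_profiles(
    stack: np.ndarray,
    positions: np.ndarray,
    pixel_size_xy: float,
    z_step: float,
    window_xy: float = 1.2,
    window_z: float = 3.0,
) -> list[BeadProfiles]:
    """Extract X/Y/Z intensity profiles through each bead's maximum.

    Parameters
    ----------
    stack:
        3-D (z, y, x) intensity array.
    positions:
        (n, 3) physical bead coordinates in µm, ordered (z, y, x).
    window_xy, window_z:
        Profile half-width in µm per axis.  Beads closer than one window to
        any border are skipped with a logged warning.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.size == 0:
        raise DataError("bead stack must be a non-empty 3-D array")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] == 0:
        raise DataError("no bead positions supplied")

    wz = max(int(round(window_z / z_step)), 2)
    wxy = max(int(round(window_xy / pixel_size_xy)), 2)
    nz, ny, nx = stack.shape
    out: list[BeadProfiles] = []
    for pos in positions:
        zc = int(round(pos[0] / z_step))
        yc = int(round(pos[1] / pixel_size_xy))
        xc = int(round(pos[2] / pixel_size_xy))
        # refine onto the local intensity maximum (sub-pixel truth positions)
        z0, z1 = max(zc - 2, 0), min(zc + 3, nz)
        y0, y1 = max(yc - 2, 0), min(yc + 3, ny)
        x0, x1 = max(xc - 2, 0), min(xc + 3, nx)
        local = stack[z0:z1, y0:y1, x0:x1]
        dz, dy, dx = np.unravel_index(int(np.argmax(local)), local.shape)
        zc, yc, xc = z0 + dz, y0 + dy, x0 + dx
        if not (wz <= zc < nz - wz and wxy <= yc < ny - wxy and wxy <= xc < nx - wxy):
            log.warning("bead at %s too close to border; skipped", np.round(pos, 3))
            continue
        px = _subtract_background(stack[zc, yc, xc - wxy : xc + wxy + 1])
        py = _subtract_background(stack[zc, yc - wxy : yc + wxy + 1, xc])
        pz = _subtract_background(stack[zc - wz : zc + wz + 1, yc, xc])
        out.append(BeadProfiles(x=_recenter(px), y=_recenter(py), z=_recenter(pz)))
    if not out:
        raise DataError("no usable beads (all skipped at borders)")
    return out


def average_profiles(profiles: list[np.ndarray]) -> np.ndarray:
    """Pointwise mean of peak-aligned, equal-length profiles."""
    if len(profiles) == 0:
        raise DataError("cannot average an empty profile list")
    lengths = {np.asarray(p).size for p in profiles}
    if len(lengths) != 1:
        raise DataError(f"profile length mismatch: {sorted(lengths)}")
    return np.mean(np.stack([np.asarray(p, dtype=float) for p in profiles]), axis=0)


def _gaussian_offset(x: np.ndarray, amp: float, x0: float, sigma: float, offset: float) -> np.ndarray:
    return amp * np.exp(-((x - x0) ** 2) / (2.0 * sigma**2)) + offset


def fit_fwhm(profile: np.ndarray, pixel_size: float) -> tuple[float, float]:
    """Least-squares Gaussian-plus-offset fit of a 1-D profile.

    Returns ``(sigma, fwhm)`` in physical units (``pixel_size`` per sample).
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < 5:
        raise DataError("profile must be 1-D with at least 5 samples")
    if np.ptp(profile) == 0:
        raise FitError("flat profile: no peak to fit")
    x = np.arange(profile.size) * pixel_size
    p0 = (
        float(np.ptp(profile)),
        float(x[np.argmax(profile)]),
        max(profile.size * pixel_size / 8.0, pixel_size / 2.0),
        float(np.min(profile)),
    )
    try:
        popt, _ = curve_fit(_gaussian_offset, x, profile, p0=p0, maxfev=5000)
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    sigma = abs(float(popt[2]))
    if sigma <= 0 or not np.isfinite(sigma):
        raise FitError("degenerate fitted width")
    return sigma, FWHM_FACTOR * sigma


def estimate_psf(
    stack: np.ndarray,
    positions: np.ndarray,
    pixel_size_xy: float,
    z_step: float,
    window_xy: float = 1.2,
    window_z: float = 3.0,
) -> PSFEstimate:
    """End-to-end PSF estimate: extract, average, and fit profiles.

    Lateral X and Y profiles are pooled into a single lateral estimate, in
    keeping with a single reported lateral resolution.
    """
    profiles = extract_bead_profiles(
        stack, positions, pixel_size_xy, z_step, window_xy=window_xy, window_z=window_z
    )
    lateral = average_profiles([p.x for p in profiles] + [p.y for p in profiles])
    axial = average_profiles([p.z for p in profiles])
    sigma_xy, fwhm_xy = fit_fwhm(lateral, pixel_size_xy)
    sigma_z, fwhm_z = fit_fwhm(axial, z_step)
    return PSFEstimate(
        fwhm_xy=fwhm_xy,
        fwhm_z=fwhm_z,
        sigma_xy=sigma_xy,
        sigma_z=sigma_z,
        n_beads_used=len(profiles),
    )
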