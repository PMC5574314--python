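"""Ground-truthed synthetic microscopy generator.

Produces the four input families the analysis consumes — dual-emission
3-D stacks with rod-shaped, individually polarized mitochondria; single
channel mitochondrial-stain images; sub-resolution bead stacks; and
excitation-pair redox time series with calibration epochs — together with
truth sidecars so every downstream stage has a parameter-recovery surface.

Geometry conventions: stacks are (z, y, x); lateral sampling defaults to
0.08 µm/pixel and axial spacing to 0.25 µm.  Mitochondria are capsules
(segments with hemispherical caps) of fixed radius lying in a thin slab
around the central plane.  The optical model is a separable 3-D Gaussian
blur; noise is Poisson shot noise on a configurable photon scale plus a
small Gaussian read component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .errors import ConfigError, DataError, InfeasibleSceneError, PlacementError
from .psf import FWHM_FACTOR
from .ratiometrics import DEFAULT_RATIO_SCALING

# fixed mitochondrial half-width; typical organelle width ~0.4 µm
ROD_RADIUS_UM = 0.2


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class SceneParams:
    """Parameters of one synthetic cell scene.

    ``image_shape`` may be None, in which case a field just large enough for
    the requested cell area (plus a margin) is chosen automatically.
    """

    image_shape: tuple[int, int, int] | None = None
    n_planes: int = 9
    pixel_size_xy: float = 0.08
    z_step: float = 0.25
    cell_area: float = 1200.0
    n_mitochondria: int = 60
    length_mean: float = 2.4
    length_sd: float = 0.7
    ratio_mean: float = 200.0
    ratio_sd: float = 40.0
    psf_fwhm_xy: float = 0.4
    psf_fwhm_z: float = 1.4
    noise_level: float = 200.0
    background: float = 0.005
    min_gap: float = 0.6
    rod_radius: float = ROD_RADIUS_UM
    decoys: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        positives = {
            "pixel_size_xy": self.pixel_size_xy,
            "z_step": self.z_step,
            "cell_area": self.cell_area,
            "length_mean": self.length_mean,
            "length_sd": self.length_sd,
            "ratio_mean": self.ratio_mean,
            "psf_fwhm_xy": self.psf_fwhm_xy,
            "psf_fwhm_z": self.psf_fwhm_z,
            "rod_radius": self.rod_radius,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {value}")
        if self.n_mitochondria < 0:
            raise ConfigError("n_mitochondria must be >= 0")
        if self.n_planes < 1:
            raise ConfigError("n_planes must be >= 1")
        if self.noise_level < 0 or self.ratio_sd < 0 or self.background < 0:
            raise ConfigError("noise_level, ratio_sd and background must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthParticle:
    """One ground-truth mitochondrion."""

    centroid: tuple[float, float]  # (y, x) in µm
    orientation: float  # radians, in-plane
    length: float  # tip-to-tip, µm
    ratio: float  # dimensionless, scaled-ratio units
    pixels: np.ndarray  # (n, 2) int, in-plane footprint (row, col)

    @property
    def area(self) -> float | None:
        return None  # filled via GroundTruth.pixel_size_xy; see particle_area


@dataclass
class DecoyParticle:
    """Deliberately pathological object injected for filter testing."""

    kind: str  # border | fused | pixel | oversized
    expected_status: str  # the exclusion reason a correct filter assigns
    pixels: np.ndarray


@dataclass
class GroundTruth:
    """Truth sidecar for one synthetic scene."""

    cell_mask: np.ndarray
    particles: list[TruthParticle]
    decoys: list[DecoyParticle]
    pixel_size_xy: float
    true_cell_area: float
    true_total_mito_area: float
    mito_integrated_intensity: float = 0.0

    def particle_area(self, particle: TruthParticle) -> float:
        return particle.pixels.shape[0] * self.pixel_size_xy**2


@dataclass
class RoGFPSeriesParams:
    """Parameters of one synthetic excitation-pair redox series."""

    true_oxd: float = 0.4
    r_red: float = 0.6
    r_ox: float = 1.4
    instrument_factor: float = 1.0
    epoch_lengths: tuple[int, int, int] = (20, 16, 16)
    noise_sd: float = 0.0
    frame_shape: tuple[int, int] = (16, 16)
    brightness: float = 100.0
    frame_rate_hz: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_oxd <= 1.0:
            raise ConfigError("true_oxd must lie in [0, 1]")
        if self.r_red >= self.r_ox:
            raise ConfigError("r_red must be smaller than r_ox")
        if self.instrument_factor <= 0:
            raise ConfigError("instrument_factor must be positive")
        if any(n < 1 for n in self.epoch_lengths):
            raise ConfigError("every epoch needs at least one frame")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def ratio_from_oxd(oxd: float, r_red: float, r_ox: float, instrument_factor: float) -> float:
    """Ratio analytically implied by an oxidation degree and calibration.

    Inverse of the oxidation-degree formula: with ``w = oxd * instrument_factor``,
    ``R = (w * r_ox + (1 - oxd) * r_red) / (w + (1 - oxd))``.
    """
    w = oxd * instrument_factor
    return (w * r_ox + (1.0 - oxd) * r_red) / (w + (1.0 - oxd))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _cell_blob_mask(
    shape_yx: tuple[int, int], area_px: float, rng: np.random.Generator,
    n_modes: int = 6, irregularity: float = 0.12,
) -> np.ndarray:
    """Smoothed random star-shaped blob of (approximately) the requested area."""
    ny, nx = shape_yx
    amps = rng.uniform(-irregularity, irregularity, size=n_modes) / np.arange(1, n_modes + 1)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
    # mean of R(theta)^2 over theta = r0^2 * (1 + sum(a_k^2)/2)
    r0 = np.sqrt(area_px / np.pi / (1.0 + np.sum(amps**2) / 2.0))
    r_max = r0 * (1.0 + np.sum(np.abs(amps)))
    if 2.0 * r_max + 4.0 > min(ny, nx):
        raise DataError(
            f"image {shape_yx} too small for a cell of area {area_px:.0f} px "
            f"(needs ~{int(2 * r_max + 4)} px per side)"
        )
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    theta = np.arctan2(yy - cy, xx - cx)
    radius = np.hypot(yy - cy, xx - cx)
    boundary = r0 * (
        1.0
        + sum(a * np.cos((k + 1) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
    )
    return radius <= boundary


def _capsule_footprint(
    p0: np.ndarray, p1: np.ndarray, radius: float, shape: tuple[int, int]
) -> tuple[tuple[slice, slice], np.ndarray] | None:
    """Rasterize a 2-D capsule (distance-to-segment <= radius), clipped to shape.

    Returns (bounding slices, local boolean mask) or None if fully outside.
    """
    lo = np.floor(np.minimum(p0, p1) - radius - 1.0).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius + 2.0).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(shape))
    if np.any(hi <= lo):
        return None
    yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1]]
    d = p1 - p0
    seg2 = float(d @ d)
    py, px = yy - p0[0], xx - p0[1]
    if seg2 == 0.0:
        dist = np.hypot(py, px)
    else:
        t = np.clip((py * d[0] + px * d[1]) / seg2, 0.0, 1.0)
        dist = np.hypot(py - t * d[0], px - t * d[1])
    mask = dist <= radius
    if not mask.any():
        return None
    return (slice(lo[0], hi[0]), slice(lo[1], hi[1])), mask


@dataclass
class _Rod:
    p0: np.ndarray  # segment endpoints, pixel coords (y, x)
    p1: np.ndarray
    length_px: float  # tip-to-tip including caps
    orientation: float
    ratio: float
    amplitude: float


def _sample_truncated(
    rng: np.random.Generator, mean: float, sd: float, low: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (low - mean) / sd
    dist = truncnorm(a, np.inf, loc=mean, scale=sd)
    return dist.rvs(size=size, random_state=rng)


def _place_rods(
    allowed: np.ndarray,
    lengths_px: np.ndarray,
    ratios: np.ndarray,
    amplitudes: np.ndarray,
    radius_px: float,
    gap_px: float,
    rng: np.random.Generator,
    max_attempts: int = 600,
) -> tuple[list[_Rod], np.ndarray]:
    """Place non-overlapping capsules inside ``allowed`` by rejection sampling.

    Pairwise surface clearance >= ``gap_px`` is enforced by stamping each
    accepted capsule dilated by gap/2 into an occupancy grid and testing
    candidates at the same dilation.
    """
    occupancy = np.zeros(allowed.shape, dtype=bool)
    candidates = np.argwhere(allowed)
    if candidates.shape[0] == 0:
        raise PlacementError("no interior region available for rod placement")
    rods: list[_Rod] = []
    pad = radius_px + gap_px / 2.0
    for length, ratio, amp in zip(lengths_px, ratios, amplitudes):
        seg = max(length - 2.0 * radius_px, 0.0)
        placed = False
        for _ in range(max_attempts):
            center = candidates[rng.integers(candidates.shape[0])] + rng.uniform(-0.5, 0.5, 2)
            theta = rng.uniform(0.0, np.pi)
            half = 0.5 * seg * np.array([np.sin(theta), np.cos(theta)])
            p0, p1 = center - half, center + half
            hit = _capsule_footprint(p0, p1, pad, allowed.shape)
            if hit is None:
                continue
            slices, foot = hit
            if not allowed[slices][foot].all():
                continue
            if occupancy[slices][foot].any():
                continue
            occupancy[slices][foot] = True
            rods.append(
                _Rod(p0=p0, p1=p1, length_px=length, orientation=theta, ratio=ratio, amplitude=amp)
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place rod {len(rods) + 1}/{len(lengths_px)} "
                f"after {max_attempts} attempts; scene too crowded"
            )
    return rods, occupancy


def _render_rods_3d(
    shape: tuple[int, int, int],
    rods: list[_Rod],
    z_offsets_um: np.ndarray,
    radius_um: float,
    pixel_size_xy: float,
    z_step: float,
    scaling: float = DEFAULT_RATIO_SCALING,
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-blur channel volumes: red = amplitude, green = amplitude*ratio/scaling."""
    nz = shape[0]
    green = np.zeros(shape)
    red = np.zeros(shape)
    zc = nz // 2
    for rod, z0 in zip(rods, z_offsets_um):
        for k in range(nz):
            dz = (k - zc) * z_step - z0
            if abs(dz) >= radius_um:
                continue
            r_eff = np.sqrt(radius_um**2 - dz**2) / pixel_size_xy
            hit = _capsule_footprint(rod.p0, rod.p1, r_eff, shape[1:])
            if hit is None:
                continue
            slices, foot = hit
            red[k][slices][foot] += rod.amplitude
            green[k][slices][foot] += rod.amplitude * rod.ratio / scaling
    return green, red


def _apply_noise(
    image: np.ndarray, noise_level: float, rng: np.random.Generator, read_noise_sd: float = 0.5
) -> np.ndarray:
    """Poisson shot noise at ``noise_level`` photons per unit intensity.

    ``noise_level == 0`` returns the expectation unchanged (noise-free mode).
    """
    if noise_level <= 0:
        return image
    counts = rng.poisson(image * noise_level).astype(float)
    counts += rng.normal(0.0, read_noise_sd, size=image.shape)
    return np.clip(counts, 0.0, None)


def _scene_shape(params: SceneParams, margin_px: int = 12) -> tuple[int, int, int]:
    area_px = params.cell_area / params.pixel_size_xy**2
    r_max = np.sqrt(area_px / np.pi) * 1.25
    side = int(2 * np.ceil(r_max)) + 2 * margin_px
    return (params.n_planes, side, side)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_jc1_stack(params: SceneParams) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate a registered dual-emission stack with per-rod polarization.

    Returns ``(green, red, truth)``; both stacks share geometry exactly.  For
    every rod the pre-blur voxel intensities satisfy
    ``green * 200 / red == true_ratio``.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.image_shape or _scene_shape(params)
    if len(shape) != 3:
        raise ConfigError("image_shape must be (z, y, x)")
    px = params.pixel_size_xy
    area_px = params.cell_area / px**2
    cell_mask = _cell_blob_mask(shape[1:], area_px, rng)

    radius_px = params.rod_radius / px
    gap_px = params.min_gap / px
    n = params.n_mitochondria
    lengths_um = _sample_truncated(
        rng, params.length_mean, params.length_sd, low=max(0.5, 2 * params.rod_radius), size=n
    )
    ratios = _sample_truncated(rng, params.ratio_mean, params.ratio_sd, low=1.0, size=n)
    amplitudes = rng.uniform(0.7, 1.3, size=n)

    rod_area_um2 = lengths_um * 2 * params.rod_radius + np.pi * params.rod_radius**2
    if rod_area_um2.sum() > params.cell_area:
        raise InfeasibleSceneError(
            f"requested mitochondrial area {rod_area_um2.sum():.0f} µm² exceeds "
            f"cell area {params.cell_area:.0f} µm²"
        )

    allowed = ndimage.binary_erosion(cell_mask, iterations=2)
    rods, occupancy = _place_rods(
        allowed, lengths_um / px, ratios, amplitudes, radius_px, gap_px, rng
    )
    z_offsets = rng.uniform(-0.4 * params.rod_radius, 0.4 * params.rod_radius, size=len(rods))
    green, red = _render_rods_3d(shape, rods, z_offsets, params.rod_radius, px, params.z_step)

    decoys: list[DecoyParticle] = []
    if params.decoys:
        clear = allowed & ~ndimage.binary_dilation(occupancy, iterations=int(np.ceil(gap_px)))
        decoys = _inject_decoys(green, red, clear, radius_px, gap_px, rng, px)

    particles = []
    for rod in rods:
        hit = _capsule_footprint(rod.p0, rod.p1, radius_px, shape[1:])
        slices, foot = hit  # interior rods always rasterize
        pix = np.argwhere(foot) + [slices[0].start, slices[1].start]
        centroid = tuple(((rod.p0 + rod.p1) / 2.0) * px)
        particles.append(
            TruthParticle(
                centroid=(float(centroid[0]), float(centroid[1])),
                orientation=rod.orientation,
                length=rod.length_px * px,
                ratio=rod.ratio,
                pixels=pix,
            )
        )

    sigma = (params.psf_fwhm_z / FWHM_FACTOR / params.z_step,
             params.psf_fwhm_xy / FWHM_FACTOR / px,
             params.psf_fwhm_xy / FWHM_FACTOR / px)
    green = ndimage.gaussian_filter(green, sigma, mode="constant") + params.background
    red = ndimage.gaussian_filter(red, sigma, mode="constant") + params.background
    green = _apply_noise(green, params.noise_level, rng)
    red = _apply_noise(red, params.noise_level, rng)

    truth = GroundTruth(
        cell_mask=cell_mask,
        particles=particles,
        decoys=decoys,
        pixel_size_xy=px,
        true_cell_area=float(cell_mask.sum()) * px**2,
        true_total_mito_area=float(sum(p.pixels.shape[0] for p in particles)) * px**2,
    )
    return green, red, truth


def _inject_decoys(
    green: np.ndarray,
    red: np.ndarray,
    allowed: np.ndarray,
    radius_px: float,
    gap_px: float,
    rng: np.random.Generator,
    px: float,
) -> list[DecoyParticle]:
    """Stamp pathological objects: border rod, fused pair, lone pixel, huge blob."""
    nz, ny, nx = green.shape
    zc = nz // 2
    decoys: list[DecoyParticle] = []

    def stamp(slices, foot, amp, ratio=DEFAULT_RATIO_SCALING):
        red[zc][slices][foot] += amp
        green[zc][slices][foot] += amp * ratio / DEFAULT_RATIO_SCALING

    # rod crossing the image border (truncated); bright enough that the
    # blur's edge falloff cannot detach it from row 0
    p0 = np.array([-6.0, nx * 0.5])
    p1 = np.array([10.0, nx * 0.5 + 6.0])
    hit = _capsule_footprint(p0, p1, radius_px, (ny, nx))
    if hit is not None:
        slices, foot = hit
        stamp(slices, foot, 2.5)
        pix = np.argwhere(foot) + [slices[0].start, slices[1].start]
        decoys.append(DecoyParticle("border", "excluded_truncated", pix))

    # two rods crossing at an angle (fused / ramified)
    spot = _find_clear_spot(allowed, int(np.ceil(25 + gap_px)), rng)
    if spot is not None:
        cy, cx = spot
        arm = 12.0
        pieces = []
        for theta in (0.3, 1.8):
            d = arm * np.array([np.sin(theta), np.cos(theta)])
            hit = _capsule_footprint(np.array([cy, cx]) - d, np.array([cy, cx]) + d,
                                     radius_px, (ny, nx))
            if hit is not None:
                slices, foot = hit
                stamp(slices, foot, 1.0)
                pieces.append(np.argwhere(foot) + [slices[0].start, slices[1].start])
        if pieces:
            decoys.append(DecoyParticle("fused", "excluded_ramified", np.vstack(pieces)))

    # isolated bright pixel (below minimum size)
    spot = _find_clear_spot(allowed, int(np.ceil(8 + gap_px)), rng)
    if spot is not None:
        cy, cx = spot
        red[zc, cy, cx] += 10.0
        green[zc, cy, cx] += 10.0
        decoys.append(DecoyParticle("pixel", "excluded_size", np.array([[cy, cx]])))

    # oversized aggregate (above maximum size): disk of ~2.8 µm radius
    r_big = 2.8 / px
    spot = _find_clear_spot(allowed, int(np.ceil(r_big + gap_px + 2)), rng)
    if spot is not None:
        cy, cx = spot
        c = np.array([float(cy), float(cx)])
        hit = _capsule_footprint(c, c, r_big, (ny, nx))
        if hit is not None:
            slices, foot = hit
            stamp(slices, foot, 1.0)
            pix = np.argwhere(foot) + [slices[0].start, slices[1].start]
            decoys.append(DecoyParticle("oversized", "excluded_size", pix))
    return decoys


def _find_clear_spot(
    allowed: np.ndarray, clearance_px: int, rng: np.random.Generator, attempts: int = 200
) -> tuple[int, int] | None:
    """Random pixel whose ``clearance_px`` neighborhood is entirely allowed."""
    safe = ndimage.binary_erosion(allowed, iterations=clearance_px)
    coords = np.argwhere(safe)
    if coords.shape[0] == 0:
        return None
    cy, cx = coords[rng.integers(coords.shape[0])]
    return int(cy), int(cx)


def generate_mitotracker_image(params: SceneParams) -> tuple[np.ndarray, GroundTruth]:
    """Single-channel 2-D mitochondrial-stain image with integrated-intensity truth.

    The truth records the blurred, background-free signal integrated over the
    cell mask, which a correct background-subtracting measurement recovers
    exactly in the noise-free case.
    """
    rng = np.random.default_rng(params.seed)
    shape3 = params.image_shape or _scene_shape(params)
    shape = shape3[1:]
    px = params.pixel_size_xy
    area_px = params.cell_area / px**2
    cell_mask = _cell_blob_mask(shape, area_px, rng)

    radius_px = params.rod_radius / px
    n = params.n_mitochondria
    lengths_um = _sample_truncated(
        rng, params.length_mean, params.length_sd, low=max(0.5, 2 * params.rod_radius), size=n
    )
    amplitudes = rng.uniform(0.7, 1.3, size=n)
    allowed = ndimage.binary_erosion(cell_mask, iterations=2)
    rods, _ = _place_rods(
        allowed, lengths_um / px, np.full(n, DEFAULT_RATIO_SCALING), amplitudes,
        radius_px, params.min_gap / px, rng,
    )
    image = np.zeros(shape)
    particles = []
    for rod in rods:
        hit = _capsule_footprint(rod.p0, rod.p1, radius_px, shape)
        slices, foot = hit
        image[slices][foot] += rod.amplitude
        pix = np.argwhere(foot) + [slices[0].start, slices[1].start]
        centroid = tuple(((rod.p0 + rod.p1) / 2.0) * px)
        particles.append(
            TruthParticle(
                centroid=(float(centroid[0]), float(centroid[1])),
                orientation=rod.orientation,
                length=rod.length_px * px,
                ratio=rod.ratio,
                pixels=pix,
            )
        )

    sigma_px = params.psf_fwhm_xy / FWHM_FACTOR / px
    signal = ndimage.gaussian_filter(image, sigma_px, mode="constant")
    integrated = float(signal[cell_mask].sum())
    image = _apply_noise(signal + params.background, params.noise_level, rng)

    truth = GroundTruth(
        cell_mask=cell_mask,
        particles=particles,
        decoys=[],
        pixel_size_xy=px,
        true_cell_area=float(cell_mask.sum()) * px**2,
        true_total_mito_area=float(sum(p.pixels.shape[0] for p in particles)) * px**2,
        mito_integrated_intensity=integrated,
    )
    return image, truth


def generate_bead_stack(
    fwhm_xy: float,
    fwhm_z: float,
    n_beads: int,
    noise_level: float = 0.0,
    seed: int = 0,
    pixel_size_xy: float = 0.08,
    z_step: float = 0.25,
    shape: tuple[int, int, int] | None = None,
    amplitude: float = 1.0,
    background: float = 0.01,
    spacing_factor: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render well-separated sub-resolution beads as 3-D Gaussians.

    Each bead's lateral/axial FWHM equal the requested values before noise.
    Returns ``(stack, positions)`` with positions in physical (z, y, x) µm.
    Beads sit on a jittered grid with lateral spacing ``spacing_factor`` times
    the lateral FWHM so profiles do not overlap.
    """
    if fwhm_xy <= 0 or fwhm_z <= 0:
        raise ConfigError("FWHM values must be positive")
    if n_beads < 0:
        raise ConfigError("n_beads must be >= 0")
    rng = np.random.default_rng(seed)
    sigma_xy = fwhm_xy / FWHM_FACTOR / pixel_size_xy
    sigma_z = fwhm_z / FWHM_FACTOR / z_step

    spacing = int(np.ceil(spacing_factor * fwhm_xy / pixel_size_xy))
    margin_xy = int(np.ceil(max(2.0 * fwhm_xy / pixel_size_xy, 16)))
    margin_z = int(np.ceil(2.5 * fwhm_z / z_step))
    if shape is None:
        ncols = max(int(np.ceil(np.sqrt(max(n_beads, 1)))), 1)
        side = 2 * margin_xy + max(ncols - 1, 0) * spacing + 1
        shape = (2 * margin_z + 1, side, side)
    nz, ny, nx = shape
    ncols = (nx - 2 * margin_xy) // spacing + 1 if nx >= 2 * margin_xy else 0
    nrows = (ny - 2 * margin_xy) // spacing + 1 if ny >= 2 * margin_xy else 0
    if n_beads > ncols * nrows:
        raise PlacementError(
            f"image {shape} fits at most {ncols * nrows} non-overlapping beads, "
            f"requested {n_beads}"
        )

    stack = np.full(shape, background)
    positions = np.zeros((n_beads, 3))
    zc = (nz - 1) / 2.0
    for i in range(n_beads):
        row, col = divmod(i, max(ncols, 1))
        y0 = margin_xy + row * spacing + rng.uniform(-1.0, 1.0)
        x0 = margin_xy + col * spacing + rng.uniform(-1.0, 1.0)
        z0 = zc + rng.uniform(-0.5, 0.5)
        positions[i] = (z0 * z_step, y0 * pixel_size_xy, x0 * pixel_size_xy)
        _add_gaussian_bead(stack, (z0, y0, x0), (sigma_z, sigma_xy, sigma_xy), amplitude)
    stack = _apply_noise(stack, noise_level, rng, read_noise_sd=0.2)
    return stack, positions


def _add_gaussian_bead(
    stack: np.ndarray, center: tuple[float, float, float],
    sigma: tuple[float, float, float], amplitude: float,
) -> None:
    lo = [max(int(np.floor(c - 4 * s)), 0) for c, s in zip(center, sigma)]
    hi = [min(int(np.ceil(c + 4 * s)) + 1, n) for c, s, n in zip(center, sigma, stack.shape)]
    zz, yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    stack[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * np.exp(
        -((zz - center[0]) ** 2) / (2 * sigma[0] ** 2)
        - ((yy - center[1]) ** 2) / (2 * sigma[1] ** 2)
        - ((xx - center[2]) ** 2) / (2 * sigma[2] ** 2)
    )


def generate_rogfp1_series(
    params: RoGFPSeriesParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Excitation-pair frame sequences with baseline/oxidant/reductant epochs.

    Returns ``(f395, f470, labels)`` where both frame arrays are (t, h, w) and
    ``labels`` gives one of ``baseline | oxidant | reductant`` per frame.
    Noise-free, the baseline frame ratio equals the value analytically implied
    by ``(true_oxd, r_red, r_ox, instrument_factor)``, the oxidant-epoch ratio
    equals ``r_ox`` and the reductant-epoch ratio equals ``r_red``.  The 470 nm
    level encodes the instrument factor (oxidant/reductant level quotient).
    """
    rng = np.random.default_rng(params.seed)
    n_base, n_ox, n_red = params.epoch_lengths
    b = params.brightness
    d, i_f = params.true_oxd, params.instrument_factor
    r_base = ratio_from_oxd(d, params.r_red, params.r_ox, i_f)

    # F470 is linear in the oxidized sensor fraction; full reduction -> level b,
    # full oxidation -> level b * instrument_factor
    levels_470 = [b * ((1.0 - d) + d * i_f), b * i_f, b * 1.0]
    ratios = [r_base, params.r_ox, params.r_red]
    labels = np.array(
        ["baseline"] * n_base + ["oxidant"] * n_ox + ["reductant"] * n_red, dtype=object
    )
    t_total = n_base + n_ox + n_red
    h, w = params.frame_shape
    f470 = np.empty((t_total, h, w))
    f395 = np.empty((t_total, h, w))
    start = 0
    for n_frames, lvl, r in zip(params.epoch_lengths, levels_470, ratios):
        f470[start : start + n_frames] = lvl
        f395[start : start + n_frames] = r * lvl
        start += n_frames
    if params.noise_sd > 0:
        f470 += rng.normal(0.0, params.noise_sd * b, size=f470.shape)
        f395 += rng.normal(0.0, params.noise_sd * b, size=f395.shape)
        np.clip(f470, 1e-6, None, out=f470)
        np.clip(f395, 0.0, None, out=f395)
    return f395, f470, labels
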