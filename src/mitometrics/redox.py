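"""Excitation-ratiometric redox quantification.

From paired 395 nm / 470 nm frame sequences: per-frame ratio traces,
calibration against saturating oxidant/reductant plateaus, the relative
degree of sensor oxidation, and the Nernst reduction potential.

The oxidation degree uses the standard excitation-ratiometric form with a
470 nm instrument factor:

    OxD = (R - R_red) / (I * (R_ox - R) + (R - R_red)),   I = F470_ox / F470_red

and the potential is E = E0 - (R_gas * T / (2 * F)) * ln((1 - OxD) / OxD).
The sensor midpoint potential defaults to -291 mV and the temperature to
310.15 K (cells at 37 °C); both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import constants

from .errors import CalibrationError, ConfigError, DataError

#: default sensor midpoint potential, mV
DEFAULT_E0_MV = -291.0
#: default temperature, K (37 °C)
DEFAULT_TEMPERATURE_K = 310.15
#: electrons transferred by the sensor's dithiol/disulfide couple
N_ELECTRONS = 2

BASELINE = "baseline"
OXIDANT = "oxidant"
REDUCTANT = "reductant"
EPOCHS = (BASELINE, OXIDANT, REDUCTANT)


@dataclass
class RoGFPTrace:
    """Per-frame ratio trace for one cell, with epoch labels.

    ``f470_means`` keeps the per-frame 470 nm mask means needed for the
    instrument factor.  ``invalid`` flags frames whose 470 nm mean was zero.
    """

    ratios: np.ndarray
    labels: np.ndarray
    f470_means: np.ndarray
    frame_rate_hz: float = 0.1
    invalid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.f470_means = np.asarray(self.f470_means, dtype=float)
        if not (self.ratios.shape == self.labels.shape == self.f470_means.shape):
            raise DataError("ratios, labels and f470_means must have equal length")
        unknown = set(self.labels) - set(EPOCHS)
        if unknown:
            raise DataError(f"unknown epoch labels: {sorted(unknown)}")
        if self.invalid is None:
            self.invalid = np.zeros(self.ratios.shape, dtype=bool)

    def epoch(self, name: str) -> np.ndarray:
        return np.flatnonzero((self.labels == name) & ~self.invalid)


@dataclass
class CalibrationResult:
    """Endpoint ratios and instrument factor from saturating treatments."""

    r_red: float
    r_ox: float
    instrument_factor: float

    def __post_init__(self) -> None:
        if self.r_red >= self.r_ox:
            raise CalibrationError(
                f"calibration failure: r_red ({self.r_red:.4g}) must be below "
                f"r_ox ({self.r_ox:.4g})"
            )
        if self.instrument_factor <= 0:
            raise CalibrationError("instrument factor must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RedoxState:
    """Oxidation degree and reduction potential for one cell."""

    oxd: float
    e_mv: float
    e0_mv: float = DEFAULT_E0_MV
    temperature_k: float = DEFAULT_TEMPERATURE_K


def compute_ratio_trace(
    f395: np.ndarray,
    f470: np.ndarray,
    cell_mask: np.ndarray,
    labels: np.ndarray,
    frame_rate_hz: float = 0.1,
) -> RoGFPTrace:
    """Per-frame R = mean(F395 in mask) / mean(F470 in mask).

    Frames with zero 470 nm mean are flagged invalid rather than dropped.
    """
    f395 = np.asarray(f395, dtype=float)
    f470 = np.asarray(f470, dtype=float)
    if f395.shape != f470.shape:
        raise DataError("excitation frame sequences must have identical shape")
    if len(labels) != f395.shape[0]:
        raise DataError("one epoch label per frame is required")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise DataError("empty cell mask")
    m395 = f395[:, cell_mask].mean(axis=1)
    m470 = f470[:, cell_mask].mean(axis=1)
    invalid = m470 == 0
    ratios = np.full(m395.shape, np.nan)
    np.divide(m395, m470, out=ratios, where=~invalid)
    return RoGFPTrace(
        ratios=ratios,
        labels=np.asarray(labels, dtype=object),
        f470_means=m470,
        frame_rate_hz=frame_rate_hz,
        invalid=invalid,
    )


def _plateau_frames(trace: RoGFPTrace, name: str, fraction: float, minimum: int = 5) -> np.ndarray:
    idx = trace.epoch(name)
    if idx.size < minimum:
        raise CalibrationError(
            f"missing or too-short {name!r} epoch ({idx.size} frames, need >= {minimum})"
        )
    keep = max(int(np.ceil(idx.size * fraction)), 1)
    return idx[-keep:]


def extract_calibration(trace: RoGFPTrace, plateau_fraction: float = 0.5) -> CalibrationResult:
    """Endpoint ratios from the last ``plateau_fraction`` of each saturating epoch.

    The trailing part of each epoch avoids transition kinetics.  The
    instrument factor is the 470 nm plateau-mean quotient (oxidant/reductant).
    """
    if not 0 < plateau_fraction <= 1:
        raise ConfigError("plateau_fraction must lie in (0, 1]")
    ox = _plateau_frames(trace, OXIDANT, plateau_fraction)
    red = _plateau_frames(trace, REDUCTANT, plateau_fraction)
    return CalibrationResult(
        r_red=float(trace.ratios[red].mean()),
        r_ox=float(trace.ratios[ox].mean()),
        instrument_factor=float(trace.f470_means[ox].mean() / trace.f470_means[red].mean()),
    )


def compute_oxd(
    ratio: float | np.ndarray, cal: CalibrationResult, clamp: bool = True
) -> float | np.ndarray:
    """Relative degree of sensor oxidation for a ratio (or array of ratios).

    Values are clamped to [0, 1]; out-of-range inputs (ratios beyond the
    calibration endpoints) are thereby flagged at the endpoints.
    """
    r = np.asarray(ratio, dtype=float)
    numerator = r - cal.r_red
    denominator = cal.instrument_factor * (cal.r_ox - r) + numerator
    oxd = numerator / denominator
    if clamp:
        oxd = np.clip(oxd, 0.0, 1.0)
    return float(oxd) if np.isscalar(ratio) else oxd


def compute_potential(
    oxd: float,
    e0_mv: float = DEFAULT_E0_MV,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Nernst reduction potential (mV) at a given oxidation degree.

    Undefined at the endpoints OxD = 0 and OxD = 1.
    """
    if not 0.0 < oxd < 1.0:
        raise DataError(f"potential undefined at OxD = {oxd}; need 0 < OxD < 1")
    rt_over_nf_mv = constants.R * temperature_k / (N_ELECTRONS * constants.value(
        "Faraday constant"
    )) * 1000.0
    return e0_mv - rt_over_nf_mv * np.log((1.0 - oxd) / oxd)


def quantify_trace(
    trace: RoGFPTrace,
    plateau_fraction: float = 0.5,
    e0_mv: float = DEFAULT_E0_MV,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> tuple[CalibrationResult, RedoxState, float]:
    """Calibrate a trace and quantify its baseline epoch.

    Returns ``(calibration, state, baseline_ratio)``; the baseline ratio is
    the mean over all valid baseline frames.
    """
    cal = extract_calibration(trace, plateau_fraction)
    base = trace.epoch(BASELINE)
    if base.size == 0:
        raise DataError("trace has no baseline frames")
    r_base = float(trace.ratios[base].mean())
    oxd = compute_oxd(r_base, cal)
    oxd_safe = float(np.clip(oxd, 1e-9, 1 - 1e-9))
    state = RedoxState(
        oxd=float(oxd),
        e_mv=compute_potential(oxd_safe, e0_mv, temperature_k),
        e0_mv=e0_mv,
        temperature_k=temperature_k,
    )
    return cal, state, r_base
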