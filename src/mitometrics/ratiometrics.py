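"""Emission-ratiometric JC-1 image computation.

The green (~530 nm, monomer) over red (~590 nm, J-aggregate) intensity
quotient reports relative mitochondrial polarization.  A fixed scaling
constant (default 200) keeps the quotient in a convenient display range;
analysis values are stored as floating point and never quantized to 8 bit.
No background subtraction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError

DEFAULT_RATIO_SCALING = 200.0


@dataclass
class ChannelStack:
    """Registered dual-emission image data (2-D plane or 3-D stack).

    Attributes
    ----------
    green, red:
        Intensity arrays of identical shape.  ``green`` is the short-wavelength
        (monomer) channel, ``red`` the long-wavelength (aggregate) channel.
    pixel_size_xy:
        Lateral sampling in µm/pixel.
    z_step:
        Axial plane spacing in µm (ignored for 2-D data).
    """

    green: np.ndarray
    red: np.ndarray
    pixel_size_xy: float = 0.08
    z_step: float = 0.25

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.green.shape != self.red.shape:
            raise DataError(
                f"channel shape mismatch: green {self.green.shape} vs red {self.red.shape}"
            )
        if self.green.ndim not in (2, 3):
            raise DataError(f"expected 2-D or 3-D channels, got {self.green.ndim}-D")
        if self.green.size and (np.nanmin(self.green) < 0 or np.nanmin(self.red) < 0):
            raise DataError("channel intensities must be non-negative")
        if self.pixel_size_xy <= 0:
            raise ConfigError("pixel_size_xy must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.green.shape

    @property
    def ndim(self) -> int:
        return self.green.ndim

    def summed(self) -> np.ndarray:
        """Channel sum, used for focus selection and thresholding."""
        return self.green + self.red


@dataclass
class RatioImage:
    """Per-voxel ratiometric values plus a validity mask.

    ``invalid_mask`` marks voxels where the ratio is undefined (red channel
    zero); those voxels carry no polarization information and are excluded
    from all downstream statistics.
    """

    values: np.ndarray
    invalid_mask: np.ndarray
    scaling: float = DEFAULT_RATIO_SCALING
    pixel_size_xy: float = 0.08
    z_step: float = field(default=0.25)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        """Flat array of defined ratio values."""
        return self.values[~self.invalid_mask]


def compute_ratio(stack: ChannelStack, scaling: float = DEFAULT_RATIO_SCALING) -> RatioImage:
    """Compute the scaled green/red emission ratio per voxel.

    ``R = green * scaling / red``.  Voxels with ``red == 0`` are flagged in
    ``invalid_mask`` and set to NaN in ``values``.

    Parameters
    ----------
    stack:
        Registered dual-channel data.
    scaling:
        Dimensionless multiplier applied to the green channel (default 200).
    """
    if scaling <= 0:
        raise ConfigError("scaling must be positive")
    invalid = stack.red == 0
    values = np.full(stack.shape, np.nan, dtype=float)
    np.divide(stack.green * scaling, stack.red, out=values, where=~invalid)
    return RatioImage(
        values=values,
        invalid_mask=invalid,
        scaling=scaling,
        pixel_size_xy=stack.pixel_size_xy,
        z_step=stack.z_step,
    )
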