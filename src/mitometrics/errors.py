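"""Exception hierarchy.

Errors are grouped so the CLI can map them to distinct exit codes:
configuration problems, data/input problems, and computation failures.
"""


class MitometricsError(Exception):
    """Base class for all package errors."""


class ConfigError(MitometricsError):
    """Invalid configuration or parameter values."""


class DataError(MitometricsError):
    """Malformed or inconsistent input data (shape mismatch, empty mask, ...)."""


class PlacementError(MitometricsError):
    """Synthetic scene cannot place the requested objects."""


class InfeasibleSceneError(PlacementError):
    """Requested object load exceeds the available cell area."""


class FitError(MitometricsError):
    """A model fit failed to converge or is ill-posed."""


class CalibrationError(MitometricsError):
    """Redox calibration is missing an epoch or is internally inconsistent."""


class MeasurementError(MitometricsError):
    """A per-particle measurement could not be computed."""


class PairingError(MitometricsError):
    """Pre/post records could not be matched to the same cell."""
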