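"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class OpporscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(OpporscreenError):
    """Invalid or missing configuration (bad spec, unknown scanner, ...)."""


class DataError(OpporscreenError):
    """Input data violates a contract (missing level, empty class, ...)."""


class MissingCalibrationError(ConfigError):
    """No HU-to-BMD calibration configured for the requested scanner."""


class MissingCorrectionError(ConfigError):
    """No contrast correction configured for an enhanced phase."""


class UnsupportedProtocolError(ConfigError):
    """Acquisition protocol outside the calibrated regime (e.g. not 120 kVp)."""


class DegenerateGeometryError(ConfigError):
    """Phantom geometry too small for the requested voxel spacing or shell."""


class MissingLevelError(DataError):
    """A requested vertebral level is absent from the mask."""


class EmptyRegionError(DataError):
    """A mask or compartment is empty, the level is non-evaluable."""


class DegeneratePredictorError(DataError):
    """Zero-variance predictor cannot be standardized."""


class UndefinedStatisticError(DataError):
    """Statistic undefined for this input (single outcome class, etc.)."""


class SeparationError(DataError):
    """Perfect separation in a logistic fit; no finite estimate exists."""


class RosterError(DataError):
    """Exclusion counts inconsistent with the available patient pool."""
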