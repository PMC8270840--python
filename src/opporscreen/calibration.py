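"""Asynchronous HU-to-BMD calibration and contrast-phase correction.

Quantitative CT converts attenuation to volumetric bone mineral
density through a scanner/protocol-specific linear relation obtained
from phantom scans acquired separately from the patient ("asynchronous"
calibration).  Scans acquired after intravenous contrast injection are
additionally corrected with a linear per-phase equation.  Both steps
are applied, in that order, before any bone measure is extracted:

    vBMD       = slope_cal * HU + intercept_cal
    vBMD_corr  = slope_phase * vBMD + intercept_phase   (enhanced phases)

Coefficients live in configuration (JSON/YAML), not in code; the
defaults shipped with the package are synthetic placeholders intended
for phantom work and testing, not clinical coefficients.
Calibrations are keyed per scanner at 120 kVp; other tube voltages are
rejected as uncalibrated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import (
    ConfigError,
    MissingCalibrationError,
    MissingCorrectionError,
    UnsupportedProtocolError,
)
from .image import CtVolume

CONTRAST_PHASES = ("none", "arterial", "portal_venous")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear HU -> vBMD map for one scanner/protocol (120 kVp)."""

    scanner_id: str
    slope: float  # mg/cm^3 per HU
    intercept: float  # mg/cm^3

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ConfigError("calibration slope must be positive")


@dataclass(frozen=True)
class ContrastCorrection:
    """Linear vBMD correction for one intravenous contrast phase."""

    phase: str
    slope: float  # dimensionless
    intercept: float  # mg/cm^3

    def __post_init__(self) -> None:
        if self.phase not in ("arterial", "portal_venous"):
            raise ConfigError(f"unknown contrast phase {self.phase!r}")
        if self.slope <= 0:
            raise ConfigError("contrast-correction slope must be positive")


@dataclass(frozen=True)
class CalibrationConfig:
    """A set of scanner calibrations plus per-phase contrast corrections."""

    scanners: dict[str, CalibrationModel]
    corrections: dict[str, ContrastCorrection]

    def model_for(self, scanner_id: str, kvp: float = 120.0) -> CalibrationModel:
        if abs(kvp - 120.0) > 1e-9:
            raise UnsupportedProtocolError(
                f"no calibration for tube voltage {kvp} kVp (120 kVp only)"
            )
        try:
            return self.scanners[scanner_id]
        except KeyError:
            raise MissingCalibrationError(
                f"no calibration configured for scanner {scanner_id!r}"
            ) from None

    def correction_for(self, phase: str) -> ContrastCorrection:
        try:
            return self.corrections[phase]
        except KeyError:
            raise MissingCorrectionError(
                f"no contrast correction configured for phase {phase!r}"
            ) from None


#: Synthetic placeholder coefficients used for digital phantoms and tests.
DEFAULT_CALIBRATION = CalibrationConfig(
    scanners={"synthetic": CalibrationModel("synthetic", slope=0.8, intercept=-4.0)},
    corrections={
        "arterial": ContrastCorrection("arterial", slope=0.92, intercept=-8.0),
        "portal_venous": ContrastCorrection("portal_venous", slope=0.88, intercept=-12.0),
    },
)


def load_calibration(path: str | Path) -> CalibrationConfig:
    """Load a calibration config from a JSON or YAML file.

    Expected structure::

        scanners:
          - {scanner_id: philips_ict256, slope: 0.78, intercept: -3.1}
        contrast_corrections:
          - {phase: arterial, slope: 0.91, intercept: -9.0}
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"calibration file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        scanners = {
            s["scanner_id"]: CalibrationModel(s["scanner_id"], float(s["slope"]), float(s["intercept"]))
            for s in raw.get("scanners", [])
        }
        corrections = {
            c["phase"]: ContrastCorrection(c["phase"], float(c["slope"]), float(c["intercept"]))
            for c in raw.get("contrast_corrections", [])
        }
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed calibration config {path}: {exc}") from exc
    if not scanners:
        raise ConfigError(f"calibration config {path} defines no scanners")
    return CalibrationConfig(scanners, corrections)


def hu_to_bmd(hu, model: CalibrationModel):
    """Convert attenuation (HU) to volumetric BMD (mg/cm^3).

    Elementwise over arrays. Negative outputs are permitted (air, fat);
    downstream masks restrict evaluation to bone.
    """
    return model.slope * np.asarray(hu, dtype=np.float64) + model.intercept


def bmd_to_hu(bmd, model: CalibrationModel):
    """Inverse calibration: the attenuation a density would produce.

    Used by the phantom generator so that calibration recovery is exact
    in the noiseless case.
    """
    return (np.asarray(bmd, dtype=np.float64) - model.intercept) / model.slope


def correct_contrast(bmd, phase: str, config: CalibrationConfig):
    """Correct vBMD for intravenous contrast enhancement.

    ``phase="none"`` is the identity; enhanced phases apply the
    configured linear equation. Must be applied after :func:`hu_to_bmd`
    and before any measure extraction.
    """
    if phase == "none":
        return np.asarray(bmd, dtype=np.float64)
    if phase not in ("arterial", "portal_venous"):
        raise ConfigError(f"unknown contrast phase {phase!r}")
    corr = config.correction_for(phase)
    return corr.slope * np.asarray(bmd, dtype=np.float64) + corr.intercept


def calibrate_volume(volume: CtVolume, config: CalibrationConfig = DEFAULT_CALIBRATION) -> np.ndarray:
    """Full attenuation-to-density pipeline for one volume.

    Looks up the scanner calibration (120 kVp enforced), converts HU to
    vBMD, then applies the contrast correction for the volume's phase.
    Returns a float64 density field in mg/cm^3 on the volume's grid.
    """
    model = config.model_for(volume.scanner_id, volume.kvp)
    bmd = hu_to_bmd(volume.data, model)
    return correct_contrast(bmd, volume.contrast_phase, config)
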