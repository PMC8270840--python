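"""Volumetric bone measures from labelled vertebral masks.

Given a calibrated, contrast-corrected density field (mg/cm^3) and a
vertebral label mask, this module reduces each vertebra to its body,
erodes the body by a physical distance (default 5 mm) to discard the
cortical shell, and computes

* trabecular vBMD — mean density over the eroded (trabecular) compartment,
* integral vBMD — mean density over the whole vertebral body,
* BMC — total mineral mass of the body in grams,

and aggregates evaluable levels (T12-L4 by default) to patient level
by an unweighted mean.

Erosion uses the Euclidean distance transform with anisotropic voxel
spacing: a voxel survives if its distance to the mask complement is
*strictly greater* than the erosion distance. The erosion distance is
physical (millimetres), not a voxel count — clinical reformats have
0.9-3 mm slices, so voxel-wise erosion would be anisotropic in
physical space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError, EmptyRegionError, MissingLevelError
from .image import VOLUMETRIC_LEVELS, VertebraMask

#: Erosion distance excluding cortical bone, in millimetres.
DEFAULT_EROSION_MM = 5.0

EXCLUSION_REASONS = ("fracture", "degeneration", "other")


@dataclass
class LevelMeasures:
    """Bone measures of one vertebral level.

    ``excluded`` marks levels removed from patient aggregation by the
    quality survey (fracture, degenerative change, other abnormality);
    ``evaluable`` is False when the trabecular compartment vanished
    under erosion.
    """

    level: str
    trabecular_vbmd: float = np.nan  # mg/cm^3
    integral_vbmd: float = np.nan  # mg/cm^3
    bmc: float = np.nan  # g
    body_volume: float = np.nan  # cm^3
    evaluable: bool = True
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.excluded and self.exclusion_reason not in EXCLUSION_REASONS:
            raise DataError(
                f"exclusion reason must be one of {EXCLUSION_REASONS}, "
                f"got {self.exclusion_reason!r}"
            )


def separate_body(mask: VertebraMask, level: str) -> np.ndarray:
    """Boolean mask of the vertebral body of *level*.

    If the mask carries subregion labels the body label is returned
    directly. For an unpartitioned vertebra a geometric heuristic cuts
    at the posterior wall: the voxel-count profile along the
    anterior-posterior axis has a large anterior mode (the body) and a
    smaller posterior one (the posterior elements); the cut plane is
    placed at the profile minimum between the two modes.
    """
    labs = mask.labels_for(level)
    body_labs = [lab for lab in labs if mask.subregion_map.get(lab) == "body"]
    if body_labs:
        out = np.zeros(mask.labels.shape, dtype=bool)
        for lab in body_labs:
            out |= mask.labels == lab
        return out
    if any(mask.subregion_map.get(lab) == "posterior" for lab in labs):
        # Posterior elements labelled but no body: degenerate, empty body.
        return np.zeros(mask.labels.shape, dtype=bool)

    support = mask.support(level)
    profile = support.sum(axis=(0, 2)).astype(float)
    nz = np.nonzero(profile)[0]
    if nz.size == 0:
        raise MissingLevelError(f"level {level!r} has empty support")
    # Smooth lightly so single-voxel dents do not masquerade as the wall.
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(profile, kernel, mode="same")
    peak = nz[0] + int(np.argmax(smooth[nz[0] : nz[-1] + 1]))
    if peak >= nz[-1]:
        return support  # no posterior lobe behind the main mode
    valley = peak + 1 + int(np.argmin(smooth[peak + 1 : nz[-1] + 1]))
    if smooth[valley] >= 0.5 * smooth[peak]:
        return support  # no pronounced waist: treat as body only
    body = support.copy()
    body[:, valley:, :] = False
    return body


def erode_metric(
    body_mask: np.ndarray,
    distance_mm: float = DEFAULT_EROSION_MM,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Erode a boolean mask by a physical Euclidean distance.

    Keeps voxels whose distance to the nearest background voxel,
    measured with the anisotropic spacing, strictly exceeds
    ``distance_mm``. ``distance_mm = 0`` is the identity. May return an
    empty mask (the level is then non-evaluable, not an error here).
    """
    if distance_mm < 0:
        raise DataError("erosion distance must be non-negative")
    body_mask = np.asarray(body_mask, dtype=bool)
    if distance_mm == 0:
        return body_mask.copy()
    if not body_mask.any():
        return body_mask.copy()
    dt = ndimage.distance_transform_edt(body_mask, sampling=spacing_mm)
    return dt > distance_mm


def trabecular_vbmd(volume_bmd: np.ndarray, trabecular_mask: np.ndarray) -> float:
    """Mean calibrated density (mg/cm^3) over the trabecular compartment."""
    trabecular_mask = np.asarray(trabecular_mask, dtype=bool)
    if not trabecular_mask.any():
        raise EmptyRegionError("trabecular compartment is empty")
    return float(np.mean(volume_bmd[trabecular_mask]))


def integral_vbmd(volume_bmd: np.ndarray, body_mask: np.ndarray) -> float:
    """Mean calibrated density (mg/cm^3) over the whole vertebral body."""
    body_mask = np.asarray(body_mask, dtype=bool)
    if not body_mask.any():
        raise EmptyRegionError("body mask is empty")
    return float(np.mean(volume_bmd[body_mask]))


def bmc(
    volume_bmd: np.ndarray,
    body_mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
) -> float:
    """Bone mineral content in grams: sum of density x voxel volume.

    mg/cm^3 times cm^3 gives mg; divided by 1000 for grams. Identical
    to ``integral_vbmd * body_volume / 1000`` by construction.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    if not body_mask.any():
        raise EmptyRegionError("body mask is empty")
    voxvol_cm3 = float(np.prod(spacing_mm)) * 1e-3
    return float(np.sum(volume_bmd[body_mask]) * voxvol_cm3 / 1000.0)


def measure_level(
    volume_bmd: np.ndarray,
    mask: VertebraMask,
    level: str,
    spacing_mm: tuple[float, float, float],
    erosion_mm: float = DEFAULT_EROSION_MM,
) -> LevelMeasures:
    """Compute all volumetric measures of one level.

    A level whose trabecular compartment empties under erosion is
    returned with ``evaluable=False`` rather than raising.
    """
    body = separate_body(mask, level)
    if not body.any():
        return LevelMeasures(level=level, evaluable=False)
    trab_mask = erode_metric(body, erosion_mm, spacing_mm)
    voxvol_cm3 = float(np.prod(spacing_mm)) * 1e-3
    integral = integral_vbmd(volume_bmd, body)
    volume = float(body.sum()) * voxvol_cm3
    result = LevelMeasures(
        level=level,
        integral_vbmd=integral,
        bmc=bmc(volume_bmd, body, spacing_mm),
        body_volume=volume,
    )
    if trab_mask.any():
        result.trabecular_vbmd = trabecular_vbmd(volume_bmd, trab_mask)
    else:
        result.evaluable = False
    return result


def aggregate_patient(
    levels: list[LevelMeasures],
    eligible_levels: tuple[str, ...] = VOLUMETRIC_LEVELS,
) -> dict[str, float]:
    """Patient-level measures: unweighted mean over usable levels.

    A level contributes if it is eligible, evaluable and not excluded
    by the quality survey. Raises :class:`EmptyRegionError` when no
    level qualifies (the patient is non-evaluable).
    """
    usable = [
        lm
        for lm in levels
        if lm.level in eligible_levels and lm.evaluable and not lm.excluded
    ]
    if not usable:
        raise EmptyRegionError("no evaluable eligible level for this patient")
    return {
        "trabecular_vbmd": float(np.mean([lm.trabecular_vbmd for lm in usable])),
        "integral_vbmd": float(np.mean([lm.integral_vbmd for lm in usable])),
        "bmc": float(np.mean([lm.bmc for lm in usable])),
        "body_volume": float(np.mean([lm.body_volume for lm in usable])),
        "n_levels": len(usable),
    }


def measures_frame(levels: list[LevelMeasures]) -> pd.DataFrame:
    """Tabular (CSV-ready) view of per-level measures."""
    return pd.DataFrame(
        [
            {
                "level": lm.level,
                "trabecular_vbmd": lm.trabecular_vbmd,
                "integral_vbmd": lm.integral_vbmd,
                "bmc": lm.bmc,
                "body_volume": lm.body_volume,
                "evaluable": lm.evaluable,
                "excluded": lm.excluded,
                "exclusion_reason": lm.exclusion_reason,
            }
            for lm in levels
        ]
    )
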