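"""CT-based areal BMD from virtual posterior-anterior projections.

DXA reports *areal* BMD: mineral mass per projected area (g/cm^2). To
compare CT against it on its own terms, the calibrated density field
is integrated along the anterior-posterior axis through the vertebral
*body* masks only — a parallel (non-divergent) monoenergetic
projection that conserves mass exactly and excludes the lateral
processes by construction, because only body voxels contribute.

For a pixel of the projection plane,

    aBMD [g/cm^2] = sum_y density [mg/cm^3] * dy [mm] * 1e-4

and the patient value is the footprint mean, averaged over evaluable
levels L1-L4 (per level first, then across levels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, EmptyRegionError

#: Projection axis: anterior-posterior (axis 1 of the shared convention).
PROJECTION_AXIS = 1

#: mg/cm^3 * mm  ->  g/cm^2
_MG_MM_TO_G_CM2 = 1e-4


@dataclass
class ArealMap:
    """A virtual DXA image: areal density on the coronal plane.

    ``values`` has shape (nx, nz) in g/cm^2; ``footprint`` marks pixels
    that received at least one body voxel; values are zero elsewhere.
    """

    values: np.ndarray
    footprint: np.ndarray
    pixel_spacing_mm: tuple[float, float]  # (dx, dz)

    @property
    def pixel_area_cm2(self) -> float:
        return self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1] * 1e-2

    def total_mass_g(self) -> float:
        """Integrated areal density x area: the projected mineral mass."""
        return float(self.values.sum() * self.pixel_area_cm2)


@dataclass(frozen=True)
class TScoreReference:
    """Young-adult reference for T-score computation (g/cm^2).

    The shipped default is a synthetic placeholder — vendor reference
    curves are proprietary — and is configurable wherever used.
    """

    mean: float = 1.18
    sd: float = 0.12

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigError("T-score reference SD must be positive")


def project_pa(
    volume_bmd: np.ndarray,
    body_mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
) -> ArealMap:
    """Project masked density posterior-anteriorly onto the coronal plane.

    Only voxels of ``body_mask`` contribute. An empty mask yields an
    all-zero map with an empty footprint.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    dx, dy, dz = spacing_mm
    masked = np.where(body_mask, np.asarray(volume_bmd, dtype=np.float64), 0.0)
    values = masked.sum(axis=PROJECTION_AXIS) * dy * _MG_MM_TO_G_CM2
    footprint = body_mask.any(axis=PROJECTION_AXIS)
    values[~footprint] = 0.0
    return ArealMap(values=values, footprint=footprint, pixel_spacing_mm=(dx, dz))


def ct_abmd(areal_map: ArealMap) -> float:
    """Mean areal density (g/cm^2) over the footprint of a projection."""
    if not areal_map.footprint.any():
        raise EmptyRegionError("projection footprint is empty")
    return float(areal_map.values[areal_map.footprint].mean())


def patient_ct_abmd(
    volume_bmd: np.ndarray,
    body_masks: dict[str, np.ndarray],
    spacing_mm: tuple[float, float, float],
) -> float:
    """Patient CT-based aBMD: per-level projection means, then averaged.

    ``body_masks`` maps level name to its body mask (typically L1-L4).
    Levels with empty masks are skipped; raises if none is usable.
    """
    per_level = []
    for level, mask in body_masks.items():
        try:
            per_level.append(ct_abmd(project_pa(volume_bmd, mask, spacing_mm)))
        except EmptyRegionError:
            continue
    if not per_level:
        raise EmptyRegionError("no projectable level for this patient")
    return float(np.mean(per_level))


def t_score(abmd: float, ref: TScoreReference) -> float:
    """Standardised deviation from the young-adult reference, in SD units."""
    return (abmd - ref.mean) / ref.sd


def classify_t_score(t: float) -> str:
    """WHO diagnostic bands: T <= -2.5 osteoporosis, -2.5 < T <= -1 low
    bone mass, T > -1 normal."""
    if t <= -2.5:
        return "osteoporosis"
    if t <= -1.0:
        return "low_bone_mass"
    return "normal"
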