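"""In-memory containers for CT volumes and vertebral label masks.

Axis convention, shared by every module in the package:

* axis 0 — left-right (LR)
* axis 1 — anterior-posterior (AP); the index increases from anterior
  to posterior, so the vertebral body sits at *lower* indices than the
  posterior elements
* axis 2 — inferior-superior (IS)

Voxel spacing is anisotropic and carried in millimetres. Volumes and
masks are persisted as NIfTI (via nibabel) with the spacing encoded in
the affine; the label semantics of a mask (which integer is which
vertebral level and subregion) travel in a small JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DataError, MissingLevelError

#: Vertebral levels recognised by the package, cranial to caudal.
LEVELS = tuple(f"T{i}" for i in range(1, 13)) + tuple(f"L{i}" for i in range(1, 6))

#: Levels eligible for volumetric patient aggregation.
VOLUMETRIC_LEVELS = ("T12", "L1", "L2", "L3", "L4")

#: Levels projected for CT-based areal BMD.
AREAL_LEVELS = ("L1", "L2", "L3", "L4")


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise DataError(f"spacing must be three positive numbers, got {spacing!r}")
    return spacing


@dataclass
class CtVolume:
    """A 3-D attenuation field in Hounsfield units.

    Parameters
    ----------
    data:
        Attenuation values (HU), shape ``(nx, ny, nz)``.
    spacing_mm:
        Voxel spacing ``(dx, dy, dz)`` in millimetres.
    scanner_id:
        Identifier used to look up the HU-to-BMD calibration.
    contrast_phase:
        ``"none"``, ``"arterial"`` or ``"portal_venous"``.
    kvp:
        Peak tube voltage; calibrations are only valid at 120 kVp.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    scanner_id: str = "synthetic"
    contrast_phase: str = "none"
    kvp: float = 120.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DataError("CtVolume.data must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise DataError("CtVolume.data contains non-finite values")
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3 (product of spacings, mm^3 -> cm^3)."""
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz * 1e-3

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(
        cls,
        path: str | Path,
        scanner_id: str = "synthetic",
        contrast_phase: str = "none",
        kvp: float = 120.0,
    ) -> "CtVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            np.asanyarray(img.dataobj),
            spacing,
            scanner_id=scanner_id,
            contrast_phase=contrast_phase,
            kvp=kvp,
        )


@dataclass
class VertebraMask:
    """Integer label volume for vertebral levels and subregions.

    ``labels`` shares the grid of its companion :class:`CtVolume`.
    ``level_map`` assigns each positive label a vertebral level
    (``"T1"`` ... ``"L5"``); ``subregion_map`` assigns it a subregion,
    ``"body"`` or ``"posterior"``. A label missing from
    ``subregion_map`` marks an unpartitioned vertebra, for which the
    geometric body/posterior split heuristic applies downstream.
    """

    labels: np.ndarray
    level_map: dict[int, str] = field(default_factory=dict)
    subregion_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DataError("VertebraMask.labels must be 3-D")
        if self.labels.min() < 0:
            raise DataError("mask labels must be non-negative")
        self.level_map = {int(k): str(v) for k, v in self.level_map.items()}
        self.subregion_map = {int(k): str(v) for k, v in self.subregion_map.items()}
        bodies = [
            self.level_map[lab]
            for lab, sub in self.subregion_map.items()
            if sub == "body" and lab in self.level_map
        ]
        if len(bodies) != len(set(bodies)):
            raise DataError("each level may carry at most one body label")

    @property
    def levels(self) -> tuple[str, ...]:
        """Levels present, in anatomical order."""
        present = set(self.level_map.values())
        return tuple(lv for lv in LEVELS if lv in present)

    def labels_for(self, level: str) -> list[int]:
        labs = [lab for lab, lv in self.level_map.items() if lv == level]
        if not labs:
            raise MissingLevelError(f"level {level!r} not present in mask")
        return sorted(labs)

    def support(self, level: str) -> np.ndarray:
        """Boolean mask of every voxel belonging to *level*."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for lab in self.labels_for(level):
            out |= self.labels == lab
        return out

    def to_nifti(self, path: str | Path) -> None:
        """Write labels as NIfTI plus a ``<path>.labels.json`` sidecar."""
        affine = np.eye(4)
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))
        sidecar = Path(str(path) + ".labels.json")
        sidecar.write_text(
            json.dumps(
                {
                    "level_map": {str(k): v for k, v in self.level_map.items()},
                    "subregion_map": {str(k): v for k, v in self.subregion_map.items()},
                },
                indent=1,
            )
        )

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VertebraMask":
        img = nib.load(str(path))
        labels = np.asanyarray(img.dataobj).astype(np.int32)
        sidecar = Path(str(path) + ".labels.json")
        level_map: dict[int, str] = {}
        subregion_map: dict[int, str] = {}
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            level_map = {int(k): v for k, v in meta.get("level_map", {}).items()}
            subregion_map = {int(k): v for k, v in meta.get("subregion_map", {}).items()}
        return cls(labels, level_map, subregion_map)
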