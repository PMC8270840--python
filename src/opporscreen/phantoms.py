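"""Seeded digital vertebra phantoms.

The study's patient CT scans are not public, so every image-processing
stage in this package is exercised on synthetic phantoms: stacks of
vertebra-like bodies with a superellipsoidal cross-section, a denser
cortical shell, separate posterior elements, soft-tissue background,
Gaussian HU noise, optional contrast enhancement, and optional anterior
wedge deformities for fracture grading.

Attenuation is synthesised by *inverting* the calibration model (and,
for enhanced phases, the contrast correction), so that running the
calibration pipeline on a noiseless phantom recovers the ground-truth
densities exactly — a deliberate closure property that the test suite
relies on.

Geometry is intentionally simple: it is sufficient to exercise the
metric erosion and projection mathematics, not to be anatomically
realistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import (
    DEFAULT_CALIBRATION,
    CalibrationConfig,
    bmd_to_hu,
)
from .errors import ConfigError, DataError, DegenerateGeometryError
from .image import LEVELS, CtVolume, VertebraMask

#: Genant semiquantitative grade boundaries as fractional height loss.
#: Grade 1: 20-25 %, grade 2: 25-40 %, grade 3: > 40 %.
GENANT_BANDS = (0.20, 0.25, 0.40)


def genant_grade(anterior_height_mm: float, reference_height_mm: float) -> int:
    """Semiquantitative vertebral fracture grade from height loss.

    The fractional anterior height reduction
    ``r = 1 - anterior/reference`` is mapped to grades 0-3 using the
    conventional bands: < 20 % grade 0, 20-25 % grade 1, 25-40 % grade
    2, > 40 % grade 3.  A patient is dichotomised as *fractured* if any
    level reaches grade >= 1.
    """
    if anterior_height_mm <= 0 or reference_height_mm <= 0:
        raise DataError("vertebral heights must be positive")
    r = 1.0 - anterior_height_mm / reference_height_mm
    if r < GENANT_BANDS[0]:
        return 0
    if r < GENANT_BANDS[1]:
        return 1
    if r <= GENANT_BANDS[2]:
        return 2
    return 3


@dataclass
class PhantomSpec:
    """Parameters of a synthetic vertebral phantom.

    Densities are ground-truth values in mg/cm^3; the cortical shell is
    carved as the layer of body voxels within ``shell_thickness_mm`` of
    the body surface (Euclidean distance with physical spacing), the
    remainder is trabecular core.
    """

    levels: tuple[str, ...] = ("T12", "L1", "L2", "L3", "L4")
    body_extent_mm: tuple[float, float, float] = (34.0, 28.0, 27.0)
    shell_thickness_mm: float = 3.0
    trabecular_density: float = 100.0
    cortical_density: float = 400.0
    posterior_density: float = 300.0
    background_density: float = 30.0
    noise_sd: float = 0.0  # HU
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    contrast_phase: str = "none"
    #: per-level fractional anterior height loss, e.g. {"L1": 0.3}
    fracture_height_loss: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.levels) - set(LEVELS)
        if unknown:
            raise ConfigError(f"unknown vertebral levels: {sorted(unknown)}")
        if self.shell_thickness_mm <= 0:
            raise ConfigError("shell_thickness_mm must be positive")
        for name in ("trabecular_density", "cortical_density", "posterior_density", "background_density"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigError("spacing components must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.contrast_phase not in ("none", "arterial", "portal_venous"):
            raise ConfigError(f"unknown contrast phase {self.contrast_phase!r}")
        for lv, r in self.fracture_height_loss.items():
            if lv not in self.levels:
                raise ConfigError(f"fracture at level {lv!r} not in phantom levels")
            if not (0.0 <= r < 1.0):
                raise ConfigError("fracture_height_loss must lie in [0, 1)")


@dataclass
class LevelTruth:
    """Exact per-level ground truth of the discretised phantom."""

    level: str
    trabecular_vbmd: float  # mg/cm^3
    integral_vbmd: float  # mg/cm^3
    body_volume_cm3: float
    bmc_g: float
    anterior_height_mm: float
    reference_height_mm: float
    genant: int


@dataclass
class GroundTruth:
    """Ground truth for a whole phantom; ``fractured`` is Genant >= 1."""

    per_level: dict[str, LevelTruth]

    @property
    def fractured(self) -> bool:
        return any(t.genant >= 1 for t in self.per_level.values())


def _superellipse(nx: int, ny: int, dx: float, dy: float, cx: float, cy: float,
                  ax_mm: float, ay_mm: float, power: float = 2.5) -> np.ndarray:
    """Boolean 2-D cross-section |2(x-cx)/ax|^p + |2(y-cy)/ay|^p <= 1."""
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    u = np.abs(2.0 * (x[:, None] - cx) / ax_mm) ** power
    v = np.abs(2.0 * (y[None, :] - cy) / ay_mm) ** power
    return (u + v) <= 1.0


def generate_phantom(
    spec: PhantomSpec,
    calibration: CalibrationConfig = DEFAULT_CALIBRATION,
    scanner_id: str = "synthetic",
) -> tuple[CtVolume, VertebraMask, GroundTruth]:
    """Build a labelled digital phantom.

    Returns the attenuation volume (HU, with noise and contrast bias
    applied), the label mask (one body and one posterior-elements label
    per level), and the exact ground truth of the discretised geometry.
    """
    ax, ay, hz = (float(v) for v in spec.body_extent_mm)
    dx, dy, dz = spec.spacing_mm
    if ax <= dx or ay <= dy or hz <= dz:
        raise DegenerateGeometryError("body extent must exceed voxel spacing")
    if ax <= 2 * spec.shell_thickness_mm or ay <= 2 * spec.shell_thickness_mm or hz <= 2 * spec.shell_thickness_mm:
        raise DegenerateGeometryError("body extent must exceed twice the shell thickness")

    margin = 4.0  # mm of soft tissue around the bone
    post_depth = 0.35 * ay  # AP depth of the posterior-elements block
    gap = 4.0  # intervertebral spacing along IS

    nx = int(np.ceil((ax + 2 * margin) / dx))
    ny = int(np.ceil((ay + post_depth + 2 * margin) / dy))
    nz = int(np.ceil((len(spec.levels) * (hz + gap) + 2 * margin) / dz))

    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    density = np.full((nx, ny, nz), float(spec.background_density))

    level_map: dict[int, str] = {}
    subregion_map: dict[int, str] = {}
    per_level: dict[str, LevelTruth] = {}

    cx = margin + ax / 2.0
    cy_body = margin + ay / 2.0  # anterior side at low y per axis convention
    body_xy = _superellipse(nx, ny, dx, dy, cx, cy_body, ax, ay)

    y_mm = (np.arange(ny) + 0.5) * dy
    z_mm = (np.arange(nz) + 0.5) * dz

    # Posterior-elements block: centred laterally, behind the body.
    post_y0 = margin + ay
    post_y1 = post_y0 + post_depth
    post_x_half = 0.2 * ax
    x_mm = (np.arange(nx) + 0.5) * dx
    post_xy = (
        (np.abs(x_mm[:, None] - cx) <= post_x_half)
        & (y_mm[None, :] > post_y0)
        & (y_mm[None, :] <= post_y1)
    )

    # Anterior wedge weight: 1 at the anterior body edge, 0 at the
    # posterior edge; modulates the local body height for fractures.
    w_y = np.clip((margin + ay - y_mm) / ay, 0.0, 1.0)

    voxvol_cm3 = dx * dy * dz * 1e-3

    for i, level in enumerate(spec.levels):
        body_label = 2 * i + 1
        post_label = 2 * i + 2
        level_map[body_label] = level
        level_map[post_label] = level
        subregion_map[body_label] = "body"
        subregion_map[post_label] = "posterior"

        zc = margin + i * (hz + gap) + hz / 2.0
        frac = float(spec.fracture_height_loss.get(level, 0.0))
        # Local height shrinks linearly towards the anterior edge.
        local_h = hz * (1.0 - frac * w_y)  # (ny,)
        in_z = np.abs(z_mm[None, :] - zc) <= local_h[:, None] / 2.0  # (ny, nz)

        body = body_xy[:, :, None] & in_z[None, :, :]
        post = post_xy[:, :, None] & (np.abs(z_mm - zc) <= 0.35 * hz)[None, None, :]
        post &= ~body

        labels[body] = body_label
        labels[post] = post_label

        # Cortical shell: body voxels within shell_thickness of the surface.
        dt = ndimage.distance_transform_edt(body, sampling=spec.spacing_mm)
        shell = body & (dt <= spec.shell_thickness_mm)
        core = body & ~shell
        density[core] = spec.trabecular_density
        density[shell] = spec.cortical_density
        density[post] = spec.posterior_density

        n_core, n_shell = int(core.sum()), int(shell.sum())
        n_body = n_core + n_shell
        if n_body == 0:
            raise DegenerateGeometryError(f"level {level}: body empty at this spacing")
        integral = (
            n_core * spec.trabecular_density + n_shell * spec.cortical_density
        ) / n_body
        volume = n_body * voxvol_cm3
        per_level[level] = LevelTruth(
            level=level,
            trabecular_vbmd=float(spec.trabecular_density),
            integral_vbmd=float(integral),
            body_volume_cm3=float(volume),
            bmc_g=float(integral * volume / 1000.0),
            anterior_height_mm=hz * (1.0 - frac),
            reference_height_mm=hz,
            genant=genant_grade(hz * (1.0 - frac), hz),
        )

    # Contrast enhancement biases the *observed* bone density such that
    # the configured correction equation inverts it exactly.
    observed = density.copy()
    if spec.contrast_phase != "none":
        corr = calibration.correction_for(spec.contrast_phase)
        bone = labels > 0
        observed[bone] = (density[bone] - corr.intercept) / corr.slope

    model = calibration.model_for(scanner_id)
    hu = bmd_to_hu(observed, model)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape)

    volume = CtVolume(
        hu,
        spec.spacing_mm,
        scanner_id=scanner_id,
        contrast_phase=spec.contrast_phase,
    )
    mask = VertebraMask(labels, level_map, subregion_map)
    return volume, mask, GroundTruth(per_level)
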