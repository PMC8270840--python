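"""Diagnostic cutoffs and ROC-distance threshold transfer.

Quantitative-CT practice has accepted trabecular-vBMD cutoffs
(osteoporosis below 80 mg/cm^3, low bone mass 80-120 mg/cm^3, upper
bound inclusive), but no established bands for *integral* vBMD. The
transfer procedure derives them empirically: compute the reference
cutoff's (sensitivity, specificity) operating point for fracture
discrimination, scan every operating point of the target measure's
ROC curve on the same subjects, and adopt the target threshold whose
point lies at the smallest Euclidean distance — so the transferred
cutoff matches the reference's diagnostic behaviour as closely as the
data allow. Transferred cutoffs are rounded to the nearest 5 mg/cm^3.

Ties between equidistant operating points are broken toward higher
specificity (a screening context favours fewer false positives); the
rule is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, UndefinedStatisticError
from .stats import sens_spec_at

DEFAULT_ROUNDING_STEP = 5.0


@dataclass(frozen=True)
class DiagnosticThresholds:
    """A pair of diagnostic cutoffs for one measure (mg/cm^3).

    ``upper_inclusive`` controls the low-bone-mass band's upper edge:
    the accepted trabecular bands are closed there (80 <= v <= 120),
    the transferred integral bands half-open (160 <= v < 190).
    """

    measure: str
    osteoporosis_cutoff: float
    low_bone_mass_cutoff: float
    provenance: str = "reference"  # or "transferred"
    upper_inclusive: bool = False

    def __post_init__(self) -> None:
        if self.osteoporosis_cutoff >= self.low_bone_mass_cutoff:
            raise ConfigError("osteoporosis cutoff must lie below the low-bone-mass cutoff")
        if self.provenance not in ("reference", "transferred"):
            raise ConfigError(f"unknown provenance {self.provenance!r}")


#: Accepted trabecular-vBMD bands (upper bound inclusive).
ACR_TRABECULAR = DiagnosticThresholds(
    "trabecular_vbmd", 80.0, 120.0, provenance="reference", upper_inclusive=True
)

#: Integral-vBMD bands derived by ROC-distance transfer (half-open).
INTEGRAL_TRANSFERRED = DiagnosticThresholds(
    "integral_vbmd", 160.0, 190.0, provenance="transferred", upper_inclusive=False
)


def classify_band(value: float, thresholds: DiagnosticThresholds) -> str:
    """Assign a measurement to osteoporosis / low bone mass / normal."""
    if value < thresholds.osteoporosis_cutoff:
        return "osteoporosis"
    if value < thresholds.low_bone_mass_cutoff or (
        thresholds.upper_inclusive and value == thresholds.low_bone_mass_cutoff
    ):
        return "low_bone_mass"
    return "normal"


def round_to_step(value: float, step: float = DEFAULT_ROUNDING_STEP) -> float:
    """Round half away from zero to the nearest multiple of *step*."""
    if step <= 0:
        raise ConfigError("rounding step must be positive")
    return float(np.sign(value) * np.floor(abs(value) / step + 0.5) * step)


@dataclass
class TransferResult:
    """Outcome of one ROC-distance threshold transfer."""

    cutoff: float  # rounded, mg/cm^3
    cutoff_unrounded: float
    reference_point: tuple[float, float]  # (sensitivity %, specificity %)
    matched_point: tuple[float, float]
    distance: float  # Euclidean, on [0,1] x [0,1] axes
    rounding_step: float


def _bracket(sorted_values: np.ndarray, k: int) -> tuple[float, float]:
    """Values bracketing the split 'k subjects below threshold'."""
    n = sorted_values.size
    lo = sorted_values[k - 1] if k > 0 else sorted_values[0]
    hi = sorted_values[k] if k < n else sorted_values[-1]
    return float(lo), float(hi)


def transfer_threshold(
    outcome,
    reference_values,
    reference_cutoff: float,
    target_values,
    rounding_step: float = DEFAULT_ROUNDING_STEP,
    tie_break: str = "specificity",
) -> TransferResult:
    """Transfer a diagnostic cutoff between measures via ROC geometry.

    Both measures follow the "lower is abnormal" convention and must be
    observed on the same subjects. The scan enumerates every split of
    the sorted target values (0..n subjects called abnormal), computes
    its (sensitivity, specificity) point and minimises the Euclidean
    distance to the reference point, both axes on [0, 1]. Ties go to
    the higher-specificity point (``tie_break="specificity"``) or to
    the higher-sensitivity point (``"sensitivity"``).

    The cutoff realising the chosen split is placed between the two
    bracketing target values by linear interpolation, at the same
    relative position the reference cutoff occupies between *its*
    bracketing values — so transferring a measure onto itself returns
    the reference cutoff exactly, and an affine target relation maps
    the cutoff through that relation before rounding.
    """
    if tie_break not in ("specificity", "sensitivity"):
        raise ConfigError(f"unknown tie_break {tie_break!r}")
    outcome = np.asarray(outcome, dtype=bool)
    ref = np.asarray(reference_values, dtype=np.float64)
    tgt = np.asarray(target_values, dtype=np.float64)
    if not (outcome.shape == ref.shape == tgt.shape):
        raise UndefinedStatisticError("outcome and both measures must align")
    if np.unique(tgt).size < 2:
        raise UndefinedStatisticError("target measure is constant; nothing to transfer")

    ref_sens, ref_spec = sens_spec_at(outcome, ref, reference_cutoff, direction="below")
    ref_point = np.array([ref_sens, ref_spec]) / 100.0

    order = np.argsort(tgt, kind="stable")
    tgt_sorted = tgt[order]
    out_sorted = outcome[order]
    m = out_sorted.sum()
    n_neg = (~out_sorted).sum()

    # Split k: the k smallest target values are called abnormal. Only
    # splits between distinct values are realisable by a threshold.
    best = None
    cum_pos = np.concatenate([[0], np.cumsum(out_sorted)])
    for k in range(tgt_sorted.size + 1):
        if 0 < k < tgt_sorted.size and tgt_sorted[k - 1] == tgt_sorted[k]:
            continue
        sens = cum_pos[k] / m
        spec = 1.0 - (k - cum_pos[k]) / n_neg
        d = float(np.hypot(sens - ref_point[0], spec - ref_point[1]))
        key = (d, -spec) if tie_break == "specificity" else (d, -sens)
        if best is None or key < best[0]:
            best = (key, k, sens, spec)

    _, k, sens, spec = best
    t_lo, t_hi = _bracket(tgt_sorted, k)

    # Position of the reference cutoff inside its own bracketing gap.
    ref_sorted = np.sort(ref)
    k_ref = int(np.searchsorted(ref_sorted, reference_cutoff, side="left"))
    r_lo, r_hi = _bracket(ref_sorted, k_ref)
    frac = 0.5 if r_hi == r_lo else np.clip((reference_cutoff - r_lo) / (r_hi - r_lo), 0.0, 1.0)
    unrounded = t_lo + frac * (t_hi - t_lo)

    return TransferResult(
        cutoff=round_to_step(unrounded, rounding_step),
        cutoff_unrounded=float(unrounded),
        reference_point=(ref_sens, ref_spec),
        matched_point=(float(100.0 * sens), float(100.0 * spec)),
        distance=float(best[0][0]),
        rounding_step=float(rounding_step),
    )


def transfer_bands(
    outcome,
    reference_values,
    target_values,
    reference: DiagnosticThresholds = ACR_TRABECULAR,
    target_measure: str = "integral_vbmd",
    rounding_step: float = DEFAULT_ROUNDING_STEP,
) -> tuple[DiagnosticThresholds, dict[str, TransferResult]]:
    """Transfer both diagnostic cutoffs of a reference band pair."""
    results = {
        "osteoporosis": transfer_threshold(
            outcome, reference_values, reference.osteoporosis_cutoff,
            target_values, rounding_step,
        ),
        "low_bone_mass": transfer_threshold(
            outcome, reference_values, reference.low_bone_mass_cutoff,
            target_values, rounding_step,
        ),
    }
    bands = DiagnosticThresholds(
        target_measure,
        results["osteoporosis"].cutoff,
        results["low_bone_mass"].cutoff,
        provenance="transferred",
        upper_inclusive=False,
    )
    return bands, results
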