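"""Synthetic patient cohorts and the study exclusion roster.

The clinical cohort behind the screening study is not deposited; what
is published are group-level summaries: per-measure means and standard
deviations stratified by prevalent-fracture status (44 non-fractured
vs 148 fractured patients), the fraction of women per group, and the
patient-selection cascade.  This module reproduces that statistical
structure: each group is modelled as Gaussian per measure, with a
single shared latent factor inducing positive cross-correlation
between the bone measures of one subject.

The group parameters in :data:`GROUP_PARAMS` are the published
summaries and double as the package's default simulation conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, RosterError

#: Bone-measure columns (share the latent factor; lower = weaker bone).
BONE_MEASURES = (
    "dxa_tscore",
    "dxa_abmd",
    "ct_abmd",
    "manual_vbmd",
    "trabecular_vbmd",
    "integral_vbmd",
    "bmc",
)

#: All continuous measures carried by a cohort table.
MEASURES = ("age",) + BONE_MEASURES

#: Units for reporting.
UNITS = {
    "age": "years",
    "dxa_tscore": "SD",
    "dxa_abmd": "g/cm^2",
    "ct_abmd": "g/cm^2",
    "manual_vbmd": "mg/cm^3",
    "trabecular_vbmd": "mg/cm^3",
    "integral_vbmd": "mg/cm^3",
    "bmc": "g",
}

#: Published group summaries: {group: {measure: (mean, sd)}}, with group
#: sizes 44 (no fracture) / 148 (fracture) and the women counts 34/107.
GROUP_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "nonfractured": {
        "age": (64.3, 8.6),
        "dxa_tscore": (-1.4, 1.6),
        "dxa_abmd": (1.076, 0.219),
        "ct_abmd": (0.951, 0.204),
        "manual_vbmd": (119.7, 38.1),
        "trabecular_vbmd": (113.5, 34.3),
        "integral_vbmd": (188.0, 35.5),
        "bmc": (6.42, 1.87),
    },
    "fractured": {
        "age": (72.0, 9.3),
        "dxa_tscore": (-2.4, 1.6),
        "dxa_abmd": (0.948, 0.204),
        "ct_abmd": (0.752, 0.199),
        "manual_vbmd": (58.4, 32.7),
        "trabecular_vbmd": (62.8, 27.5),
        "integral_vbmd": (140.2, 32.1),
        "bmc": (5.00, 1.68),
    },
}

GROUP_SIZES = {"nonfractured": 44, "fractured": 148}
WOMEN_FRACTION = {"nonfractured": 34 / 44, "fractured": 107 / 148}


@dataclass
class CohortSpec:
    """Simulation parameters for a two-group fracture cohort.

    ``correlation`` is the pairwise correlation between any two bone
    measures of one subject, induced by a single latent factor; age is
    drawn independently within group (the within-group age/BMD
    dependence of the study population is unknown).
    """

    n_fractured: int = GROUP_SIZES["fractured"]
    n_nonfractured: int = GROUP_SIZES["nonfractured"]
    params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(m) for g, m in GROUP_PARAMS.items()}
    )
    women_fraction: dict[str, float] = field(default_factory=lambda: dict(WOMEN_FRACTION))
    correlation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractured <= 0 or self.n_nonfractured <= 0:
            raise ConfigError("group sizes must be positive")
        if not (0.0 <= self.correlation < 1.0):
            raise ConfigError("correlation must lie in [0, 1)")
        for group in ("fractured", "nonfractured"):
            if group not in self.params:
                raise ConfigError(f"missing parameters for group {group!r}")
            for measure, (mean, sd) in self.params[group].items():
                if sd <= 0:
                    raise ConfigError(f"{group}/{measure}: SD must be positive")
            wf = self.women_fraction.get(group)
            if wf is None or not (0.0 <= wf <= 1.0):
                raise ConfigError(f"{group}: women_fraction must lie in [0, 1]")

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Within each group every measure is Gaussian with the specified
    mean/SD.  Bone measures share a latent standard-normal factor with
    loading ``sqrt(correlation)``, so any two of them correlate at
    ``spec.correlation``; age is independent.  Returns one row per
    patient with columns ``id``, ``fracture`` (bool), ``sex`` and the
    measures of :data:`MEASURES`.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.correlation
    frames = []
    pid = 0
    for group, fracture in (("nonfractured", False), ("fractured", True)):
        n = spec.n_fractured if fracture else spec.n_nonfractured
        latent = rng.standard_normal(n)
        cols: dict[str, np.ndarray] = {}
        for measure in MEASURES:
            mean, sd = spec.params[group][measure]
            eps = rng.standard_normal(n)
            if measure in BONE_MEASURES:
                z = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * eps
            else:
                z = eps
            cols[measure] = mean + sd * z
        sex = np.where(rng.random(n) < spec.women_fraction[group], "F", "M")
        frames.append(
            pd.DataFrame(
                {
                    "id": np.arange(pid, pid + n),
                    "fracture": fracture,
                    "sex": sex,
                    **cols,
                }
            )
        )
        pid += n
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Exclusion roster

#: Patient-selection cascade, in the order it was applied: criterion
#: name -> number of patients removed, starting from 360 with DXA and
#: CT available. The coverage criterion applies to non-fractured
#: patients only, after fracture screening of the remaining 258.
DEFAULT_CASCADE: tuple[tuple[str, int], ...] = (
    ("metastasis_hematologic", 18),
    ("no_assessable_dxa", 34),
    ("no_assessable_ct", 15),
    ("age_below_50", 35),
    ("insufficient_coverage_nonfractured", 66),
)

DEFAULT_INITIAL = 360
DEFAULT_FRACTURED_FINAL = 148


def build_exclusion_roster(
    cascade: tuple[tuple[str, int], ...] = DEFAULT_CASCADE,
    initial: int = DEFAULT_INITIAL,
    fractured_final: int = DEFAULT_FRACTURED_FINAL,
) -> pd.DataFrame:
    """Construct a patient roster carrying mutually exclusive exclusion flags.

    Returns a table of ``initial`` patients with columns ``id``,
    ``exclusion_reason`` (empty string for analysed patients) and
    ``fracture``.  Flags follow the cascade order, each patient removed
    at most once; patients flagged for insufficient spine coverage are
    non-fractured by construction.
    """
    if any(count < 0 for _, count in cascade):
        raise RosterError("exclusion counts must be non-negative")
    total_excluded = sum(count for _, count in cascade)
    if total_excluded > initial:
        raise RosterError(
            f"cascade removes {total_excluded} patients from a pool of {initial}"
        )
    analyzed = initial - total_excluded
    if fractured_final > analyzed:
        raise RosterError(
            f"{fractured_final} fractured patients exceed the {analyzed} analysed"
        )
    reason = np.full(initial, "", dtype=object)
    fracture = np.zeros(initial, dtype=bool)
    pos = 0
    for criterion, count in cascade:
        reason[pos : pos + count] = criterion
        pos += count
    fracture[pos : pos + fractured_final] = True
    return pd.DataFrame(
        {"id": np.arange(1, initial + 1), "exclusion_reason": reason, "fracture": fracture}
    )
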