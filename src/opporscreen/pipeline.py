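"""End-to-end orchestration: exclusions, measurement, statistics, thresholds.

The full analysis reads (or simulates) a patient roster, applies the
selection cascade, extracts calibrated bone measures from each
volume/mask pair, assembles the cohort table, runs the
fracture-association statistics and derives transferred diagnostic
thresholds. Every stage is also callable on its own, and a run is
deterministic given its seed: result files are byte-identical across
repeated runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import DEFAULT_CALIBRATION, CalibrationConfig, calibrate_volume, load_calibration
from .cohorts import (
    BONE_MEASURES,
    DEFAULT_CASCADE,
    CohortSpec,
    build_exclusion_roster,
    generate_cohort,
)
from .errors import ConfigError, DataError, EmptyRegionError, SeparationError
from .image import AREAL_LEVELS, VOLUMETRIC_LEVELS
from .measures import DEFAULT_EROSION_MM, aggregate_patient, measure_level, separate_body
from .phantoms import PhantomSpec, generate_phantom
from .stats import delong_test, group_compare, logistic_or, roc_auc, standardize
from .thresholds import ACR_TRABECULAR, transfer_bands
from .virtual_dxa import patient_ct_abmd

#: Measures entering the image-derived cohort.
IMAGE_MEASURES = ("trabecular_vbmd", "integral_vbmd", "bmc", "ct_abmd")


@dataclass
class ExclusionCascade:
    """Ordered patient-selection criteria with expected removal counts."""

    criteria: tuple[tuple[str, int], ...] = DEFAULT_CASCADE

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.criteria)


def apply_exclusions(
    roster: pd.DataFrame, cascade: ExclusionCascade | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the selection cascade; return analysed cohort and audit trail.

    The audit trail records, per criterion in order, the number
    removed and the running pool size; analysed + total removed equals
    the initial roster size.
    """
    cascade = cascade or ExclusionCascade()
    if "exclusion_reason" not in roster.columns:
        raise DataError("roster lacks an exclusion_reason column")
    known = set(cascade.names) | {""}
    stray = set(roster["exclusion_reason"].unique()) - known
    if stray:
        raise DataError(f"roster carries flags outside the cascade: {sorted(stray)}")
    remaining = roster
    audit = []
    for criterion in cascade.names:
        hit = remaining["exclusion_reason"] == criterion
        remaining = remaining[~hit]
        audit.append(
            {"criterion": criterion, "removed": int(hit.sum()), "remaining": int(len(remaining))}
        )
    return remaining.reset_index(drop=True), audit


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    n_patients: int = 20
    fractured_fraction: float = 148 / 192
    calibration_path: str | None = None
    erosion_mm: float = DEFAULT_EROSION_MM
    volumetric_levels: tuple[str, ...] = VOLUMETRIC_LEVELS
    areal_levels: tuple[str, ...] = AREAL_LEVELS
    adjust: tuple[str, ...] = ("age", "sex")
    noise_sd: float = 8.0
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    correlation: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"run config not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        stray = set(raw) - valid
        if stray:
            raise ConfigError(f"unknown config keys: {sorted(stray)}")
        for key in ("volumetric_levels", "areal_levels", "adjust", "spacing_mm"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def load_calibration(self) -> CalibrationConfig:
        if self.calibration_path is None:
            return DEFAULT_CALIBRATION
        return load_calibration(self.calibration_path)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV with exact float round-trip.

    Pipeline outputs are written with full precision; reading them back
    this way reproduces bit-identical statistics (stage isolation).
    """
    return pd.read_csv(path, float_precision="round_trip")


def measure_patient_volume(
    volume,
    mask,
    calibration: CalibrationConfig = DEFAULT_CALIBRATION,
    erosion_mm: float = DEFAULT_EROSION_MM,
    volumetric_levels: tuple[str, ...] = VOLUMETRIC_LEVELS,
    areal_levels: tuple[str, ...] = AREAL_LEVELS,
) -> dict:
    """Calibrate one scan and reduce it to patient-level measures."""
    bmd = calibrate_volume(volume, calibration)
    per_level = [
        measure_level(bmd, mask, lv, volume.spacing_mm, erosion_mm)
        for lv in mask.levels
        if lv in volumetric_levels
    ]
    patient = aggregate_patient(per_level, volumetric_levels)
    body_masks = {
        lv: separate_body(mask, lv) for lv in mask.levels if lv in areal_levels
    }
    try:
        patient["ct_abmd"] = patient_ct_abmd(bmd, body_masks, volume.spacing_mm)
    except EmptyRegionError:
        patient["ct_abmd"] = np.nan
    patient["per_level"] = per_level
    return patient


def simulate_imaging_cohort(config: RunConfig) -> pd.DataFrame:
    """Simulate patients as digital phantoms and measure them.

    Draws per-patient ground-truth trabecular density (and DXA
    covariates) from the two-group cohort model, renders one phantom
    per patient — fractured patients get a grade-2 wedge at L1 — and
    runs the full calibration/measurement chain on the images. The
    returned table mixes image-derived measures with the drawn
    demographic and DXA columns.
    """
    n_frac = max(2, round(config.n_patients * config.fractured_fraction))
    n_non = max(2, config.n_patients - n_frac)
    spec = CohortSpec(
        n_fractured=n_frac,
        n_nonfractured=n_non,
        correlation=config.correlation,
        seed=config.seed,
    )
    drawn = generate_cohort(spec)
    calibration = config.load_calibration()
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for _, patient in drawn.iterrows():
        trab = float(max(10.0, patient["trabecular_vbmd"]))
        pspec = PhantomSpec(
            levels=("T12", "L1", "L2", "L3", "L4"),
            trabecular_density=trab,
            cortical_density=trab + 260.0,
            noise_sd=config.noise_sd,
            spacing_mm=config.spacing_mm,
            fracture_height_loss={"L1": 0.3} if patient["fracture"] else {},
            seed=int(rng.integers(2**31)),
        )
        volume, mask, truth = generate_phantom(pspec, calibration)
        measured = measure_patient_volume(
            volume,
            mask,
            calibration,
            config.erosion_mm,
            config.volumetric_levels,
            config.areal_levels,
        )
        rows.append(
            {
                "id": int(patient["id"]),
                "fracture": truth.fractured,
                "sex": patient["sex"],
                "age": patient["age"],
                "dxa_tscore": patient["dxa_tscore"],
                "dxa_abmd": patient["dxa_abmd"],
                "trabecular_vbmd": measured["trabecular_vbmd"],
                "integral_vbmd": measured["integral_vbmd"],
                "bmc": measured["bmc"],
                "ct_abmd": measured["ct_abmd"],
                "n_levels": measured["n_levels"],
            }
        )
    return pd.DataFrame(rows)


def stage_stats(cohort: pd.DataFrame, adjust: tuple[str, ...] = ("age", "sex")) -> dict:
    """Association statistics on an assembled cohort table.

    Returns Table 1/2/3-shaped frames: group comparison, crude and
    adjusted per-SD odds ratios, and ROC AUCs with DeLong comparisons
    against DXA aBMD.
    """
    measures = [m for m in ("age",) + BONE_MEASURES if m in cohort.columns]
    bone = [m for m in BONE_MEASURES if m in cohort.columns]
    table1 = group_compare(cohort, tuple(measures))

    outcome = cohort["fracture"].to_numpy(bool)
    or_rows = []
    for measure in bone:
        z = standardize(cohort[measure], risk_direction="lower")
        for adjusted in (False, True):
            cov = cohort[list(adjust)] if adjusted and adjust else None
            try:
                res = logistic_or(outcome, z, cov)
                or_rows.append(
                    {
                        "measure": measure,
                        "adjusted": adjusted,
                        "odds_ratio": res.odds_ratio,
                        "ci_low": res.ci[0],
                        "ci_high": res.ci[1],
                        "p": res.p,
                    }
                )
            except SeparationError:
                or_rows.append(
                    {
                        "measure": measure,
                        "adjusted": adjusted,
                        "odds_ratio": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p": np.nan,
                    }
                )
    table2 = pd.DataFrame(or_rows)

    scores = {m: standardize(cohort[m], risk_direction="lower") for m in bone}
    auc_rows = []
    for measure in bone:
        curve = roc_auc(outcome, scores[measure])
        row = {
            "measure": measure,
            "auc": curve.auc,
            "ci_low": curve.ci[0],
            "ci_high": curve.ci[1],
        }
        if "dxa_abmd" in scores and measure != "dxa_abmd":
            row["p_vs_dxa_abmd"] = delong_test(outcome, scores[measure], scores["dxa_abmd"])["p"]
        auc_rows.append(row)
    table3 = pd.DataFrame(auc_rows)
    return {"table1": table1, "table2": table2, "table3": table3}


def stage_thresholds(cohort: pd.DataFrame) -> dict:
    """Transfer the trabecular reference bands onto integral vBMD."""
    bands, results = transfer_bands(
        cohort["fracture"].to_numpy(bool),
        cohort["trabecular_vbmd"].to_numpy(float),
        cohort["integral_vbmd"].to_numpy(float),
        reference=ACR_TRABECULAR,
    )
    return {
        "reference": {
            "measure": ACR_TRABECULAR.measure,
            "osteoporosis_cutoff": ACR_TRABECULAR.osteoporosis_cutoff,
            "low_bone_mass_cutoff": ACR_TRABECULAR.low_bone_mass_cutoff,
        },
        "transferred": {
            "measure": bands.measure,
            "osteoporosis_cutoff": bands.osteoporosis_cutoff,
            "low_bone_mass_cutoff": bands.low_bone_mass_cutoff,
            "matched_points": {
                name: {
                    "cutoff": res.cutoff,
                    "cutoff_unrounded": res.cutoff_unrounded,
                    "sensitivity": res.matched_point[0],
                    "specificity": res.matched_point[1],
                    "reference_sensitivity": res.reference_point[0],
                    "reference_specificity": res.reference_point[1],
                }
                for name, res in results.items()
            },
        },
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the results bundle.

    Writes ``cohort.csv``, ``table1.csv``, ``table2.csv``,
    ``table3.csv``, ``thresholds.json``, ``audit.json`` and
    ``run.json`` (package version, config hash, seed) into
    ``config.out_dir``. Deterministic given the seed.
    """
    calibration = config.load_calibration()  # fail fast on bad config
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    roster = build_exclusion_roster()
    analyzed, audit = apply_exclusions(roster)

    cohort = simulate_imaging_cohort(config)
    results = stage_stats(cohort, config.adjust)
    thresholds = stage_thresholds(cohort)

    # %.17g round-trips float64 exactly: reloading the CSV reproduces
    # bit-identical statistics (stage isolation)
    cohort.to_csv(out / "cohort.csv", index=False, float_format="%.17g")
    results["table1"].to_csv(out / "table1.csv", index=False)
    results["table2"].to_csv(out / "table2.csv", index=False)
    results["table3"].to_csv(out / "table3.csv", index=False)
    (out / "thresholds.json").write_text(json.dumps(thresholds, indent=1, sort_keys=True))
    (out / "audit.json").write_text(
        json.dumps({"initial": len(roster), "audit": audit, "analyzed": len(analyzed)}, indent=1)
    )
    (out / "run.json").write_text(
        json.dumps(
            {
                "version": __version__,
                "config_hash": config.digest(),
                "seed": config.seed,
                "n_scanners": len(calibration.scanners),
            },
            indent=1,
            sort_keys=True,
        )
    )
    return {
        "cohort": cohort,
        "audit": audit,
        "analyzed_roster": analyzed,
        "thresholds": thresholds,
        **results,
    }
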