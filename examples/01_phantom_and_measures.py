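"""Build a digital vertebra phantom and extract its bone measures.

A noiseless phantom makes the whole chain auditable: the attenuation
is synthesised by inverting the calibration, so the measured densities
must equal the ground truth exactly.
"""

from opporscreen import PhantomSpec, calibrate_volume, generate_phantom
from opporscreen.measures import aggregate_patient, measure_level

spec = PhantomSpec(
    levels=("T12", "L1", "L2", "L3", "L4"),
    trabecular_density=100.0,  # mg/cm^3, ground truth
    cortical_density=400.0,
    shell_thickness_mm=3.0,
    noise_sd=0.0,
    seed=0,
)
volume, mask, truth = generate_phantom(spec)
print(f"phantom grid {volume.data.shape}, spacing {volume.spacing_mm} mm")

bmd = calibrate_volume(volume)  # HU -> mg/cm^3, contrast-corrected
per_level = [measure_level(bmd, mask, lv, volume.spacing_mm) for lv in mask.levels]
for lm in per_level:
    t = truth.per_level[lm.level]
    print(
        f"{lm.level}: trabecular {lm.trabecular_vbmd:7.2f} (truth {t.trabecular_vbmd:.2f}) "
        f"integral {lm.integral_vbmd:7.2f} (truth {t.integral_vbmd:.2f}) "
        f"BMC {lm.bmc:.3f} g"
    )

patient = aggregate_patient(per_level)
print(
    f"patient mean over {patient['n_levels']} levels: "
    f"trabecular {patient['trabecular_vbmd']:.2f} mg/cm^3, "
    f"integral {patient['integral_vbmd']:.2f} mg/cm^3, BMC {patient['bmc']:.3f} g"
)
# Trabecular vBMD recovers the 100 mg/cm^3 truth exactly: the 5 mm
# erosion removes the 3 mm cortical shell before sampling. Integral
# vBMD is higher because it includes that dense shell.
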