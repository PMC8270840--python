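# Methods

## Scope and model

The package analyses opportunistic CT for osteoporosis screening: it
converts attenuation to volumetric bone mineral density, reduces
labelled vertebral masks to compartment measures, renders virtual DXA
projections, and relates all measures to prevalent vertebral fracture
status. Segmentation itself is out of scope — masks are an input (the
phantom generator produces them); so are scanner physics, DICOM
ingestion and incident-fracture (prospective) modelling.

All modules share one axis convention: axis 0 left–right, axis 1
anterior–posterior (index grows towards posterior), axis 2
inferior–superior; voxel spacing is anisotropic, in millimetres.

## Calibration

Asynchronous quantitative CT calibrates each scanner/protocol with a
phantom scanned separately from the patient, giving a linear map
`vBMD = a·HU + b` (a > 0). Intravenous contrast biases attenuation;
a linear per-phase correction (`arterial`, `portal_venous`) is applied
*after* calibration and *before* any measurement. Order matters: two
affine maps only commute in special cases, and a test asserts the
pipeline uses the stated order. Calibrations are keyed per scanner at
120 kVp; other tube voltages are rejected as uncalibrated, mirroring
the exclusion of non-120 kVp scans from the screening population.
Shipped coefficients are synthetic placeholders (clinical coefficients
are scanner-specific and not public); real deployments supply a
JSON/YAML config.

## Volumetric measures

* **Body separation.** When the mask labels subregions, the body label
  is used directly. For unpartitioned vertebrae a geometric heuristic
  stands in for template registration: the voxel-count profile along
  the anterior–posterior axis has a dominant anterior mode (the body)
  and a smaller posterior mode (posterior elements); the cut plane is
  the profile minimum between them, accepted only if the valley drops
  below half the main peak. On phantoms this recovers the body at
  Dice ≥ 0.95.
* **Metric erosion.** The trabecular compartment is the set of body
  voxels whose Euclidean distance to the mask complement, computed by
  a distance transform with physical spacing, strictly exceeds the
  erosion distance (default 5 mm). The distance is physical, not a
  voxel count, because clinical reformats have 0.9–3 mm slices.
  Erosion is applied in 3-D (slice-wise application is a plausible
  alternative; 3-D was chosen and is flagged here). Distances are
  voxel-centre to voxel-centre; the unit tests pin this convention
  against a brute-force all-pairs oracle. A level whose compartment
  empties under erosion becomes non-evaluable rather than an error.
* **Measures.** Trabecular vBMD is the mean calibrated density over
  the eroded compartment; integral vBMD the mean over the whole body;
  BMC is density × voxel volume summed (mg→g), so BMC ≡ integral vBMD
  × volume / 1000 identically. Voxel volume is the product of spacing
  components; no partial-volume modelling at mask boundaries. Patient
  values are unweighted means over evaluable, non-excluded levels
  T12–L4 (levels may be excluded for fracture, degeneration or other
  abnormality).

## Virtual DXA

Areal BMD is obtained by parallel projection of the masked density
field along the anterior–posterior axis: per projection pixel,
`aBMD = Σ density·Δy · 10⁻⁴` (mg/cm³·mm → g/cm²). Parallel,
monoenergetic projection conserves mass exactly (areal integral =
BMC), which the tests exploit as an oracle; divergent-beam geometry is
deliberately not modelled. Only body masks are projected, so lateral
processes are excluded by construction, and the sampling region is the
projection footprint rather than a fitted contour. Patient aBMD is
computed per level (L1–L4) and then averaged — pooling all footprint
pixels would weight levels by area instead. T-scores use a
configurable young-adult reference (default mean 1.18, SD 0.12 g/cm²,
a synthetic placeholder; vendor references are proprietary), with the
usual bands: T ≤ −2.5 osteoporosis, −2.5 < T ≤ −1 low bone mass.

## Statistics

Bone measures are standardised with the whole-cohort SD and *negated*,
so odds ratios and AUCs read "per SD decrease" and are > 1 / > 0.5 for
protective measures. Logistic fits use maximum likelihood
(statsmodels) with Wald 95% CIs — the standard for the reported
format; perfect separation is flagged, not estimated. The empirical
AUC equals the Mann–Whitney concordance probability with ties counted
½; its variance and the paired test for two correlated ROC curves use
DeLong's structural components (placement values per positive and
negative subject, jackknife-style covariance). ROC thresholds sit at
midpoints between adjacent distinct scores. Group descriptives use a
pooled-variance two-sample t test and a chi-squared test of
independence for sex; agreement uses Bland–Altman bias ± 1.96 SD and
least-squares R². Significance is two-sided at 0.05 with no
multiplicity correction.

## Threshold transfer

Accepted trabecular-vBMD bands (osteoporosis < 80 mg/cm³; low bone
mass 80 ≤ v ≤ 120, upper bound inclusive) are transferred to another
measure by ROC-point matching: compute the reference cutoff's
(sensitivity, specificity) on the cohort, enumerate every realisable
operating point of the target measure, and take the point at minimal
Euclidean distance with both axes on [0, 1]. Ties go to the
higher-specificity point (a screening context favours fewer false
positives); the rule is configurable. The cutoff realising the chosen
split is placed between its bracketing target values by linear
interpolation at the same relative position the reference cutoff
occupies between *its* bracketing values — this makes identity
transfer exact and maps affine target relations through exactly —
then rounded half-away-from-zero to 5 mg/cm³. Rounding follows
matching, so the reported operating point belongs to the unrounded
threshold. Transferred bands are half-open (osteoporosis < low edge ≤
low bone mass < high edge), while the trabecular reference keeps its
inclusive upper bound; both conventions are preserved per measure.

## Synthetic data

* **Phantoms** are stacks of vertebra-like bodies: superellipsoidal
  cross-section (exponent 2.5) extruded along the IS axis, a cortical
  shell carved as the layer within the shell thickness of the body
  surface, a posterior-elements block, soft-tissue background,
  optional Gaussian HU noise, and optional anterior wedge deformities
  (local height reduced linearly towards the anterior edge). Genant
  grades follow the conventional height-loss bands: < 20 % grade 0,
  20–25 % grade 1, 25–40 % grade 2, > 40 % grade 3; a patient is
  fractured if any level reaches grade ≥ 1. Attenuation is synthesised
  by inverting the calibration (and, for enhanced phases, the contrast
  correction), so the noiseless measurement chain recovers ground
  truth to machine precision — a closure property, not a claim of
  realism. Defaults: body 34×28×27 mm, 3 mm shell, trabecular
  100 mg/cm³, cortical 400, posterior 300, background 30, 1 mm
  isotropic spacing.
* **Cohorts** model each fracture group as Gaussian per measure with
  the published group means/SDs (44 non-fractured / 148 fractured;
  women 34/44 and 107/148). A single latent standard-normal factor
  with loading √ρ induces pairwise correlation ρ between the bone
  measures of one subject; ρ defaults to 0.5, chosen once as a
  realistic positive cross-correlation — the study does not report
  inter-measure correlations, so ρ is a simulation parameter, not an
  estimate. Age loads zero on the factor because the within-group
  age–BMD dependence is likewise unknown.

What passing tests show, and what they do not: the phantoms exercise
the geometry and unit bookkeeping of erosion, projection and
aggregation exactly, but contain no trabecular microstructure, beam
hardening, scatter, metal or motion artefacts; the cohorts reproduce
first and second moments and a homogeneous correlation, not the tail
behaviour or covariate structure of a clinical population. Agreement
on synthetic data therefore validates the computation, not clinical
performance.

## Numerical choices and problem sizes

Seeded `numpy` generators make every simulation bit-reproducible;
pipeline result files are byte-identical across repeated runs, and
cohort CSVs are written at full float precision so that re-running
only the statistics stage on saved output reproduces identical
numbers. Degenerate inputs fail loud and typed: zero-variance
predictors, single-class outcomes, constant transfer targets, empty
masks and inconsistent exclusion rosters raise specific errors (the
CLI maps configuration errors to exit 2, data errors to exit 3). The
test suite uses phantoms of ≲ 3·10⁵ voxels, 100-seed noise-recovery
batches, 200-cohort AUC averages, 500-cohort CI-coverage runs and
10⁴-replicate bootstrap oracles — sizes at which the Monte-Carlo error
of each check is far below its assertion tolerance.

## Known limitations

Body/posterior separation for unpartitioned masks is a geometric
heuristic, not the registration-based separation used with clinical
segmentations. The erosion convention at voxel resolution makes
compartment membership depend on voxel-centre distances, so very
coarse spacing biases small compartments. Virtual DXA is monoenergetic
and parallel; it cannot reproduce DXA's energy-dependent soft-tissue
compensation. Exclusion handling models the published cascade's
bookkeeping, not the radiological judgements behind it.
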