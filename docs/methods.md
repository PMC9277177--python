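# Methods

## Pipeline model

`sciquant` operationalises a semi-automated workflow for quantifying
silent cerebral infarction (SCI) from co-registered FLAIR and T1
volumes. The package assumes preprocessing is done: volumes are
bias-corrected, affine-aligned onto one voxel grid, and accompanied by
binary masks of cortex, white matter and ventricles plus candidate
lesion ROIs (a neuroradiologist's identifications, or the phantom
generator's). Everything downstream of those inputs is automated and
deterministic.

### Intensity thresholds

The lesion criterion is relative, not absolute: a voxel inside a
candidate ROI belongs to the lesion if its FLAIR intensity is at or
above `1.02 ×` the participant's mean cortical FLAIR intensity, and to
the T1-surviving subset if additionally its T1 intensity is at or below
`1.02 ×` the mean cortical T1 intensity. Referencing cortex makes the
threshold robust to scanner scaling; the multiplier is configurable and
recorded with every run. Comparisons are inclusive (≥ / ≤): strictness
at the boundary is not specified by the criterion itself, and the
inclusive choice keeps the boundary voxel in the mask while remaining
auditable via the multiplier. The T1 criterion is evaluated only within
FLAIR-surviving voxels, so T1 hypo-intensities outside the FLAIR mask
are never captured — a deliberate property of the threshold order.
Connected components (26-connectivity by default; 6 and 18 available)
are computed for diagnostics, but all components within one ROI are
merged into a single lesion mask so masks map one-to-one to identified
lesions. A lesion needs ≥ 1 surviving voxel by default (`min_voxels`
exposes the cut).

### Greatest dimension and definitions

Greatest dimension is a caliper (edge-to-edge) measurement: the maximum
Euclidean distance over the corner vertices of the lesion's voxels.
Centre-to-centre distances would systematically shrink lesions by about
one voxel and flip 3 mm boundary cases; the corner-vertex rule mirrors
an on-screen manual measurement. The default mode measures within
single coronal slices (through-slice extent projected out, matching the
plane manual measurements are made in) and takes the maximum over
slices; a full-3D mode is available and is never smaller. The three
definitions are nested: liberal (any surviving voxels), traditional
(liberal and dimension ≥ 3.0 mm inclusive), restrictive (traditional
and ≥ 1 T1-surviving voxel). Restrictive *volume* sums T1-surviving
voxels — the only reading consistent with restrictive volumes being an
order of magnitude below traditional ones. Raw voxel counts are
reported alongside mm³ volumes for auditability. The per-decade burden
rule counts the current, partially-elapsed decade: `decades =
floor(age/10) + 1`, abnormal when `n_lesions > decades`; the arithmetic
is configurable because "per decade of life" admits alternatives.

### Regional parcellation

Absolute-distance rules (e.g. 10 mm periventricular bands) derive from
older adults; in a paediatric/young-adult sample the package instead
partitions each participant's white matter by percentile thresholds on
Euclidean distance maps, computed with anisotropic voxel sampling in
mm. Periventricular = white-matter voxels with ventricle distance at or
below the 5th percentile of that distance over white matter;
juxta-cortical = of the remaining white matter, voxels with cortex
distance at or below the 75th percentile over the remaining white
matter; deep = the rest. The juxta-cortical quantile is computed after
periventricular exclusion (the stated exclusion order); a flag switches
to all-white-matter quantiles for sensitivity analysis. Both
percentiles are configurable — note the 75th-percentile juxta-cortical
rule deliberately makes juxta-cortical the largest band. Lesions take
the region with the strict maximum voxel overlap; exact ties are
returned as ties (the source workflow escalated such cases, three in
its sample, to the neuroradiologist) and can be resolved via a
`tie_resolutions` mapping. Regional volumes allow within-lesion overlap
between regions and sum to the lesion's white-matter volume. The
bullseye crosses the 3 regions with 4 lobes (lobe labels travel with
the ROI; no atlas-based lobar segmentation is attempted) and reports
three group metrics: percent of participants with lesion voxels per
zone, percent of lesion count, and percent of lesion volume.

## Synthetic phantoms

Phantoms emulate the geometry and contrast the pipeline depends on and
nothing more: nested ellipsoids (brain, cortical ribbon of 3 mm, white
matter, central ventricles) on a 96³ grid of 0.65 × 0.65 × 1.0 mm
voxels, piecewise-constant tissue intensities (FLAIR cortex 100 / WM 80
/ CSF 25; T1 cortex 100 / WM 130 / CSF 40, arbitrary units), and
spherical lesions that set FLAIR to `flair_multiplier ×` the cortical
FLAIR base and T1 to `t1_multiplier ×` the cortical T1 base. The lesion
profile is a uniform plateau by default so threshold behaviour is
analytically predictable (a 1.5 multiplier survives a 1.02 threshold on
a noise-free phantom by construction; 1.01 cannot); a smooth-edge
option exists. Gaussian noise (default 0) can be added to both
modalities. Each lesion yields a candidate ROI (bounding box dilated by
2 voxels) and a realised ground-truth record: voxel set, caliper
diameter, expected definition flags and region. Lobes are assigned by
anterior/posterior × superior/inferior quadrant of the white-matter
bounding box, standing in for the radiologist's label.

Lesion placement (`sample_truth_lesions`) guarantees unambiguous
regional ground truth: centres are drawn as deep inside the requested
band as geometry allows (preferring full containment with a 2 mm
margin), and every placement is verified to give the intended region a
strict majority of the realised voxel set. The periventricular band —
5% of white matter — is thinner than a ≥ 3 mm lesion plus margin, so
periventricular lesions may spill into neighbouring bands; the majority
check keeps their assignment exact nonetheless. Overlapping lesions or
ROIs are rejected: phantoms must have separable ground truth.

What phantoms do *not* emulate: realistic anatomy, partial-volume
ramps, bias fields, registration error, or lesion-shaped mimics
(perivascular spaces). Passing recovery tests therefore demonstrates
correctness of the thresholding/measurement/assignment logic under the
stated geometry, not segmentation performance on clinical images.

## Synthetic cohorts

The cohort generator reproduces the statistical structure the battery
assumes, with defaults fixed to the study sample: 106 patients and 48
controls; nested prevalences 45/42/25 of 106 and 11/5/2 of 48; IQ/WMI/
PSI means (SDs) of 93.15 (13.28) / 92.04 (14.18) / 89.56 (12.99) in
patients and 97.29 (11.78) / 98.90 (13.34) / 97.10 (13.03) in controls.
The status triple is drawn from a single uniform per subject, making
nesting a construction rather than a constraint to check. Lesion count
given presence is zero-truncated negative binomial (means 6 / 3 for
patients / controls, dispersion 1.2) and liberal volume is log-normal
(medians 75 / 22 mm³, log-SD 1.5), chosen to bracket the reported
medians and ranges of right-skewed metrics analysed on a log scale;
traditional/restrictive counts and volumes are nested thinnings.
Covariates (age uniform 8-30, sex, SpO2, hemoglobin, education decile,
intracranial volume) are drawn per group; hemoglobin exists only for
patients. Missingness mirrors the imputation step: 4/106 of patient
hemoglobin and 7/48 of control SpO2. An optional per-outcome
`lesion_effect` adds `β × log1p(liberal volume)` to the scores; the
default 0 is the no-association null. The generator draws covariates
independently of lesion status within group, so it does not emulate
the reported SpO2-lesion correlations; null-calibration results are
therefore clean by design. Scores are kept continuous (not rounded to
integer index scores).

## Statistics: formulas and conventions

* Cochran's Q: `Q = (k−1)(k ΣCj² − N²) / (k ΣRi − Ri²-sum)` with df
  k−1; all-constant matrices return Q = 0, p = 1. At k = 2 this is the
  uncorrected McNemar statistic.
* Friedman via average-rank ties (scipy), Kendall's W = Q / (n(k−1)).
* 2×2 chi-square uses the Yates continuity correction by default
  (required to reproduce the published between-group statistic from its
  printed counts); φ = √(X²/N).
* Fisher's exact test reports the *conditional* maximum-likelihood odds
  ratio under the noncentral hypergeometric model — the estimator
  printed by exact-test software, and the one that matches the
  published value (7.03, where the sample cross-product ratio is 7.10).
  Boundary tables (a zero cell) have an unbounded estimate, reported as
  NaN with a flag.
* Mann-Whitney U reports r = |Z|/√N from the tie-corrected normal
  approximation; an exact-enumeration p is available for small
  samples.
* Cohen's d uses the pooled SD. Welch's t and df for mean comparisons.
* Spearman screens use pairwise-complete cases and flag p < 0.05
  uncorrected; no multiple-comparison correction is applied anywhere by
  default, deliberately maximising sensitivity to lesion effects.
* Missing hemoglobin/SpO2 are imputed with the observed group mean
  before model fitting; the imputation count is returned.

The regression ladder fits, per outcome × definition: (1) presence
indicator; (2) + indicator × mean-centred group; (3) + log1p count;
(4) + both interactions; (5) + log1p volume; (6) + both interactions —
always alongside age, sex, intracranial volume, SpO2 and education
decile, plus the group indicator in whole-sample runs and hemoglobin
(minus the group terms) in patient-only runs. Count/volume enter as
log1p because zeros are ubiquitous. OLS serves continuous outcomes and
logistic regression the impairment indicator (any of IQ/WMI/PSI < 70);
separation or singular designs are reported as model errors rather than
raised. Variance inflation factors are computed for the lesion terms;
presence indicators with VIF > 5 are dropped (logged in the report)
when a continuous quantifier remains — with log-volume and presence
being near-collinear by construction, this rule fires routinely in
models 5-6, as intended. Semi-partial correlations for lesion terms are
`t √((1−R²)/df_resid)`.

## Numerical choices and problem sizes

Quantiles use numpy's default linear interpolation; the parcellation
size invariant is asserted to within the rank granularity of tied
distances at the cut. Distance transforms use `scipy.ndimage`'s exact
Euclidean EDT with per-axis sampling. Caliper measurements switch to a
convex hull above 400 corner points (exact either way). Determinism:
every stochastic component takes a `numpy.random.default_rng` seed;
identical seed + spec gives bit-identical volumes and tables.

The test suite exercises recovery on 50 randomised noise-free phantoms
at 96³ (three lesions each, spanning both sides of the 3 mm boundary,
both T1 classes and all three regions), null calibration on 2,000
simulated cohorts of 154 subjects (Model-1 type-I error within the
binomial 95% band around α = 0.05), and effect recovery of a −5
point-per-log-unit volume effect over 500 cohorts of 500 subjects —
sizes chosen to give tight Monte-Carlo error at interactive runtimes.

## Known limitations

* The maximum-corrected Cochran effect size printed alongside published
  Q values has no recoverable formula and is not implemented.
* Candidate ROIs are required inputs; the package does not detect
  lesions de novo, exclude mimics, or segment lobes.
* The restrictive definition requires only ≥ 1 T1-surviving voxel; no
  minimum size is imposed on the T1-surviving cluster itself.
* A single shared threshold multiplier couples the FLAIR and T1
  criteria: raising it tightens the FLAIR criterion but loosens the T1
  one, so only FLAIR-derived volumes are monotone in the multiplier.
* Phantom and cohort realism limits are described above; conclusions
  about clinical images or real cohorts require real data.
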