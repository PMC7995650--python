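# Methods

This note documents the models and procedures implemented by
`wmh-subclass`, the assumptions behind them, the tunable parameters, and
what the synthetic phantoms do and do not establish about real data.

## The sub-classification model

White matter hyperintensities (WMHs) are bright regions on FLAIR MRI and
a radiological hallmark of cerebral small vessel disease. The package
sub-classifies a binary WMH mask along two independent axes and reports
the resulting four classes.

**Intensity axis (voxel-level).** A WMH voxel counts as *non*
T1-hypointense when the white-matter partial volume estimate (PVE) from
tissue segmentation exceeds 0.5 at that voxel; the remaining WMH voxels
are T1-hypointense. The PVE acts as a proxy for T1 signal: segmentation
assigns dark lesion tissue mostly to grey matter or CSF, pulling its
white-matter PVE to 0.5 or below. The boundary value (PVE exactly 0.5)
falls in the hypointense class because the rule is a strict inequality;
the threshold is configurable for sensitivity analyses.

**Location axis (cluster-level).** WMH voxels are grouped into 3D
connected components ("clusters") under a chosen voxel connectivity. A
cluster is *periventricular* iff at least one of its voxels overlaps an
extended ventricle mask (lateral ventricles, thalami and fornix,
thresholded at a very low probability); otherwise it is *deep*. One
overlapping voxel suffices. Location is constant within a cluster;
intensity may vary within a cluster.

Combining the axes yields four voxel codes: periventricular hypointense
(1), periventricular non-hypointense (2), deep hypointense (3), deep
non-hypointense (4). The four classes partition the WMH mask exactly —
an integer identity asserted on every run, not a tolerance check.

**Rim/core decomposition.** Clusters are split into those containing at
least one hypointense voxel and those containing none. Within a
hypointense-containing cluster, the hypointense voxels form the *core*
and the remaining voxels the *rim*. Two identities follow from the
definitions and are verified at voxel-count level on every run:

* non-hypointense volume = volume of clusters without hypointense
  voxels + rim volume;
* hypointense volume = core volume.

## Volumetrics and DTI summaries

Volumes are voxel counts times voxel volume, reported in cm³, then
*adjusted* by dividing by total brain volume (a dimensionless ratio,
both in cm³) and log transformed. Natural log is the default; the base
affects regression coefficients but not their p-values, and the base
used is recorded in output metadata. Adjustment by ratio was chosen over
residualisation as the simplest defensible reading; residual-based
normalisation is out of scope. Empty classes are handled by a
`zero_policy`: `missing` (default — the class is flagged and excluded
from models using it), `epsilon` (one voxel volume substituted before
the ratio), or `error`.

DTI metrics (FA, and MD/AD/RD in mm²/s × 10⁻³) are averaged within a
mask over voxels with finite values, one value per subject per mask.
Subject-level means of means (not voxel-weighted pooling) feed the
across-subject paired t-test, matching the paired design. An empty mask
yields a missing value, never zero.

## Cognitive-association models

One ordinary-least-squares model per cognitive outcome, with
demographic covariates (age, sex, years of education, systolic and
diastolic blood pressure) plus either the log-adjusted total WMH volume
or the four log-adjusted sub-class volumes simultaneously. Per-term
significance uses Type III sums of squares, i.e. the full model is
compared against the model with that single term removed. With only
continuous covariates and a single two-level factor, the Type III F is
exactly the drop-one-term F, and for a one-column term equals the
squared t of its coefficient.

Numerically, the drop-term sum of squares is computed through a QR
factorisation with the dropped column permuted last, so it is obtained
as a single projection rather than a cancellation-prone subtraction of
two large residual sums; this keeps agreement with the
general-linear-hypothesis formula at the 1e-12 level even for terms with
F near zero. Sex is coded 0/1 (reference: the female-like level when
level names identify one); with a single two-level factor and no
interactions the coding does not affect the F tests. Missing data are
handled by listwise deletion per model, with the n used reported. The
Bonferroni family size defaults to the number of outcomes actually
modelled and is configurable, since the appropriate family depends on
the battery a user runs. Rank-deficient designs and constant outcomes
are errors, not silent drops. A residual sum of squares below 1e-12 of
the outcome's total variation is treated as a perfect fit (overall F
reported as infinite with p = 0) — this only arises for exactly linear
outcomes.

## The phantom generator

Phantoms exist so that every stage is testable against a known ground
truth without any imaging data. A subject is:

* an ellipsoidal brain and two ellipsoidal lateral ventricles on a
  40³ grid of 1 mm isotropic voxels by default (tests use 32³ for
  speed); the extended ventricle mask is the ventricles dilated by 2
  voxels;
* lesions grown by a random walk from a seed voxel (repeatedly pick a
  random member voxel and a random 6-neighbour), giving irregular blobs
  that exercise nontrivial connectivity rather than spheres. Sizes are
  log-normal (median 15 voxels, log-sd 0.8, capped at 150).
  Periventricular lesions are seeded inside the extended-mask margin,
  guaranteeing overlap; deep lesions grow in tissue excluded from the
  extended mask, guaranteeing zero overlap. Every lesion is kept
  26-disconnected from every other, so planted lesions are exactly the
  connected components at any supported connectivity;
* each lesion carries a hypointense core with probability 0.5 (the
  planted analogue of roughly half of clusters containing hypointense
  voxels), occupying a uniform 20–70% of the lesion and placed at its
  morphological interior (largest distance to the lesion boundary);
* white-matter PVE is two-level: 0.8 on rims, 0.2 on cores, 0.85 in
  normal-appearing tissue, ~0 in CSF, plus optional truncated Gaussian
  noise (default sd 0.05, clipped to [0,1]). With zero noise the
  classification thresholds recover the planted classes exactly; with
  noise, individual voxels may cross the PVE threshold, but cluster
  location flags are unaffected because location is geometry-only;
* DTI maps assign tissue means — FA 0.45/0.37/0.26 and MD 0.80/0.92/1.12,
  AD 1.25/1.30/1.42, RD 0.58/0.73/0.97 (×10⁻³ mm²/s) for normal white
  matter / rim / core — plus Gaussian noise (sd 0.04–0.08 per metric).
  Cores are thus planted with lower FA and higher diffusivities than
  rims, the contrast pattern expected of more damaged tissue.

**Cohorts.** Cohort generation has two regimes. *Image-based* cohorts
render one phantom per subject and measure its volumes through the full
pipeline — used for end-to-end checks at small n. *Parametric* cohorts
draw the four log-adjusted sub-class volumes from a one-factor Gaussian
model (per-class means matching sub-class volumes of roughly 2.7, 2.1,
0.43 and 0.60 cm³ in a 1.456 dm³ brain; loading 0.5 and residual sd 0.65,
giving volume correlations near 0.4 and spreads with coefficient of
variation near one) — used for the Monte-Carlo calibration studies,
where rendering hundreds of thousands of images would add nothing to
what is being tested (the regression machinery, not the image
processing). Covariates are drawn to resemble an older, mostly male
occupational cohort: age uniform on 60–83 years, 81% male, education
13–28 years, blood pressures Gaussian around 141/77 mmHg. Cognitive
scores are a linear combination of covariates and the log-adjusted
volume predictors named in the planted effect, plus Gaussian noise
(sd 1.0 by default).

`beta_for_f2` converts a target partial effect size (Cohen's f²) into
the slope to plant, using the closed-form conditional variance of one
predictor given the other three under the factor model.

**What phantoms do not emulate.** No MR physics, bias fields,
registration error, anatomy beyond ellipsoids, realistic lesion shape
priors, or partial-volume structure beyond the two-level PVE scheme.
Passing tests therefore demonstrate correctness of the *computations*
(partitions, labeling, identities, statistics) under the stated
geometric assumptions — not segmentation accuracy or clinical validity
on real images.

## Defaults and numerical choices

| Parameter | Default | Why |
|---|---|---|
| WMH probability threshold | 0.9, strict `>` | literal "exceeding"; `strict` flag for `>=` |
| WM PVE threshold | 0.5, strict `>` | boundary voxel goes hypointense; configurable |
| Connectivity | 26 | common lesion-analysis practice; 6/18 selectable |
| Ventricle-map threshold | 0.05 | operationalises "very low"; mask may be supplied ready-made |
| Log base | e | base does not affect p-values; recorded in output |
| Zero-volume policy | missing | realistic cohorts have no zero classes; zeros flagged, not fudged |
| Grid tolerance | 1e-4 mm on voxel dims | registration round-off, far below anatomical scale |
| PVE clamp | 1e-6 | float round-off in segmentation outputs; larger excursions error |

The package never resamples or registers: all volumes for one subject
must arrive on one grid, and a mismatch is an error. Cluster IDs are
assigned in increasing order of each cluster's first voxel in C-order
scan, so labelings are reproducible across runs and platforms. All
randomness flows through a single integer seed; there is no hidden
global state.

## Problem sizes used in the shipped studies

The test suite and `scripts/acceptance.py` use 32³ phantom grids with
2–4 lesions per location class, cohorts of 200–300 subjects for the
regression calibration (500–2000 Monte-Carlo replicates), and 50-subject
cohorts across 20 seeds for the DTI contrast study. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands (e.g.
±0.5% on a 5% type-I rate at 2000 replicates) while the whole suite
runs in about a minute.

## Known limitations

* The intensity criterion inherits any inaccuracy of the upstream
  tissue segmentation; the package deliberately has no access to raw T1
  intensities.
* The continuity-to-ventricle criterion is one of several
  periventricular definitions; distance- and dilation-based variants are
  out of scope.
* Brain-volume adjustment is a ratio, not residualisation.
* The GLM family covers OLS with Type III tests only — no mixed models,
  robust errors, or longitudinal structure.
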