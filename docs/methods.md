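# Methods

## The analysis model

Each subject's data are a 4-D BOLD series on a common 3 mm isotropic grid
(default 64 × 64 × 40, world origin at the grid centre, x increasing to
the subject's right) together with a six-column rigid-motion table
(x, y, z, pitch, roll, yaw).  The task paradigm is a block design: each
cycle is `rest_s` seconds of rest followed by `task_s` seconds of task,
repeated `cycles` times and sampled at the TR (defaults 20 s / 20 s / 5 /
2 s, i.e. 100 volumes ≈ 3.5 min).

The voxel-wise model is ordinary least squares,

    y = β₀ + β_task · x_task + Σⱼ βⱼ mⱼ + β_d d + ε,

where `x_task` is the boxcar convolved with a canonical double-gamma HRF
(response peak gamma shape 6, undershoot shape 16, undershoot ratio 1/6;
peak-normalised), `mⱼ` are the six mean-centred motion series, and `d` is
an optional linear drift (default on).  The first three volumes are
dropped from data and design before fitting.  The map statistic is
t = β_task / SE(β_task) with residual dof = rows − rank(design); the dof
is carried on the map so thresholds can be translated to Student-t tail
probabilities.  No prewhitening is applied — the synthetic noise is white
by construction (see below).

Activation is counted on the positive tail only (task > rest): a voxel is
active at threshold τ iff t ≥ τ (inclusive).  Two-sided counting is
available behind a flag but is off by default, since the LI counts task
activation and negative-going voxels would corrupt VL/VR.

## LI, categories, sweep

LI = (VL − VR)/(VL + VR) is computed from integer counts as an exact
ratio.  When VL + VR = 0 the LI is an explicit *undetermined* state, never
a silent 0 — at τ = 4 sparse maps are genuinely empty and a 0 would fake
"bilateral".  Categories: LI > 0.2 left, |LI| ≤ 0.2 bilateral, LI < −0.2
right.  The conventional scale is stated with open intervals that exclude
±1.0; here the endpoints are assigned left/right respectively, since an
all-left map is maximally left-lateralized.  The default sweep is
τ ∈ {2, 2.67, 3.5, 4}.

Two mask families are provided. *Hemispheric*: all voxels with world
x < 0 (left) / x > 0 (right); voxels on the midline plane belong to
neither.  *Network*: the union of 5 mm closed-ball spheres at configured
left-hemisphere MNI seeds, mirrored through x → −x for the right side.
Mirroring happens in world space (negate x, re-rasterise), which is
correct for any affine; on the package's symmetric grids it is an exact
voxel permutation, so mirror-antisymmetry of the LI holds exactly.  The
hemispheric LI is the headline number; per-ROI-pair LIs (sphere vs
mirrored sphere, with the mean over defined pairs) are always available.
Whether a published "average hemispheric LI" averages per-pair LIs or
pools hemispheric counts is generally ambiguous; both routes are exposed
rather than resolved.

The shipped ROI table (`data/language_rois.json`) holds canonical
left-hemisphere language-area seeds — inferior frontal pars opercularis
(−52, 12, 12) and pars triangularis (−48, 28, 8), posterior superior
temporal (−56, −42, 6), angular (−46, −62, 30), supramarginal
(−54, −44, 26), and middle frontal (−42, 24, 28), radius 5 mm.  These are
explicit defaults, not authoritative coordinates: the JSON format
(`{name, x, y, z, radius_mm}`) is documented precisely so users can
substitute exact published seeds.

## Group inference

All tests are pooled-variance (Student) unpaired two-tailed two-sample
t-tests with dof = n₁ + n₂ − 2:

* each patient group vs the control group at every threshold, with
  Bonferroni-corrected α = 0.05/4 = 0.0125 for the default sweep;
* all C(k, 2) threshold pairs within one group/task, α = 0.05/6 ≈ 0.008.

The threshold-pair comparisons are deliberately **unpaired** even though
both samples contain the same subjects: dof bookkeeping of the form
2n − 2 (112 for n = 57, 82 for 42, 48 for 25, 44 for 23, 18 for 10, 22
for 12) identifies the unpaired procedure, and reproducing that
bookkeeping is part of this package's contract.  A paired variant
(`paired=True`, dof n − 1) is provided with the explicit caveat that it
is a different, generally more powerful, procedure.  Pooled-variance
rather than Welch for the same reason: integer dofs.

Undetermined LIs are removed listwise per comparison and the exclusion
count is carried on every result.  Significance is a pure function of
(p, corrected α).  The change-in-lateralization summary categorises the
*mean* LI per (group, task, threshold) cell and reports the transition
from the loosest to the strictest threshold as a string — "B → LL",
"B (no change)", "N/A" for an empty cell.

### Known inconsistencies in the conventional presentation

* The threshold↔p correspondence t ∈ {2, 2.67, 3.5, 4} ↔
  p ∈ {0.05, 0.01, 0.001, 0.0001} cannot hold simultaneously at any
  single dof in the plausible range: at dof 65–93 the two-tailed tail
  mass at t = 4 is ≈ 1.3–1.6 × 10⁻⁴ > 10⁻⁴.  The first three pairs hold
  as upper bounds and are asserted in the acceptance tests; the fourth is
  documented here and not asserted.
* Published per-arm dof headers are occasionally internally inconsistent
  (e.g. a "(df) = 34" header where the stated arm sizes give
  25 + 10 − 2 = 33).  The package computes dof from sample sizes and
  surfaces the arithmetic; it does not reproduce inconsistent headers.

## The synthetic generator

The generator inverts the analysis model.  Inside each declared spherical
cluster, signal = baseline × (1 + amplitude × HRF-convolved boxcar), with
amplitude in percent-signal-change units as a fraction of baseline
(0.02 = 2 %); overlapping clusters take the maximum amplitude.  Gaussian
noise with sd `noise_sd` × baseline is added at every voxel-timepoint,
independently.  Six smooth low-frequency motion series (Gaussian-smoothed
white noise, sd `motion_sd` in mm/degrees) are emitted as the motion
table, and a random linear combination of their standardised forms is
added globally to the signal with weight `motion_leak` × baseline — the
leaked component lies exactly in the span of the motion regressors, so
nuisance regression measurably and correctly removes it (tested).
Ground-truth cluster membership is rasterised through the same affine the
analysis masks use.

Cohort-level defaults are declared conventions chosen from what is
typical for robust language paradigms at 3 T, fixed before any acceptance
measurement and not revisited:

| parameter | default | rationale |
|---|---|---|
| noise_sd | 0.02 (2 % of baseline) | typical voxel-wise temporal noise after preprocessing |
| left amplitude | 0.03 ± 0.005 (3 % PSC) | strong expressive-language activation |
| right amplitude | 0.015 ± 0.0025 (2:1 ratio) | weaker homologous recruitment in lesion-type cohorts; (0, 0) for controls |
| cluster radius | 12 mm per seed | cm-scale activation extent around each node of the six-seed network (≈ 1 570 voxels per side on the default grid) |
| baseline | 1000 a.u. | arbitrary scanner units |
| motion_sd / motion_leak | 0.5 mm / 0.01 | sub-voxel motion with a 1 % signal leak |

With these conditions the expected behaviour is analytic before any
simulation: on the 64 × 64 × 40 grid each hemisphere holds 81 920 voxels,
so at τ = 2 (one-sided tail 0.0243 at dof 88) ≈ 1 990 symmetric noise
voxels per side join the ≈ 1 570 left-cluster voxels — a control subject
lands at LI ≈ 1570/(1570 + 2·1990) ≈ 0.28 (left), and a 2:1 cohort,
whose right clusters sit near t ≈ 3, lands near 0 (bilateral).  At τ = 4
noise contributes ≈ 5 voxels per side, only the strong left clusters
survive, and LI rises toward 1.  This is precisely the
bilateral-at-low-threshold → left-at-high-threshold effect the package
exists to study, emerging from calibration rather than being painted in.

What the generator does **not** emulate: temporal autocorrelation
(deliberately omitted — the type-I calibration checks assume exchangeable
Gaussian noise), lesion morphology and perilesional signal dropout, BOLD
nonlinearity, physiological noise, field-strength differences, or
realistic brain geometry (the "brain" is the whole grid, so hemispheric
noise counts are larger than in a brain-masked analysis).  Passing tests
therefore demonstrate the *bookkeeping and calibration* of the method and
the *mechanism* of the threshold effect, not clinical performance on
patient data.

## Numerical choices

* Thresholding is inclusive (t ≥ τ) for determinism on constructed maps.
* Sphere membership is a closed ball on voxel centres; radius 0
  degenerates to the single containing voxel with boundary ties broken
  toward the lower index.
* Zero-variance voxel series get t = 0 and are counted on the map;
  perfectly fitted voxels (zero residual, nonzero effect) get ±inf.
* Zero-variance nuisance columns are dropped with a log notice;
  rank-deficient designs are rejected naming the most collinear pair.
* Degenerate two-sample tests (both samples zero-variance, equal means)
  return t = 0, p = 1 with a `degenerate` flag.
* Smoothing (default 6 mm FWHM, applied to the series before the GLM)
  uses σ = FWHM/(2√(2 ln 2)) per axis converted through the voxel size.
  Calibration-sensitive checks run unsmoothed: smoothing leaves each
  voxel's marginal null t distribution intact but correlates voxels,
  which would invalidate independent-voxel Monte-Carlo error bounds.
* All randomness flows through `numpy.random.default_rng`; cohort
  subjects are seeded from `SeedSequence([cohort_seed, index])`, so any
  subject is reproducible in isolation.

## Problem sizes

Acceptance-level simulations use the full default grid (64 × 64 × 40,
100 volumes): 20 subjects for the 2:1 threshold-effect cohort, 5 for the
right-silent control check, and 3 pooled null subjects (≈ 4.9 × 10⁵
voxels) for type-I calibration — sizes at which the binomial Monte-Carlo
error bounds quoted above are decisive.  Unit tests use reduced grids
(16³–32³ scale) where the same invariants hold exactly.
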