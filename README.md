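# lisweep

Statistical-threshold effects on fMRI language lateralization, as a
reusable, fully tested pipeline.

In pre-surgical language mapping, the hemispheric dominance of a patient
is summarised by the **lateralization index**

```
LI = (VL − VR) / (VL + VR)
```

where `VL` and `VR` are the counts of active (suprathreshold) voxels in
the left and right hemispheres of a task-vs-rest t-map.  `LI = +1` is
fully left-dominant, `−1` fully right-dominant, and the conventional scale
calls `LI > 0.2` left-lateralized, `−0.2 ≤ LI ≤ 0.2` bilateral, and
`LI < −0.2` right-lateralized.  The catch is that LI depends on the
statistical threshold used to define "active": lesion patients often look
bilateral at a lenient threshold (t ≥ 2) and left-lateralized at a strict
one (t ≥ 4), which matters clinically because the choice of threshold can
flip the categorical call handed to a neurosurgical team.

`lisweep` implements the entire analysis chain needed to study that
effect, driven by a synthetic cohort generator with known ground truth so
every stage is testable without any patient data:

1. **synthetic cohorts** — block-design BOLD series (20 s rest / 20 s
   task × 5 cycles, TR 2 s by default) with spherical activation clusters
   of controllable percent-signal-change amplitude per hemisphere,
   Gaussian noise, and six smooth rigid-motion nuisance series that leak
   into the signal;
2. **GLM** — voxel-wise OLS on the HRF-convolved boxcar with motion (and
   optional drift) regressors, yielding a t-map with its residual dof;
3. **ROI networks** — 5 mm spheres at left-hemisphere MNI seeds with
   mirrored right-hemisphere homologues, or whole-hemisphere masks split
   at the x = 0 midline;
4. **LI threshold sweep** — voxel counting, the exact LI ratio, and
   categorisation at t ∈ {2, 2.67, 3.5, 4};
5. **group inference** — pooled-variance unpaired two-sample t-tests
   (group vs control at each threshold; all C(4,2)=6 threshold pairs
   within a group) with Bonferroni correction, and a
   change-in-lateralization summary ("B → LL"-style transition strings).

The GLM and LI layers are scikit-learn-style estimators
(`BlockDesignGLM`, `LateralizationSweep`) that compose with sklearn
tooling; every operation is also exposed as a plain function, and a
`lisweep` CLI wraps the lot.

## Worked example

A single simulated subject whose left-hemisphere language network has
twice the activation amplitude of its right homologue (the typical
lesion-patient configuration):

```python
from lisweep import (BlockDesignGLM, CohortSpec, build_network, li_curve,
                     make_paradigm, simulate_cohort)

paradigm = make_paradigm(rest_s=20, task_s=20, cycles=5, tr=2)
cohort = CohortSpec(n_subjects=1, seed=7)   # left:right amplitude 2:1
subject = next(iter(simulate_cohort(cohort, paradigm)))

glm = BlockDesignGLM(fwhm_mm=0.0)
tmap = glm.fit(subject.bold, motion=subject.motion).statmap_
masks = build_network(None, tmap.grid, mode="hemispheric")
curve = li_curve(tmap, masks)
print(f"dof = {tmap.dof}")
for r in curve.records:
    print(f"t >= {r.threshold:<5} VL = {r.v_left:<5} VR = {r.v_right:<5} "
          f"LI = {r.li:+.3f}  {r.category}")
```

prints

```
dof = 88
t >= 2.0   VL = 3460  VR = 2850  LI = +0.097  bilateral
t >= 2.67  VL = 1902  VR = 855   LI = +0.380  left
t >= 3.5   VL = 1551  VR = 180   LI = +0.792  left
t >= 4.0   VL = 1418  VR = 67    LI = +0.910  left
```

At the lenient threshold, symmetric false-positive voxels and the weaker
right-hemisphere activation drown the asymmetry — the subject reads as
bilateral.  As the threshold rises, only the strong left-network voxels
survive and the same subject reads as clearly left-lateralized: the
threshold, not the biology, changed the categorical call.

The full pipeline (simulate → GLM → masks → LI sweep → group statistics)
runs from one config:

```sh
lisweep run --out runs/demo --seed 0        # built-in 3-arm demo cohort
lisweep li --tmap runs/demo/../tmap.nii ... # per-stage subcommands
```

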