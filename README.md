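# imiomics

Whole-body water-fat MRI analysis in a common coordinate system: a
three-step, tissue-constrained deformable registration that maps every
subject's fat/water content volumes onto a reference body, plus the
voxel-wise statistics this enables — statistical atlases, anomaly and
group-comparison P-maps, correlation r-maps against non-imaging covariates,
local tissue volume from the deformation's Jacobian determinant, and
longitudinal difference maps.

**Who it is for.** Researchers in metabolic and body-composition imaging who
want point-to-point correspondence across whole-body scans so that every
voxel, not a handful of segmented regions, becomes a statistical
observation.

## The method

Each subject carries absolute fat content `I_FAT` and water content
`I_WATER` (percent), a body mask, a bone mask, nine bodypart labels and
eight joint landmarks. Registration to the reference proceeds in order of
increasing tissue variability, minimizing weight-normalized multi-band costs
`C = (Σ ωᵢ Sᵢ)/Σ ωᵢ` built from two primitives

```
S_SSD(T) = 1/|Ω_F| Σ (I_F(x) − I_M(T(x)))²          (masked intensity SSD)
S_LM(T)  = 1/P     Σ ‖x_M − T(x_F)‖                  (mean landmark distance, mm)
```

1. **Bone** — Procrustes similarity from the 8 landmarks, then per-section
   affine (+ slight B-spline elasticity) on per-section Euclidean distance
   transforms of the bone masks; 1000 point pairs per bone segment are
   sampled as `LM_BONE`.
2. **Water** — whole-body cubic B-spline (64 mm grid) on the water images,
   soft-constrained by `LM_BONE`; 4000 pairs in high-water voxels become
   `LM_WATER`.
3. **Fat** — whole-body B-spline at 32 mm, initialized by refining the water
   grid, driven by fat SSD + body-mask SSD + both landmark sets. Its result
   is the final mapping into the common coordinate system.

Optimization is seeded stochastic gradient descent over a Gaussian pyramid
(factors 4, 2, 1) with a deterministic quasi-Newton polish for
low-dimensional transforms. Registration quality is measured by inverse
consistency — composing independently estimated forward and reverse
transforms and reporting the vector magnitude error (VME, mm), intensity
magnitude error (IME, fat %) and Dice of 50 %-thresholded fat/water masks.

Because clinical whole-body cohorts are not redistributable, the package
ships a synthetic phantom generator (`imiomics.phantom`) whose
anthropometric covariates causally drive shape and intensity, giving every
experiment analytic ground truth. See `docs/methods.md` for the full model
and its limitations.

## Worked example

```python
import numpy as np
from imiomics.phantom import generate_cohort
from imiomics.registration import RegistrationConfig, register_whole_body
from imiomics.evaluation import vme, ime
from imiomics.imagecore import resample, ScalarVolume
from imiomics.imiomics_stats import build_atlas

# two synthetic subjects on the default whole-body grid (64x64x160 @ 4x4x8 mm)
subjects, covariates = generate_cohort(2, seed=7)
ref, subj = subjects[0].record, subjects[1].record

cfg = RegistrationConfig(seed=0)
fwd = register_whole_body(ref, subj, cfg)      # maps ref coords -> subj coords
rev = register_whole_body(subj, ref, cfg)

print("whole-body VME (mm): %.2f" % vme(fwd.transform, rev.transform, ref.body))
print("whole-body IME (fat %%): %.2f" % ime(fwd.transform, rev.transform,
                                            ref.fat, ref.body))

warped = resample(subj.fat, fwd.transform, ref.grid)
atlas = build_atlas([ref.fat, ScalarVolume.like(ref.fat, warped.values)])
body = ref.body.as_bool()
print("atlas fat SD over body (pp): %.2f" % atlas.sd.values[body].mean())
```

Output:

```
whole-body VME (mm): 4.28
whole-body IME (fat %): 5.43
atlas fat SD over body (pp): 6.04
```

The VME says that composing the two independently estimated registrations
moves a typical body voxel 4.3 mm from where it started — about one voxel on
this grid — and the IME that the composition changes fat content by ~5
percentage points on average (boundary voxels dominate both). The atlas SD
is the voxel-wise spread of fat content across the co-registered subjects;
low values outside genuinely variable regions indicate successful mapping
into the common coordinate system.

The same operations are available from the shell:

```sh
imiomics phantom --n 6 --seed 17 --out cohort/
imiomics register --fixed cohort/subj000 --moving cohort/subj001 --seed 0 --out reg/
imiomics evaluate --cohort cohort/ --reference subj000 --seed 0 --out report.csv
imiomics rmap --volumes ... --covariates cohort/covariates.csv \
    --covariate total_fat_mass_kg --out rmap.nii.gz
```

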