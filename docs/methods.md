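# Methods

This note documents the models, algorithms and numerical choices behind the
package: a three-step tissue-constrained deformable registration of
whole-body water-fat MR volumes into a common coordinate system, the
voxel-wise statistical maps computed on the co-registered volumes, and the
synthetic phantom cohort that serves as ground-truth substrate for all
quantitative claims.

## Registration model

A subject pair is a *fixed* (reference) and a *moving* subject, each with
absolute fat content `I_FAT` and water content `I_WATER` (percent, 0–100), a
body mask, a bone mask, a nine-part bodypart labelling and eight anatomical
joint landmarks (left/right ankle, knee, femoral head, humeral head). All
transforms map fixed physical coordinates (mm) to moving physical
coordinates — the resampling convention `I_M(T(x))`.

Costs are weight-normalized sums `C = (Σ ωᵢ Sᵢ) / Σ ωᵢ` of two primitives:

- `S_SSD(T; I_F, I_M) = (1/|Ω_F|) Σ (I_F(x) − I_M(T(x)))²` over a masked
  fixed-image domain, moving image sampled trilinearly;
- `S_LM(T; pairs) = (1/P) Σ ‖x_M − T(x_F)‖`, the mean (not squared)
  Euclidean landmark distance in mm.

The three steps register tissues in order of increasing morphological
variability:

1. **Bone.** A global similarity transform is fitted to the eight landmark
   pairs by closed-form Procrustes analysis (Umeyama solution with
   reflection guard). Each of the nine bone sections is then refined by an
   affine transform minimizing SSD between *per-section* Euclidean distance
   transforms of the bone masks plus the section's 1/2/4 nearest landmarks
   (ankle+knee for lower legs, knee+hip for upper legs, both hips for the
   pelvis, hips+shoulders for the torso, shoulders for arms and head). Every
   section then receives a slightly elastic B-spline refinement (64 mm
   control grid) composed onto its affine — mandatory for the torso, whose
   spine articulation is not affine, and applied to the long bones as well
   (switchable via `elastic_bone_sections`) so that the `LM_BONE` pairs
   sampled next are not biased by the within-section affine approximation.
   From the result, `LM_BONE` is sampled: 1000 uniform points per fixed
   bone segment (with replacement and a warning when a segment is smaller),
   mapped through that segment's transform. Per-section computations run on
   bounding-box crops (48 mm margin; the moving crop covers the union of
   both sections' boxes, and values outside it read the margin distance).
2. **Water.** A single whole-body cubic B-spline (64 mm grid) initialized
   from the Procrustes similarity minimizes SSD on the water images over the
   fixed body mask plus a `LM_BONE` soft constraint. From the result,
   `LM_WATER` is sampled: 4000 points in fixed voxels with water signal
   above 50%, mapped through the water transform.
3. **Fat.** A whole-body cubic B-spline at 32 mm grid spacing, initialized
   by re-expressing the water-step control grid at 32 mm (control-grid
   refinement via interpolating spline coefficients), minimizes SSD on fat
   content, SSD on the body masks treated as 0/100 intensity images, and
   `S_LM` on both `LM_BONE` and `LM_WATER`. This transform is the final
   fixed→moving mapping.

Per-section distance transforms in step 1 (rather than one global bone DT)
ensure that one section's articulation cannot perturb a neighbouring
section's cost; the evaluation domain for each section is its bodypart
region in the fixed labelling.

### Cost weights

The weights are artifact defaults chosen so each step's terms have
comparable magnitude on the phantom suite, and are all configurable:
`ω_bone = (1, 1)` (DT-SSD in mm², landmarks in mm), `ω_wat = (1, 20)`,
`ω_fat = (1, 0.3, 10, 10)`. The landmark weights for the elastic steps are
large because the mean landmark distance is on the mm scale while the SSD
terms are on the percent-squared scale (tens to hundreds); at this size the
landmark products match the SSD terms, and the shared `LM_BONE`/`LM_WATER`
anchors are what makes the two registration directions inverse-consistent —
weighting them much lower lets the elastic steps drift several millimetres
from the bone correspondence.

## Optimizer

Each step minimizes its cost by stochastic gradient descent over a Gaussian
multi-resolution pyramid (downsampling factors 4, 2, 1; smoothing σ = f/2
voxels; the factor-1 level is the untouched original). Per iteration a
random subsample of 2048 domain voxels (and up to 2048 landmark pairs)
yields an analytic gradient — image gradients interpolated at the mapped
points, chain-ruled through the transform parameterization (affine entries
scaled by the domain radius so every parameter is in mm; B-spline gradients
scattered through the cubic tensor-basis weights). Steps are normalized:
`p ← p − a_k · g/‖g‖_∞` with `a_k = a₀ (A/(k+A))^0.602`, `a₀ = 3 mm`,
`A = 20`, and the iteration counter running across levels so late steps stay
small. Defaults are 150 iterations per level for the whole-body elastic
steps and 40 for the bone sections, whose precision comes from the
deterministic polish.

Three numerical devices matter:

- **Best-seen guard.** A deterministic validation subsample (up to 8000
  domain voxels) is evaluated every 20 iterations *at the current pyramid
  level* — coarse levels are judged on their own smoothed data, since
  coarse progress need not register immediately on the finest level — and
  the best parameters seen are restored at each level end. A final guard on
  the finest level reverts to the initial parameters if nothing improved,
  so the returned cost never exceeds the initial cost.
- **Deterministic polish.** Normalized-step SGD converges slowly in its
  tail. For low-dimensional transforms (≤ 5000 parameters: the per-section
  affines and elastic refinements) an L-BFGS pass on the validation
  subsample follows, and then a derivative-free Nelder–Mead finish for
  ≤ 16 parameters — trilinear interpolation makes the cost only C⁰, and the
  simplex escapes the sub-voxel kinks a quasi-Newton line search stalls on.
  The polish is *not* applied to the large elastic grids: with more
  parameters than validation samples it overfits the subsample and the
  field oscillates between sample points.
- **Landmark-cost smoothing.** During optimization the mean landmark
  distance is smoothed to `sqrt(‖r‖² + δ²) − δ` with δ = 0.1 mm so its
  gradient vanishes at a perfect fit (the raw mean of norms has a kink at
  zero that pins landmarks and stalls line searches). Reported costs use
  the exact mean distance.
- **Anchored shrinkage.** During the polish, B-spline coefficients carry a
  tiny penalty (`10⁻³ · mean((c − c_init)²)`) toward the step's
  initialization, so control points the data does not constrain keep their
  initialized displacement instead of accumulated SGD noise.

No bending-energy regularization is applied beyond the landmark terms and
the polish shrinkage; a config hook (`bspline_shrinkage`) exposes the one
regularization constant used.

All randomness flows from a single integer seed per run; per-step
substreams are derived as `default_rng([seed, step_index])`, so repeated
runs are bit-identical.

## Evaluation metrics

Inverse consistency composes two *independently estimated* transforms, one
per registration direction. Over a domain Ω_B (body mask or one bodypart of
the subject whose space the composition returns to):

- **VME** = mean ‖x − T_B→A(T_A→B(x))‖ in mm,
- **IME** = mean |I_B(x) − I_B(T_B→A(T_A→B(x)))| on fat content (%),
- **Dice** of fat/water content thresholded at 50% (strict `>`) before vs
  after the composed deformation.

Both composition orders are evaluated; whole-body values are voxel-weighted
over the body mask. Composed points that leave the volume contribute their
actual displacement to VME and use the fill-value contract (0, air) for
IME. The cohort harness registers every subject to a reference in both
directions and reports per-bodypart and whole-body mean ± SD.

## Voxel-wise statistics

On volumes deformed to the common coordinate system:

- **Atlas**: per-voxel n, mean and sample SD (n−1 denominator, SD = 0 for
  n = 1), optionally keeping the full per-subject stack.
- **Anomaly P-map**: two-sided z-test of a new subject against atlas
  mean/SD (SD floored at 10⁻⁶, floored voxels counted in metadata); an
  empirical-percentile variant is available when the atlas keeps values.
- **Group P-map**: two-tailed two-sample t-test per voxel, Welch variant by
  default (pooled available by flag).
- **r-map**: per-voxel Pearson correlation with a covariate (Spearman by
  flag); zero-variance voxels get r = 0 and are counted.
- **Local tissue volume**: Jacobian determinant of the dense fixed→moving
  displacement field, `det(I + ∇u)` by central differences (one-sided at
  borders) in physical units; values > 1 mean the subject is locally larger
  than the reference. Non-positive determinants indicate folding and are
  reported, not repaired.
- **Longitudinal difference**: per-voxel `fixed − deformed_moving` in
  percentage points.

No multiple-testing correction is applied by default;
Benjamini–Hochberg adjustment is an explicit opt-in (`bh_adjust`). Maps can
be restricted to a body mask; outside voxels carry NaN and are excluded
from any calibration count.

## The phantom

The synthetic subject is an analytic body model on a 64×64×160 grid at
4×4×8 mm (a scaled-down analog of a clinical whole-body protocol — ~650k
voxels instead of ~12M — with the spacing anisotropy kept so physical-
coordinate handling is exercised). Nine bodyparts (2 lower legs, 2 upper
legs, pelvis, torso incl. neck, head, 2 upper arms; lower arms omitted) are
capsules/ellipsoids articulated at the eight joint landmarks. Joints are
deliberately non-coplanar and each bone section carries small asymmetric
structures (tibia + offset fibula, femur + greater trochanter, humerus +
epicondyle, skull shell with unequal radii) so that no section is
rotationally symmetric about its own axis — without this, spin about a limb
axis is invisible to both the landmark and distance-transform costs, and
per-section recovery would be ill-posed, as it would be with real tubular
bones replaced by idealized cylinders. Long bones start slightly distal of
their joints so that an articulated distal bone never enters the proximal
bodypart's label region.

Covariates drive the model causally: weight sets the global scale
(transverse ∝ weight^⅓, longitudinal ∝ weight^⅙ so tall/heavy subjects stay
on the grid); total fat mass sets the subcutaneous shell thickness
`t = 4 + 0.45·fat_mass` mm *and* grows the outer radii at the same rate, so
the lean compartment is preserved across fat-mass values — subcutaneous fat
accrues outward, as in real adiposity differences; liver fat sets the fat
content of a fixed analytic ellipsoid in the torso (so region statistics
have ground truth without segmentation). Tissue intensities: lean
fat/water = 8/80%, shell 85/10%, liver fat = covariate with water
= 92 − fat, bone and air zero. Additive Gaussian noise (σ = 2 percentage
points, in-body) is clipped to keep 0 ≤ fat, water and fat+water ≤ 100; an
optional smooth multiplicative bias along the foot–head axis emulates coil
inhomogeneity for the slice-normalization step.

Cohorts draw weight ~ N(75, 12) kg clipped to [52, 100], fat mass
~ N(20, 6) kg clipped to [6, 38], liver fat log-normal with median 4%
clipped to [1, 35], articulation angles ~ N(0, 3)°, alternating sexes.
Effects can be implanted through the generative covariates: group shifts in
liver fat, a stated liver-fat/fat-mass correlation
(`liver = μ + amp(ρ z + √(1−ρ²) ε)` on the standardized covariate), or
anomaly subjects with overridden liver fat. With `vary_shape=False` the
covariates are still drawn and recorded but their morphological footprint
is switched off — used for calibration cohorts that must share a grid
without registration.

`apply_known_deformation` warps a phantom by a known transform (volumes
resampled, masks/labels nearest-neighbour, landmarks mapped through the
numeric inverse by fixed-point iteration, folding rejected via the Jacobian)
and stores the exact dense field, enabling recovery experiments where the
registered field is compared against analytic truth.

**What the phantom does not emulate**: MR physics (relaxation, chemical
shift, B0/B1 maps), organ-level anatomy beyond the named regions, partial
volume beyond grid discretization, motion or reconstruction artefacts, and
inter-subject variability beyond the parameterized covariates. Passing the
phantom suite therefore demonstrates the pipeline's correctness and
calibration under its stated generative model, not clinical-grade accuracy
on patient data.

## Problem sizes and defaults used in the shipped experiments

The test suite and the results script run at phantom scale: default-grid
subjects (~650k voxels) for registration experiments, a 6-subject cohort
for the inverse-consistency report in the test suite (the results script
evaluates 3 subjects so a full run stays near ten minutes), a 60-subject
coarse-grid cohort (32×32×80 at 8×8×16 mm) for correlation recovery, and
≥2000-voxel synthetic stacks for P-map calibration. Group-comparison power uses n = 20 vs 23 and
a +2 SD implanted shift. The known-deformation experiment deforms one
subject by a random 96 mm-grid B-spline field normalized to a 10 mm mean
displacement over the body (displacement is linear in the coefficients, so
the normalization is exact).

## Known limitations

- The fat-step grid (32 mm) cannot represent shell-confined expansion
  sharper than its support; local-volume maps under-estimate thin-shell
  volume differences (the sign is correct; the magnitude saturates).
- The simplified bone-mask extraction keys on low signal inside the eroded
  body and a maximal-inscribed-sphere thickness rule (≤ 16 mm, calibrated
  on the phantom tissue model) to reject lung-like air; near-surface bone
  (skull) is partially excluded by the erosion margin.
- Inverse consistency measures self-consistency of the method, not
  correspondence truth; the recovery experiments with known fields are the
  stronger evidence and exist only at phantom scale.
- The slice-wise normalization assumes a multiplicative, slowly varying
  axial intensity profile; it restores the global in-body mean exactly
  after smoothing the per-slice factors (running mean, window 5).
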