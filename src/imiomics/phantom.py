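"""Synthetic whole-body water-fat subjects with analytic ground truth.

The phantom emulates the per-subject data model of whole-body water-fat MRI:
fat/water content volumes (percent), body and bone masks, a nine-part
bodypart labelling and the eight anatomical joint landmarks, on a
scaled-down anisotropic grid.  Anthropometric covariates causally drive the
geometry and intensities: weight sets the global body scale, total fat mass
sets the subcutaneous fat-shell thickness, and liver fat sets the fat
content of an analytic ellipsoidal liver region.

The default grid (64x64x160 voxels at 4x4x8 mm) is a scaled-down analog of a
clinical whole-body protocol; the spacing anisotropy is kept so that
physical-coordinate handling is exercised everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imagecore import BinaryMask, Grid, LabelVolume, ScalarVolume, resample
from .subject import BODYPART_NAMES, SubjectRecord
from .transforms import (
    DisplacementField,
    LandmarkSet,
    SpatialTransform,
    jacobian_determinant,
    to_displacement_field,
)

# Tissue intensity model (percent signal): lean tissue is water-dominated,
# the subcutaneous shell fat-dominated, bone and air give no signal.
LEAN_FAT, LEAN_WATER = 8.0, 80.0
SHELL_FAT, SHELL_WATER = 85.0, 10.0
LIVER_WATER_TOTAL = 92.0  # liver water = LIVER_WATER_TOTAL - liver fat


@dataclass
class PhantomSpec:
    """Geometry, covariates and noise of one synthetic subject."""

    shape: tuple = (64, 64, 160)
    spacing: tuple = (4.0, 4.0, 8.0)
    weight_kg: float = 75.0
    fat_mass_kg: float = 20.0
    liver_fat_pct: float = 5.0
    sex: str = "F"
    knee_angle_left_deg: float = 0.0
    knee_angle_right_deg: float = 0.0
    shoulder_angle_left_deg: float = 0.0
    shoulder_angle_right_deg: float = 0.0
    noise_sigma: float = 2.0
    bias_amplitude: float = 0.0
    include_lungs: bool = False

    def __post_init__(self):
        if not 40.0 <= self.weight_kg <= 110.0:
            raise ValueError("weight must lie in [40, 110] kg")
        if not 3.0 <= self.fat_mass_kg <= 45.0:
            raise ValueError("fat mass must lie in [3, 45] kg")
        if not 0.0 <= self.liver_fat_pct <= 60.0:
            raise ValueError("liver fat must lie in [0, 60] %")


@dataclass
class PhantomSubject:
    """A generated subject plus its analytic ground truth."""

    record: SubjectRecord
    spec: PhantomSpec
    liver_center: np.ndarray
    liver_radii: np.ndarray
    true_field: DisplacementField | None = None

    def liver_mask(self) -> BinaryMask:
        g = self.record.grid
        pts = g.voxel_centers()
        d = ((pts - self.liver_center) / self.liver_radii) ** 2
        return BinaryMask((d.sum(axis=-1) <= 1.0).astype(np.uint8), g.spacing, g.origin)


def _capsule(pts, p0, p1, r):
    """Mask of points within distance r of segment [p0, p1]."""
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    L2 = float(d @ d)
    rel = pts - p0
    t = np.clip((rel @ d) / max(L2, 1e-12), 0.0, 1.0)
    closest = t[..., None] * d
    return ((rel - closest) ** 2).sum(axis=-1) <= r * r


def _ellipsoid(pts, center, radii):
    d = (pts - np.asarray(center, float)) / np.asarray(radii, float)
    return (d**2).sum(axis=-1) <= 1.0


def _elliptic_cylinder(pts, ax, ay, z0, z1):
    return (
        ((pts[..., 0] / ax) ** 2 + (pts[..., 1] / ay) ** 2 <= 1.0)
        & (pts[..., 2] >= z0)
        & (pts[..., 2] <= z1)
    )


def _rot_x(deg):
    a = math.radians(deg)
    return np.array(
        [[1, 0, 0], [0, math.cos(a), -math.sin(a)], [0, math.sin(a), math.cos(a)]]
    )


def generate_subject(spec: PhantomSpec, seed: int = 0) -> PhantomSubject:
    """Build one subject from an analytic body model.

    Nine bodyparts (2 lower legs, 2 upper legs, pelvis, torso incl. neck,
    head, 2 upper arms; lower arms omitted) are capped tubes / ellipsoids
    articulated at the joint landmarks; bone is interior tubes and a skull
    shell with zero fat+water signal; the subcutaneous fat shell thickness
    grows with the fat-mass covariate; an ellipsoidal liver carries the
    liver-fat covariate.
    """
    grid = Grid(
        spec.shape,
        spec.spacing,
        origin=(
            -(spec.shape[0] - 1) * spec.spacing[0] / 2.0,
            -(spec.shape[1] - 1) * spec.spacing[1] / 2.0,
            0.0,
        ),
    )
    pts = grid.voxel_centers()
    sxy = (spec.weight_kg / 75.0) ** (1.0 / 3.0)
    sz = (spec.weight_kg / 75.0) ** (1.0 / 6.0)
    S = np.array([sxy, sxy, sz])
    # Subcutaneous fat accrues OUTWARD: outer radii grow at the same rate as
    # the shell thickness (0.45 mm/kg), so the lean compartment is preserved
    # across fat-mass values, as in real adiposity differences.
    fat_growth = 0.45 * (spec.fat_mass_kg - 20.0)

    def P(x, y, z):
        return np.array([x, y, z]) * S

    # Joints (physical mm).  z runs foot -> head; joints are deliberately
    # non-coplanar (y offsets) so landmark-based fits are well-posed.
    hip = {"l": P(-48, -6, 640), "r": P(48, -6, 640)}
    knee = {s: hip[s] + np.array([0, 10 * sxy, -280 * sz]) for s in "lr"}
    ankle = {}
    for s, ang in (("l", spec.knee_angle_left_deg), ("r", spec.knee_angle_right_deg)):
        ankle[s] = knee[s] + _rot_x(ang) @ np.array([0, -8 * sxy, -300 * sz])
    shoulder = {"l": P(-88, 8, 1030), "r": P(88, 8, 1030)}
    arm_tip = {}
    for s, ang in (
        ("l", spec.shoulder_angle_left_deg),
        ("r", spec.shoulder_angle_right_deg),
    ):
        arm_tip[s] = shoulder[s] + _rot_x(ang) @ np.array([0, 0, -210 * sz])

    r_lower = (34 + fat_growth) * sxy
    r_upper = (44 + fat_growth) * sxy
    r_arm = 16 * sxy
    head_c = P(0, 0, 1150)
    head_r = np.array([45 * sxy, 50 * sxy, 55 * sz])

    shapes = {  # bodypart id -> outer shape; assignment priority below
        1: _capsule(pts, knee["l"], ankle["l"], r_lower),
        2: _capsule(pts, knee["r"], ankle["r"], r_lower),
        3: _capsule(pts, hip["l"], knee["l"], r_upper),
        4: _capsule(pts, hip["r"], knee["r"], r_upper),
        5: _elliptic_cylinder(
            pts, (82 + fat_growth) * sxy, (64 + fat_growth) * sxy, 600 * sz, 760 * sz
        ),
        6: _elliptic_cylinder(
            pts, (78 + fat_growth) * sxy, (62 + fat_growth) * sxy, 760 * sz, 1060 * sz
        )
        | _capsule(pts, P(0, 0, 1050), P(0, 0, 1100), 28 * sxy),
        7: _ellipsoid(pts, head_c, head_r),
        8: _capsule(pts, shoulder["l"], arm_tip["l"], r_arm),
        9: _capsule(pts, shoulder["r"], arm_tip["r"], r_arm),
    }
    labels = np.zeros(spec.shape, dtype=np.int32)
    for part in (7, 6, 5, 8, 9, 3, 4, 1, 2):  # proximal parts claim overlaps
        labels[shapes[part] & (labels == 0)] = part
    body = labels > 0
    if not body.any():
        raise ValueError("phantom body is empty")
    for part in BODYPART_NAMES:
        if not (labels == part).any():
            raise ValueError(f"bodypart {BODYPART_NAMES[part]!r} is empty on this grid")
    # Shapes must fit inside the grid: no body voxel on a boundary face.
    edge = np.zeros(spec.shape, dtype=bool)
    edge[[0, -1], :, :] = True
    edge[:, [0, -1], :] = True
    edge[:, :, [0, -1]] = True
    if (body & edge).any():
        raise ValueError("phantom shapes exceed the grid")

    # Bone: shafts plus small paired/offset structures (fibula, greater
    # trochanter, epicondyle) so no bone section is rotationally symmetric
    # about its own axis — as in real skeletons.
    # skull: ellipsoidal shell with a >= 1-voxel scalp layer outside it
    bone = _ellipsoid(pts, head_c, head_r * 0.80) & ~_ellipsoid(pts, head_c, head_r * 0.60)
    bone |= _capsule(pts, hip["l"], hip["r"], 12 * sxy)
    bone |= _capsule(pts, P(0, -18, 640), P(0, -18, 1050), 11 * sxy)
    arm_ang = {"l": spec.shoulder_angle_left_deg, "r": spec.shoulder_angle_right_deg}
    for s, lat in (("l", -1.0), ("r", 1.0)):
        axis = ankle[s] - knee[s]
        fib_off = np.array([lat * 13 * sxy, 0.0, 0.0])  # lateral: articulation-invariant
        # joint gaps keep each long bone inside its own bodypart under
        # articulation (so a rotated tibia never enters the upper-leg section)
        bone |= _capsule(pts, knee[s] + 0.18 * axis, ankle[s], 8 * sxy)  # tibia
        bone |= _capsule(
            pts, knee[s] + fib_off + 0.22 * axis, ankle[s] + fib_off, 4.5 * sxy
        )  # fibula
        bone |= _capsule(pts, hip[s], knee[s] - 0.05 * (knee[s] - hip[s]), 11 * sxy)  # femur
        bone |= _ellipsoid(
            pts, hip[s] + np.array([lat * 16 * sxy, 0.0, -14 * sz]), 9 * sxy
        )  # greater trochanter
        arm_axis = arm_tip[s] - shoulder[s]
        bone |= _capsule(pts, shoulder[s] + 0.08 * arm_axis, arm_tip[s], 7 * sxy)  # humerus
        epi_off = _rot_x(arm_ang[s]) @ np.array([0.0, 9 * sxy, 10 * sz])
        bone |= _ellipsoid(pts, arm_tip[s] + epi_off, 6 * sxy)  # epicondyle
    bone &= body

    # Subcutaneous fat shell: within t_sc of the body surface.
    from scipy import ndimage as ndi

    t_sc = 4.0 + 0.45 * spec.fat_mass_kg
    depth = ndi.distance_transform_edt(body, sampling=spec.spacing)
    shell = body & (depth <= t_sc) & ~bone

    fat = np.zeros(spec.shape)
    water = np.zeros(spec.shape)
    lean = body & ~shell & ~bone
    fat[lean], water[lean] = LEAN_FAT, LEAN_WATER
    fat[shell], water[shell] = SHELL_FAT, SHELL_WATER

    liver_c = P(28, 4, 940)
    liver_r = np.array([30 * sxy, 26 * sxy, 46 * sz])
    liver = _ellipsoid(pts, liver_c, liver_r) & lean
    fat[liver] = spec.liver_fat_pct
    water[liver] = LIVER_WATER_TOTAL - spec.liver_fat_pct

    if spec.include_lungs:
        lungs = _ellipsoid(pts, P(-38, -5, 990), (20 * sxy, 18 * sxy, 38 * sz)) | _ellipsoid(
            pts, P(38, -5, 990), (20 * sxy, 18 * sxy, 38 * sz)
        )
        lungs &= body & ~bone
        fat[lungs] = 0.0
        water[lungs] = 0.0

    if spec.bias_amplitude > 0:
        zext = (spec.shape[2] - 1) * spec.spacing[2]
        bias = 1.0 + spec.bias_amplitude * np.sin(3.0 * np.pi * pts[..., 2] / zext)
        fat *= bias
        water *= bias

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        fat[body] += rng.normal(0.0, spec.noise_sigma, size=int(body.sum()))
        water[body] += rng.normal(0.0, spec.noise_sigma, size=int(body.sum()))

    np.clip(fat, 0.0, 100.0, out=fat)
    np.clip(water, 0.0, 100.0, out=water)
    total = fat + water
    over = total > 100.0
    scale = np.where(over, 100.0 / np.maximum(total, 1e-9), 1.0)
    fat *= scale
    water *= scale
    water[over] = 100.0 - fat[over]  # keep fat + water <= 100 exactly

    landmarks = LandmarkSet(
        {
            "ankle_left": ankle["l"],
            "ankle_right": ankle["r"],
            "knee_left": knee["l"],
            "knee_right": knee["r"],
            "femoral_head_left": hip["l"],
            "femoral_head_right": hip["r"],
            "humeral_head_left": shoulder["l"],
            "humeral_head_right": shoulder["r"],
        }
    )
    covariates = {
        "weight_kg": spec.weight_kg,
        "total_fat_mass_kg": spec.fat_mass_kg,
        "lean_tissue_kg": spec.weight_kg - spec.fat_mass_kg,
        "liver_fat_pct": spec.liver_fat_pct,
        "sex": spec.sex,
    }
    record = SubjectRecord(
        subject_id=f"phantom-{seed}",
        fat=ScalarVolume(fat, grid.spacing, grid.origin),
        water=ScalarVolume(water, grid.spacing, grid.origin),
        body=BinaryMask(body.astype(np.uint8), grid.spacing, grid.origin),
        bone=BinaryMask(bone.astype(np.uint8), grid.spacing, grid.origin),
        bodyparts=LabelVolume(labels, grid.spacing, grid.origin),
        landmarks=landmarks,
        covariates=covariates,
    )
    return PhantomSubject(record, spec, liver_c, liver_r)


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortEffects:
    """Ground-truth effects implanted through the generative covariates.

    ``group_delta_pp`` shifts liver fat of group "B" subjects by that many
    percentage points; ``correlation_rho`` couples liver fat to total fat
    mass with the stated correlation (implanted as
    ``liver_fat = mu + amp * (rho * z + sqrt(1-rho^2) * eps)`` on the
    standardized covariate); ``anomaly_liver_fat`` overrides liver fat for
    the listed subject indices.
    """

    group_delta_pp: float = 0.0
    correlation_rho: float = 0.0
    correlation_amplitude_pp: float = 10.0
    anomaly_liver_fat: dict = field(default_factory=dict)


def generate_cohort(
    n: int,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    effects: CohortEffects | None = None,
    vary_shape: bool = True,
):
    """Seeded cohort of phantoms plus its covariate table.

    Covariate distributions: weight ~ N(75, 12) kg clipped to [52, 100],
    total fat mass ~ N(20, 6) kg clipped to [6, 38], liver fat log-normal
    with median 4% clipped to [1, 35], small articulation angles ~ N(0, 3)
    degrees, sexes alternating.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if base_spec is None:
        base_spec = PhantomSpec()
    if effects is None:
        effects = CohortEffects()
    rng = np.random.default_rng(seed)
    weights = np.clip(rng.normal(75.0, 12.0, n), 52.0, 100.0)
    fat_masses = np.clip(rng.normal(20.0, 6.0, n), 6.0, 38.0)
    liver = np.clip(np.exp(rng.normal(np.log(4.0), 0.5, n)), 1.0, 35.0)
    angles = rng.normal(0.0, 3.0, (n, 4))
    groups = np.array(["A", "B"])[np.arange(n) % 2]

    if effects.correlation_rho != 0.0:
        z = (fat_masses - fat_masses.mean()) / max(fat_masses.std(), 1e-9)
        eps = rng.normal(0.0, 1.0, n)
        rho = effects.correlation_rho
        liver = 15.0 + effects.correlation_amplitude_pp * (
            rho * z + math.sqrt(1.0 - rho**2) * eps
        )
        liver = np.clip(liver, 1.0, 35.0)
    if effects.group_delta_pp != 0.0:
        liver = liver + np.where(groups == "B", effects.group_delta_pp, 0.0)
        liver = np.clip(liver, 0.0, 60.0)
    for idx, lf in effects.anomaly_liver_fat.items():
        liver[idx] = lf

    subjects = []
    rows = []
    for i in range(n):
        spec = replace(
            base_spec,
            weight_kg=float(weights[i]) if vary_shape else base_spec.weight_kg,
            fat_mass_kg=float(fat_masses[i]) if vary_shape else base_spec.fat_mass_kg,
            liver_fat_pct=float(liver[i]),
            sex="F" if i % 2 == 0 else "M",
            knee_angle_left_deg=float(angles[i, 0]) if vary_shape else 0.0,
            knee_angle_right_deg=float(angles[i, 1]) if vary_shape else 0.0,
            shoulder_angle_left_deg=float(angles[i, 2]) if vary_shape else 0.0,
            shoulder_angle_right_deg=float(angles[i, 3]) if vary_shape else 0.0,
        )
        subj = generate_subject(spec, seed=int(seed * 10007 + i) % (2**31))
        subj.record.subject_id = f"subj{i:03d}"
        if not vary_shape:
            # covariates are still drawn (and can carry implanted effects);
            # only their morphological footprint is switched off
            subj.record.covariates.update(
                {
                    "weight_kg": float(weights[i]),
                    "total_fat_mass_kg": float(fat_masses[i]),
                    "lean_tissue_kg": float(weights[i] - fat_masses[i]),
                }
            )
        subj.record.covariates["group"] = groups[i]
        subjects.append(subj)
        rows.append({"subject_id": subj.record.subject_id, **subj.record.covariates})
    table = pd.DataFrame(rows).set_index("subject_id")
    return subjects, table


# ---------------------------------------------------------------------------
# Known deformations


def _invert_points(transform: SpatialTransform, targets: np.ndarray, iters: int = 50):
    """Fixed-point inversion x_{k+1} = x_k - (T(x_k) - y) for smooth fields."""
    x = targets.copy()
    for _ in range(iters):
        r = transform(x) - targets
        x = x - r
        if np.abs(r).max() < 1e-9:
            break
    return x


def apply_known_deformation(
    subject: PhantomSubject, transform: SpatialTransform
) -> PhantomSubject:
    """Warp a phantom by a known transform, keeping exact ground truth.

    The returned subject D satisfies ``D(x) = original(T(x))`` — i.e. the
    exact fixed(D)→moving(original) mapping is ``transform`` — with masks
    resampled nearest-neighbour, landmarks mapped analytically (inverse of T)
    and the dense field stored as ground truth.
    """
    rec = subject.record
    grid = rec.grid
    fieldv = to_displacement_field(transform, grid)
    jac = jacobian_determinant(fieldv)
    if np.any(jac.values <= 0):
        raise ValueError("folding detected: deformation is not invertible on the grid")
    fat = resample(rec.fat, transform, grid)
    water = resample(rec.water, transform, grid)
    body = resample(rec.body, transform, grid, mode="nearest")
    bone = resample(rec.bone, transform, grid, mode="nearest")
    parts = resample(rec.bodyparts, transform, grid, mode="nearest")
    lms = LandmarkSet(
        {
            name: _invert_points(transform, rec.landmarks[name][None, :])[0]
            for name in rec.landmarks.points
        }
    )
    new_rec = SubjectRecord(
        subject_id=rec.subject_id + "-deformed",
        fat=fat,
        water=water,
        body=BinaryMask(body.values, grid.spacing, grid.origin),
        bone=BinaryMask(bone.values, grid.spacing, grid.origin),
        bodyparts=LabelVolume(parts.values, grid.spacing, grid.origin),
        landmarks=lms,
        covariates=dict(rec.covariates),
    )
    return PhantomSubject(
        new_rec, subject.spec, subject.liver_center, subject.liver_radii, true_field=fieldv
    )
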