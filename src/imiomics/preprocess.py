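"""Input preprocessing: body mask, slice-wise intensity normalization,
multi-atlas fusion (majority vote / mean landmarks) and bone-mask extraction.

Bone extraction exploits that both air and cortical bone give no signal in
water-fat separated MRI: low-signal voxels well inside the body are bone
candidates; lung-like internal air pockets are rejected by an
inscribed-sphere thickness rule (bones are tubes and shells, lungs are
thick blobs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imagecore import BinaryMask, LabelVolume, ScalarVolume
from .transforms import LandmarkSet, LANDMARK_NAMES


@dataclass
class AtlasLibrary:
    """Manually curated subjects (labels + landmarks) used for label fusion;
    male and female subjects are treated separately."""

    subjects: list

    def __post_init__(self):
        if not self.subjects:
            raise ValueError("atlas library needs at least one subject")
        for s in self.subjects:
            if "sex" not in s.covariates:
                raise ValueError(f"library subject {s.subject_id!r} lacks a sex attribute")

    def by_sex(self, sex: str) -> list:
        return [s for s in self.subjects if s.covariates["sex"] == sex]


def extract_body_mask(
    fat: ScalarVolume,
    water: ScalarVolume,
    threshold: float = 30.0,
    min_component_voxels: int = 1,
) -> BinaryMask:
    """Threshold fat+water, close, keep the largest component, fill holes.

    The threshold default is calibrated on the phantom tissue model (lean and
    fat tissue both exceed 30% total signal) and is overridable for other
    intensity models.
    """
    if not fat.same_geometry(water):
        raise ValueError("fat and water volumes must share one grid")
    total = fat.values + water.values
    raw = total > threshold
    if not raw.any():
        raise ValueError("no voxels above the body threshold")
    struct = ndimage.generate_binary_structure(3, 1)
    closed = ndimage.binary_closing(raw, structure=struct)
    lab, nlab = ndimage.label(closed)
    if nlab == 0:
        raise ValueError("body mask empty after morphology")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = lab == keep
    if mask.sum() < min_component_voxels:
        raise ValueError("largest component below min_component_voxels")
    for k in range(mask.shape[2]):  # slice-wise hole fill (axial)
        mask[:, :, k] = ndimage.binary_fill_holes(mask[:, :, k])
    return BinaryMask(mask.astype(np.uint8), fat.spacing, fat.origin)


def normalize_slices(
    volume: ScalarVolume, body: BinaryMask, window: int = 5
) -> ScalarVolume:
    """Slice-wise intensity normalization along the foot-head axis.

    Each axial slice's in-body mean is scaled toward the global in-body mean;
    the per-slice factors are smoothed with a running mean (window 5) so the
    correction itself introduces no new discontinuities, and the global
    in-body mean is restored exactly afterwards.  Slices without body voxels
    pass through unchanged.
    """
    if not volume.same_geometry(body):
        raise ValueError("volume and body mask must share one grid")
    sel = body.as_bool()
    if not sel.any():
        raise ValueError("body mask is empty")
    out = volume.values.astype(float).copy()
    global_mean = out[sel].mean()
    nz = volume.shape[2]
    factors = np.ones(nz)
    has_body = np.zeros(nz, dtype=bool)
    for k in range(nz):
        s = sel[:, :, k]
        if s.any():
            m = out[:, :, k][s].mean()
            if abs(m) > 1e-12:
                factors[k] = global_mean / m
                has_body[k] = True
    # running-mean smoothing over body-bearing slices only
    idx = np.where(has_body)[0]
    if len(idx) >= 1:
        f = factors[idx]
        half = window // 2
        smoothed = np.array(
            [f[max(0, i - half) : i + half + 1].mean() for i in range(len(f))]
        )
        factors[idx] = smoothed
    for k in idx:
        s = sel[:, :, k]
        out[:, :, k][s] *= factors[k]
    new_mean = out[sel].mean()
    if abs(new_mean) > 1e-12:
        out[sel] *= global_mean / new_mean
    return ScalarVolume.like(volume, out)


def majority_vote(labels: list) -> LabelVolume:
    """Per-voxel modal label; ties broken by the lowest label id."""
    if not labels:
        raise ValueError("majority vote needs at least one label volume")
    ref = labels[0]
    for lv in labels[1:]:
        if not ref.same_geometry(lv):
            raise ValueError("label volumes must share one grid")
    stack = np.stack([lv.values for lv in labels])
    ids = np.unique(stack)
    counts = np.stack([(stack == i).sum(axis=0) for i in ids])
    # argmax returns the first maximum; ids ascending => ties -> lowest id
    winner = ids[np.argmax(counts, axis=0)]
    return LabelVolume(winner, ref.spacing, ref.origin)


def mean_landmarks(sets: list) -> LandmarkSet:
    """Coordinate-wise mean position per landmark name."""
    if not sets:
        raise ValueError("need at least one landmark set")
    return LandmarkSet(
        {
            name: np.mean([s[name] for s in sets], axis=0)
            for name in LANDMARK_NAMES
        }
    )


def extract_bone_mask(
    fat: ScalarVolume,
    water: ScalarVolume,
    body: BinaryMask,
    low_cutoff: float = 15.0,
    erode_voxels: int = 2,
    min_component_voxels: int = 10,
    max_inradius_mm: float = 16.0,
) -> BinaryMask:
    """Low-signal voxels well inside the body, kept if tube/shell-like.

    Candidates are voxels with fat+water below ``low_cutoff`` inside the
    eroded body mask, morphologically opened and size-filtered.  Components
    whose maximal inscribed-sphere radius exceeds ``max_inradius_mm`` are
    rejected as internal air (lungs/abdomen), which is thick, unlike bone.
    """
    if not (fat.same_geometry(water) and fat.same_geometry(body)):
        raise ValueError("inputs must share one grid")
    sel = body.as_bool()
    if not sel.any():
        raise ValueError("body mask is empty")
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(sel, structure=struct, iterations=erode_voxels)
    cand = (fat.values + water.values < low_cutoff) & interior
    cand = ndimage.binary_opening(cand, structure=struct)
    if not cand.any():
        raise ValueError("no bone candidates found")
    lab, nlab = ndimage.label(cand)
    depth = ndimage.distance_transform_edt(cand, sampling=fat.spacing)
    keep = np.zeros_like(cand)
    for i in range(1, nlab + 1):
        comp = lab == i
        if comp.sum() < min_component_voxels:
            continue
        if float(depth[comp].max()) > max_inradius_mm:
            continue  # thick blob: internal air, not bone
        keep |= comp
    if not keep.any():
        raise ValueError("no components survived the bone shape rules")
    return BinaryMask(keep.astype(np.uint8), fat.spacing, fat.origin)
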