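"""Voxel-wise statistical maps on co-registered whole-body volumes.

Once every subject is deformed into the common coordinate system, each voxel
carries a distribution of fat content (or local tissue volume) across
subjects.  This module summarizes those distributions (atlas), tests a new
subject against them (anomaly P-map), compares groups (two-tailed t-test
P-map), correlates voxel values with non-imaging covariates (r-map), derives
local tissue volume from the deformation (Jacobian determinant) and forms
longitudinal difference maps.  No multiple-testing correction is applied by
default; Benjamini-Hochberg adjustment is available as an opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .imagecore import BinaryMask, Grid, ScalarVolume
from .transforms import SpatialTransform, jacobian_determinant, to_displacement_field

_SD_FLOOR = 1e-6


@dataclass
class Atlas:
    """Voxel-wise n / mean / sample SD over a co-registered stack."""

    n: int
    mean: ScalarVolume
    sd: ScalarVolume
    content: str = "fat_pct"
    values: np.ndarray | None = None  # optional (n, *grid) per-subject stack


@dataclass
class StatMap:
    """A per-voxel statistic with provenance metadata.

    ``kind`` is one of p_value / r_value / difference / jacobian; voxels
    outside the analysis mask hold NaN.
    """

    volume: ScalarVolume
    kind: str
    metadata: dict = field(default_factory=dict)


def _check_stack(volumes) -> np.ndarray:
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    ref = volumes[0]
    for v in volumes[1:]:
        if not ref.same_geometry(v):
            raise ValueError("all volumes must share the common-coordinate grid")
    return np.stack([v.values for v in volumes])


def _apply_mask(arr: np.ndarray, mask: BinaryMask | None) -> np.ndarray:
    if mask is not None:
        arr = arr.copy()
        arr[~mask.as_bool()] = np.nan
    return arr


def build_atlas(volumes, keep_values: bool = False, content: str = "fat_pct") -> Atlas:
    """Voxel-wise n, mean and sample SD (n−1 denominator; SD = 0 for n = 1)."""
    stack = _check_stack(volumes)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    ref = volumes[0]
    return Atlas(
        n=n,
        mean=ScalarVolume.like(ref, mean),
        sd=ScalarVolume.like(ref, sd),
        content=content,
        values=stack if keep_values else None,
    )


def anomaly_pmap(
    subject: ScalarVolume,
    atlas: Atlas,
    mask: BinaryMask | None = None,
    method: str = "z",
) -> StatMap:
    """Two-sided P-map of one subject against the atlas distribution.

    Default is a z-test of ``(v − mean)/sd`` against the normal distribution
    (SD floored at a tiny ε; floored voxels are counted in metadata).  With
    ``method="percentile"`` and an atlas that kept its full value stack, the
    two-sided empirical percentile is used instead.  Uncorrected P-values.
    """
    if atlas.n < 3:
        raise ValueError("anomaly detection needs an atlas with n >= 3")
    if not subject.same_geometry(atlas.mean):
        raise ValueError("subject is not in the atlas coordinate system")
    if method == "percentile":
        if atlas.values is None:
            raise ValueError("percentile method needs an atlas built with keep_values=True")
        below = (atlas.values <= subject.values).mean(axis=0)
        p = 2.0 * np.minimum(below, 1.0 - below) + 1.0 / atlas.n
        p = np.minimum(p, 1.0)
        floored = 0
    else:
        sd = atlas.sd.values
        floored = int(np.count_nonzero((sd < _SD_FLOOR) & np.isfinite(sd)))
        z = (subject.values - atlas.mean.values) / np.maximum(sd, _SD_FLOOR)
        p = 2.0 * sps.norm.sf(np.abs(z))
    p = _apply_mask(p, mask)
    return StatMap(
        ScalarVolume.like(subject, p),
        kind="p_value",
        metadata={
            "test": f"anomaly_{method}",
            "n": atlas.n,
            "two_tailed": True,
            "sd_floored_voxels": floored,
        },
    )


def group_pmap(
    group_a,
    group_b,
    mask: BinaryMask | None = None,
    equal_var: bool = False,
) -> StatMap:
    """Two-tailed two-sample t-test P-map (Welch by default), uncorrected.

    Voxels where both groups are constant and equal get p = 1.
    """
    a = _check_stack(group_a)
    b = _check_stack(group_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must share the common-coordinate grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p) & np.isclose(a.mean(axis=0), b.mean(axis=0))
    p[degenerate] = 1.0
    p = _apply_mask(p, mask)
    ref = group_a[0]
    return StatMap(
        ScalarVolume.like(ref, p),
        kind="p_value",
        metadata={
            "test": "welch_t" if not equal_var else "pooled_t",
            "n": (a.shape[0], b.shape[0]),
            "two_tailed": True,
        },
    )


def rmap(
    volumes,
    covariate,
    mask: BinaryMask | None = None,
    method: str = "pearson",
) -> StatMap:
    """Per-voxel correlation between subject values and a covariate.

    Pearson by default (Spearman optional); voxels with zero variance get
    r = 0 and are counted in metadata.
    """
    stack = _check_stack(volumes)
    cov = np.asarray(covariate, dtype=float)
    if stack.shape[0] < 3:
        raise ValueError("correlation needs n >= 3 subjects")
    if cov.shape != (stack.shape[0],) or not np.all(np.isfinite(cov)):
        raise ValueError("covariate must be one finite value per subject")
    if np.std(cov) < 1e-12:
        raise ValueError("constant covariate has no defined correlation")
    if method == "spearman":
        stack = sps.rankdata(stack, axis=0)
        cov = sps.rankdata(cov)
    vc = stack - stack.mean(axis=0)
    cc = cov - cov.mean()
    denom_v = np.sqrt((vc**2).sum(axis=0))
    denom_c = float(np.sqrt((cc**2).sum()))
    flat_voxels = denom_v < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.einsum("i...,i->...", vc, cc) / (denom_v * denom_c)
    r[flat_voxels] = 0.0
    r = np.clip(r, -1.0, 1.0)
    r = _apply_mask(r, mask)
    ref = volumes[0]
    return StatMap(
        ScalarVolume.like(ref, r),
        kind="r_value",
        metadata={
            "test": method,
            "n": stack.shape[0],
            "zero_variance_voxels": int(flat_voxels.sum()),
        },
    )


def local_volume_map(transform: SpatialTransform, geometry: Grid) -> ScalarVolume:
    """Point-wise local expansion/compression of the registered subject.

    The Jacobian determinant of the dense fixed→moving deformation field:
    values > 1 mean the subject is locally larger than the reference.
    """
    return jacobian_determinant(to_displacement_field(transform, geometry))


def longitudinal_diff(
    fixed: ScalarVolume,
    deformed_moving: ScalarVolume,
    mask: BinaryMask | None = None,
) -> StatMap:
    """Point-wise ``fixed − deformed_moving`` difference (percentage points)."""
    if not fixed.same_geometry(deformed_moving):
        raise ValueError("difference map needs both volumes on the common grid")
    d = _apply_mask(fixed.values - deformed_moving.values, mask)
    return StatMap(
        ScalarVolume.like(fixed, d),
        kind="difference",
        metadata={"test": "difference"},
    )


def bh_adjust(pmap: StatMap) -> StatMap:
    """Optional Benjamini-Hochberg adjustment over the in-mask voxels."""
    if pmap.kind != "p_value":
        raise ValueError("BH adjustment applies to P-maps")
    p = pmap.volume.values
    sel = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    adj[sel] = sps.false_discovery_control(p[sel], method="bh")
    return StatMap(
        ScalarVolume.like(pmap.volume, adj),
        kind="p_value",
        metadata={**pmap.metadata, "adjustment": "benjamini-hochberg"},
    )
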