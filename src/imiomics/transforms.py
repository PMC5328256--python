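"""Spatial transform algebra.

All transforms map FIXED physical coordinates (mm) to MOVING physical
coordinates — the resampling convention: the moving image is pulled back
onto the fixed grid through ``I_M(T(x))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imagecore import Grid, ScalarVolume

#: The eight anatomical landmarks used to anchor whole-body registration.
LANDMARK_NAMES = (
    "ankle_left",
    "ankle_right",
    "knee_left",
    "knee_right",
    "femoral_head_left",
    "femoral_head_right",
    "humeral_head_left",
    "humeral_head_right",
)


def _as_points(points) -> tuple[np.ndarray, bool]:
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite point")
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 3:
        raise ValueError("points must have three components")
    return pts, single


class SpatialTransform:
    """Base class; subclasses implement :meth:`apply` on ``(N, 3)`` arrays."""

    def apply(self, points):
        raise NotImplementedError

    def __call__(self, points):
        pts, single = _as_points(points)
        out = self.apply(pts)
        return out[0] if single else out

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass
class SimilarityTransform(SpatialTransform):
    """T(x) = s·R(x − c) + t + c with proper rotation R and scale s > 0."""

    s: float = 1.0
    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    c: np.ndarray = field(default_factory=lambda: np.zeros(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.s <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-9):
            raise ValueError("R must be orthonormal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("R must be a proper rotation (det=+1)")

    def apply(self, points):
        pts, single = _as_points(points)
        out = self.s * (pts - self.c) @ self.R.T + self.t + self.c
        return out[0] if single else out

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    def to_dict(self):
        return {
            "type": "similarity",
            "s": float(self.s),
            "R": self.R.tolist(),
            "c": self.c.tolist(),
            "t": self.t.tolist(),
        }


@dataclass
class AffineTransform(SpatialTransform):
    """T(x) = A(x − c) + b + c; A must be invertible."""

    A: np.ndarray = field(default_factory=lambda: np.eye(3))
    b: np.ndarray = field(default_factory=lambda: np.zeros(3))
    c: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if abs(np.linalg.det(self.A)) < 1e-12:
            raise ValueError("affine matrix must be invertible")

    def apply(self, points):
        pts, single = _as_points(points)
        out = (pts - self.c) @ self.A.T + self.b + self.c
        return out[0] if single else out

    def rotation_angle_deg(self) -> float:
        """Rotation angle of the orthogonal factor of A (polar decomposition)."""
        u, _, vt = np.linalg.svd(self.A)
        rot = u @ vt
        if np.linalg.det(rot) < 0:
            u[:, -1] *= -1
            rot = u @ vt
        cos = (np.trace(rot) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))

    def to_dict(self):
        return {
            "type": "affine",
            "A": self.A.tolist(),
            "b": self.b.tolist(),
            "c": self.c.tolist(),
        }


class BSplineTransform(SpatialTransform):
    """Free-form deformation T(x) = x + u(x).

    The displacement u is a cubic B-spline sum over control-point displacement
    vectors on a coarse regular grid; ``coefficients`` has shape
    ``(3, nx, ny, nz)`` and holds the spline coefficients (= the control
    displacements in the B-spline basis), in mm.
    """

    def __init__(self, grid_origin, grid_spacing, coefficients):
        self.grid_origin = np.asarray(grid_origin, dtype=float)
        self.grid_spacing = np.asarray(grid_spacing, dtype=float)
        if np.any(self.grid_spacing <= 0):
            raise ValueError("control grid spacing must be positive")
        self.coefficients = np.asarray(coefficients, dtype=float)
        if self.coefficients.ndim != 4 or self.coefficients.shape[0] != 3:
            raise ValueError("coefficients must have shape (3, nx, ny, nz)")

    @classmethod
    def zero(cls, domain_lo, domain_hi, spacing) -> "BSplineTransform":
        """Identity transform whose grid covers [lo, hi] plus cubic support margin."""
        lo = np.asarray(domain_lo, dtype=float)
        hi = np.asarray(domain_hi, dtype=float)
        sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
        n = np.ceil((hi - lo) / sp).astype(int) + 1 + 4  # +/-2 control points margin
        origin = lo - 2.0 * sp
        return cls(origin, sp, np.zeros((3, *n)))

    def _grid_coords(self, pts: np.ndarray) -> np.ndarray:
        return (pts - self.grid_origin) / self.grid_spacing

    def displacement(self, points) -> np.ndarray:
        pts, single = _as_points(points)
        tloc = self._grid_coords(pts).T
        u = np.stack(
            [
                ndimage.map_coordinates(
                    self.coefficients[a], tloc, order=3, prefilter=False,
                    mode="constant", cval=0.0,
                )
                for a in range(3)
            ],
            axis=-1,
        )
        return u[0] if single else u

    def apply(self, points):
        pts, single = _as_points(points)
        out = pts + self.displacement(pts)
        return out[0] if single else out

    def refine(self, new_spacing) -> "BSplineTransform":
        """Re-express the deformation on a finer control grid.

        Samples the current displacement at the new control points and fits
        interpolating cubic-spline coefficients; for smooth fields sampled at
        half the spacing the round-trip error is negligible.
        """
        lo = self.grid_origin + 2.0 * self.grid_spacing
        hi = self.grid_origin + (np.array(self.coefficients.shape[1:]) - 3) * self.grid_spacing
        out = BSplineTransform.zero(lo, hi, new_spacing)
        n = out.coefficients.shape[1:]
        ii = [out.grid_origin[a] + np.arange(n[a]) * out.grid_spacing[a] for a in range(3)]
        pts = np.stack(np.meshgrid(*ii, indexing="ij"), axis=-1).reshape(-1, 3)
        u = self.displacement(pts).reshape(*n, 3)
        for a in range(3):
            out.coefficients[a] = ndimage.spline_filter(u[..., a], order=3, mode="constant")
        return out

    def to_dict(self):
        return {
            "type": "bspline",
            "grid_origin": self.grid_origin.tolist(),
            "grid_spacing": self.grid_spacing.tolist(),
            "coefficients": self.coefficients.tolist(),
        }


@dataclass
class CompositeTransform(SpatialTransform):
    """Right-to-left composition: the LAST transform in the list acts first.

    ``CompositeTransform([T3, T2, T1])`` realizes T3 ∘ T2 ∘ T1.
    """

    transforms: list

    def __post_init__(self):
        if not self.transforms:
            raise ValueError("composite transform needs at least one member")

    def apply(self, points):
        pts, single = _as_points(points)
        out = pts
        for tr in reversed(self.transforms):
            out = tr(out)
        return out[0] if single else out

    def to_dict(self):
        return {"type": "composite", "transforms": [t.to_dict() for t in self.transforms]}


def transform_from_dict(d: dict) -> SpatialTransform:
    kind = d["type"]
    if kind == "similarity":
        return SimilarityTransform(d["s"], np.array(d["R"]), np.array(d["c"]), np.array(d["t"]))
    if kind == "affine":
        return AffineTransform(np.array(d["A"]), np.array(d["b"]), np.array(d["c"]))
    if kind == "bspline":
        return BSplineTransform(d["grid_origin"], d["grid_spacing"], np.array(d["coefficients"]))
    if kind == "composite":
        return CompositeTransform([transform_from_dict(s) for s in d["transforms"]])
    raise ValueError(f"unknown transform type {kind!r}")


# ---------------------------------------------------------------------------
# Landmarks and point pairs


@dataclass
class LandmarkSet:
    """The 8 named anatomical joints (physical mm)."""

    points: dict

    def __post_init__(self):
        missing = [n for n in LANDMARK_NAMES if n not in self.points]
        if missing:
            raise ValueError(f"missing landmarks: {', '.join(missing)}")
        self.points = {n: np.asarray(self.points[n], dtype=float) for n in LANDMARK_NAMES}
        for n, p in self.points.items():
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {n!r} is not a finite 3-vector")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def array(self, names=LANDMARK_NAMES) -> np.ndarray:
        return np.stack([self.points[n] for n in names])

    def to_dict(self):
        return {n: p.tolist() for n, p in self.points.items()}


@dataclass
class PointPairs:
    """Matched fixed/moving physical points used as soft constraints."""

    fixed: np.ndarray
    moving: np.ndarray
    provenance: str = "anatomical"  # anatomical | LM_BONE | LM_WATER

    def __post_init__(self):
        self.fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        self.moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        if self.fixed.shape != self.moving.shape or self.fixed.shape[-1] != 3:
            raise ValueError("fixed and moving point lists must be (N, 3) and equal length")
        if not (np.all(np.isfinite(self.fixed)) and np.all(np.isfinite(self.moving))):
            raise ValueError("point pairs must be finite")

    def __len__(self) -> int:
        return self.fixed.shape[0]

    @classmethod
    def from_landmarks(cls, fixed: LandmarkSet, moving: LandmarkSet, names=LANDMARK_NAMES):
        return cls(fixed.array(names), moving.array(names), provenance="anatomical")

    @classmethod
    def concatenate(cls, parts: list) -> "PointPairs":
        prov = parts[0].provenance if len({p.provenance for p in parts}) == 1 else "mixed"
        return cls(
            np.concatenate([p.fixed for p in parts]),
            np.concatenate([p.moving for p in parts]),
            provenance=prov,
        )


def fit_procrustes(pairs: PointPairs) -> SimilarityTransform:
    """Closed-form similarity fit (rotation + isotropic scale + translation).

    Minimizes the mean squared distance ``mean ||x_M - T(x_F)||^2`` over
    proper rotations, positive scale and translation (Umeyama's solution,
    with the reflection guard).  Needs >= 3 non-collinear pairs.
    """
    if len(pairs) < 3:
        raise ValueError("Procrustes needs at least 3 point pairs")
    X = pairs.fixed
    Y = pairs.moving
    mu_x = X.mean(axis=0)
    mu_y = Y.mean(axis=0)
    Xc = X - mu_x
    Yc = Y - mu_y
    var_x = (Xc**2).sum() / len(pairs)
    if var_x < 1e-12:
        raise ValueError("degenerate landmark configuration (coincident points)")
    cov = Yc.T @ Xc / len(pairs)
    u, d, vt = np.linalg.svd(cov)
    if np.linalg.matrix_rank(Xc, tol=1e-9 * np.abs(Xc).max()) < 2:
        raise ValueError("degenerate landmark configuration (collinear points)")
    sign = np.ones(3)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        sign[-1] = -1
    R = u @ np.diag(sign) @ vt
    s = float((d * sign).sum() / var_x)
    if s <= 0:
        raise ValueError("degenerate configuration: non-positive scale")
    return SimilarityTransform(s=s, R=R, c=mu_x, t=mu_y - mu_x)


# ---------------------------------------------------------------------------
# Dense fields


@dataclass
class DisplacementField:
    """Per-voxel displacement u(x) in mm on a regular grid."""

    vectors: np.ndarray  # (*shape, 3)
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("vectors must have shape (*grid, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def grid(self) -> Grid:
        return Grid(self.vectors.shape[:3], self.spacing, self.origin)

    def magnitude(self) -> ScalarVolume:
        return ScalarVolume(np.linalg.norm(self.vectors, axis=-1), self.spacing, self.origin)


def to_displacement_field(transform: SpatialTransform, geometry: Grid) -> DisplacementField:
    """u(x) = T(x) − x evaluated at every voxel center of ``geometry``."""
    centers = geometry.voxel_centers()
    flat = centers.reshape(-1, 3)
    mapped = flat if transform is None else transform(flat)
    u = (mapped - flat).reshape(*geometry.shape, 3)
    return DisplacementField(u, geometry.spacing, geometry.origin)


def jacobian_determinant(fieldv: DisplacementField) -> ScalarVolume:
    """det(∇T) with ∇T = I + ∇u via central differences (one-sided at borders).

    Values > 1 mean local expansion of the moving anatomy relative to the
    reference; non-positive values indicate folding.
    """
    u = fieldv.vectors
    sp = fieldv.spacing
    J = np.empty((*u.shape[:3], 3, 3))
    for a in range(3):
        grads = np.gradient(u[..., a], *sp, axis=(0, 1, 2))
        for b in range(3):
            J[..., a, b] = grads[b]
    J += np.eye(3)
    return ScalarVolume(np.linalg.det(J), fieldv.spacing, fieldv.origin)


# ---------------------------------------------------------------------------
# Cubic B-spline basis helpers (shared with the registration optimizer)


def cubic_bspline_weights(tloc: np.ndarray):
    """Support indices and weights of the cubic B-spline basis at ``tloc``.

    ``tloc`` is an (N, 3) array of continuous control-grid coordinates.
    Returns ``(base, weights)`` where ``base`` is (N, 3) int (the lowest
    contributing control index is ``base - 1``) and ``weights`` is (N, 4, 3):
    per axis the basis values at offsets (-1, 0, 1, 2) from ``base``.
    """
    base = np.floor(tloc).astype(int)
    frac = tloc - base
    w = np.empty((tloc.shape[0], 4, 3))
    # B3 evaluated at frac+1, frac, frac-1, frac-2
    f = frac
    w[:, 0] = (1 - f) ** 3 / 6.0
    w[:, 1] = (3 * f**3 - 6 * f**2 + 4) / 6.0
    w[:, 2] = (-3 * f**3 + 3 * f**2 + 3 * f + 1) / 6.0
    w[:, 3] = f**3 / 6.0
    return base, w
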