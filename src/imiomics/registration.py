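"""Three-step tissue-constrained whole-body registration.

The pipeline maps a moving subject onto a fixed (reference) subject in three
steps ordered by increasing morphological variability of the tissue being
matched:

1. articulated piecewise-affine registration of bone sections (distance
   transforms of the bone masks + anatomical landmarks), initialized by a
   Procrustes similarity fit of the 8 joints;
2. low-elasticity B-spline registration of the water images, soft-constrained
   by point pairs sampled in the registered bone (``LM_BONE``);
3. high-elasticity B-spline registration of the fat images + body masks,
   soft-constrained by ``LM_BONE`` and by water point pairs (``LM_WATER``).

Costs are weight-normalized sums of sampled sum-of-squared-differences and
mean landmark-distance terms, minimized by stochastic gradient descent over a
Gaussian multi-resolution pyramid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imagecore import BinaryMask, LabelVolume, ScalarVolume, distance_transform
from .subject import PART_LANDMARKS, SPINE_PART, BODYPART_NAMES, SubjectRecord
from .transforms import (
    AffineTransform,
    BSplineTransform,
    CompositeTransform,
    PointPairs,
    SpatialTransform,
    cubic_bspline_weights,
    fit_procrustes,
)

# ---------------------------------------------------------------------------
# Configuration


@dataclass
class OptimizerSettings:
    """Stochastic gradient descent settings (per pyramid level)."""

    iterations_per_level: int = 150
    samples_per_iteration: int = 2048
    step_size_mm: float = 3.0        # initial max parameter change per iteration
    decay_A: float = 20.0            # a_k = a0 * (A / (k + A))^alpha
    decay_alpha: float = 0.602
    validation_samples: int = 8000   # deterministic subset used for the best-seen guard
    validation_interval: int = 20
    # Deterministic L-BFGS polish on the validation subsample, applied after
    # SGD (whose decaying normalized steps converge slowly in the tail);
    # a derivative-free simplex finish follows for low-dimensional transforms.
    # Restricted to low-dimensional transforms: with more parameters than
    # validation samples the polish overfits the subsample and the field
    # oscillates between sample points.
    polish_max_params: int = 5000
    polish_maxiter: int = 200
    # Tiny Tikhonov penalty on B-spline coefficient deviation from the step's
    # initialization during the polish: control points the data does not
    # constrain keep their initialized displacement instead of accumulated
    # SGD noise.
    bspline_shrinkage: float = 1e-3


@dataclass
class RegistrationConfig:
    """Weights, grid spacings, pyramid and sampling parameters.

    The cost-term weights are artifact defaults balancing term magnitudes on
    the phantom suite; every weight is overridable.
    """

    w_bone: tuple = (1.0, 1.0)             # (SSD on bone DTs, landmark)
    w_water: tuple = (1.0, 20.0)           # (SSD on water, LM_BONE)
    w_fat: tuple = (1.0, 0.3, 10.0, 10.0)  # (SSD fat, SSD body, LM_BONE, LM_WATER)
    grid_spine_mm: float = 64.0
    grid_water_mm: float = 64.0
    grid_fat_mm: float = 32.0
    pyramid_factors: tuple = (4, 2, 1)
    n_bone_pairs_per_segment: int = 1000
    n_water_pairs: int = 4000
    water_cutoff: float = 50.0
    #: allow the slight elastic refinement on every bone section (the spine
    #: always gets one); keeps LM_BONE free of per-section affine bias
    elastic_bone_sections: bool = True
    seed: int = 0
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)
    # Bone sections are low-dimensional and finish in the deterministic
    # polish; they need fewer stochastic iterations than the elastic steps.
    bone_optimizer: OptimizerSettings = field(
        default_factory=lambda: OptimizerSettings(
            iterations_per_level=40, polish_maxiter=100
        )
    )

    def __post_init__(self):
        for name in ("w_bone", "w_water", "w_fat"):
            w = getattr(self, name)
            if any(x < 0 for x in w) or not any(x > 0 for x in w):
                raise ValueError(f"{name} must be non-negative with at least one positive entry")
        f = self.pyramid_factors
        if f[-1] != 1 or any(a <= b for a, b in zip(f, f[1:])) or any(x < 1 for x in f):
            raise ValueError("pyramid factors must strictly decrease to 1")


@dataclass
class CostTerm:
    """One term of a multi-band cost: sampled SSD or mean landmark distance."""

    kind: str  # "ssd" | "landmark"
    fixed: ScalarVolume | None = None
    moving: ScalarVolume | None = None
    domain: BinaryMask | None = None
    pairs: PointPairs | None = None
    fill: float = 0.0  # value read outside the moving volume (0 = air)

    def __post_init__(self):
        if self.kind == "ssd":
            if self.domain is None or self.domain.n_voxels == 0:
                raise ValueError("SSD term needs a non-empty evaluation domain")
        elif self.kind == "landmark":
            if self.pairs is None or len(self.pairs) == 0:
                raise ValueError("landmark term needs at least one pair")
        else:
            raise ValueError(f"unknown cost term kind {self.kind!r}")


@dataclass
class StepResult:
    """Outcome of one optimization step."""

    transform: SpatialTransform
    initial_cost: float
    final_cost: float
    term_costs: tuple
    pairs: PointPairs | None = None
    log: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Cost functions


def _domain_points(domain: BinaryMask) -> np.ndarray:
    idx = np.argwhere(domain.as_bool())
    if idx.size == 0:
        raise ValueError("empty evaluation domain")
    return domain.grid.index_to_physical(idx)


def _sample_volume(volume: ScalarVolume, pts: np.ndarray, fill: float = 0.0) -> np.ndarray:
    idx = volume.grid.physical_to_index(pts)
    return ndimage.map_coordinates(volume.values, idx.T, order=1, mode="constant", cval=fill)


def ssd_cost(
    transform: SpatialTransform | None,
    fixed: ScalarVolume,
    moving: ScalarVolume,
    domain: BinaryMask,
    fill: float = 0.0,
) -> float:
    """Mean squared intensity difference over the domain voxels.

    ``S = (1/|Ω_F|) Σ (I_F(x) − I_M(T(x)))²`` with the moving image sampled
    by trilinear interpolation at the mapped voxel centers; points outside
    the moving volume read ``fill``.
    """
    pts = _domain_points(domain)
    fvals = fixed.values[domain.as_bool()]
    mapped = pts if transform is None else transform(pts)
    mvals = _sample_volume(moving, mapped, fill=fill)
    return float(np.mean((fvals - mvals) ** 2))


def landmark_cost(transform: SpatialTransform | None, pairs: PointPairs) -> float:
    """Mean Euclidean distance (mm) between moving points and T(fixed points)."""
    if len(pairs) == 0:
        raise ValueError("landmark cost needs at least one pair")
    mapped = pairs.fixed if transform is None else transform(pairs.fixed)
    return float(np.mean(np.linalg.norm(pairs.moving - mapped, axis=1)))


def evaluate_term(term: CostTerm, transform: SpatialTransform | None) -> float:
    if term.kind == "ssd":
        return ssd_cost(transform, term.fixed, term.moving, term.domain, fill=term.fill)
    return landmark_cost(transform, term.pairs)


def combined_cost(terms, weights, transform: SpatialTransform | None) -> float:
    """Weight-normalized sum ``C = (Σ ω_i S_i) / Σ ω_i``."""
    weights = np.asarray(weights, dtype=float)
    if len(terms) != len(weights):
        raise ValueError("terms and weights must have equal length")
    if weights.sum() <= 0:
        raise ValueError("at least one weight must be positive")
    vals = np.array([evaluate_term(t, transform) for t in terms])
    return float((weights * vals).sum() / weights.sum())


# ---------------------------------------------------------------------------
# Gaussian pyramid


def gaussian_pyramid(volume: ScalarVolume, factors=(4, 2, 1)) -> list:
    """Coarse-to-fine scale-space levels by Gaussian smoothing + subsampling.

    Level with factor f is smoothed with σ = f/2 voxels then subsampled by f;
    the factor-1 level is the original volume, untouched.
    """
    if any(int(f) < 1 for f in factors) or factors[-1] != 1:
        raise ValueError("factors must be positive integers ending in 1")
    if min(volume.shape) < max(factors):
        raise ValueError("volume smaller than the largest pyramid factor")
    levels = []
    for f in factors:
        f = int(f)
        if f == 1:
            levels.append(volume)
            continue
        sm = ndimage.gaussian_filter(volume.values.astype(float), sigma=f / 2.0)
        sub = sm[::f, ::f, ::f]
        levels.append(ScalarVolume(sub, tuple(np.array(volume.spacing) * f), volume.origin))
    return levels


def _mask_pyramid(mask: BinaryMask, factors) -> list:
    out = []
    for f in factors:
        f = int(f)
        if f == 1:
            out.append(mask)
        else:
            sub = mask.values[::f, ::f, ::f]
            out.append(BinaryMask(sub, tuple(np.array(mask.spacing) * f), mask.origin))
    return out


# ---------------------------------------------------------------------------
# Optimizable parameterizations


class _AffineParams:
    """Centered affine, entries of (A − I) scaled by the domain radius so all
    parameters are in millimetres."""

    def __init__(self, center: np.ndarray, radius: float):
        self.c = np.asarray(center, dtype=float)
        self.r = max(float(radius), 1.0)
        self.p = np.zeros(12)  # [M.ravel()*r, t]

    def get(self) -> np.ndarray:
        return self.p.copy()

    def set(self, p: np.ndarray) -> None:
        self.p = p.copy()

    def _matrices(self):
        M = self.p[:9].reshape(3, 3) / self.r
        t = self.p[9:]
        return np.eye(3) + M, t

    def apply(self, z: np.ndarray) -> np.ndarray:
        A, t = self._matrices()
        return (z - self.c) @ A.T + t + self.c

    def gradient(self, z: np.ndarray, dLdT: np.ndarray) -> np.ndarray:
        zc = (z - self.c) / self.r
        g = np.empty(12)
        g[:9] = (dLdT.T @ zc).ravel()
        g[9:] = dLdT.sum(axis=0)
        return g

    def transform(self) -> AffineTransform:
        A, t = self._matrices()
        return AffineTransform(A=A, b=t, c=self.c)


class _BSplineParams:
    """Cubic B-spline displacement; parameters are the control coefficients (mm)."""

    def __init__(self, bspline: BSplineTransform):
        self.bspl = bspline

    def get(self) -> np.ndarray:
        return self.bspl.coefficients.ravel().copy()

    def set(self, p: np.ndarray) -> None:
        self.bspl.coefficients = p.reshape(self.bspl.coefficients.shape).copy()

    def apply(self, z: np.ndarray) -> np.ndarray:
        return self.bspl.apply(z)

    def gradient(self, z: np.ndarray, dLdT: np.ndarray) -> np.ndarray:
        g = np.zeros_like(self.bspl.coefficients)
        shape = g.shape[1:]
        tloc = self.bspl._grid_coords(z)
        base, w = cubic_bspline_weights(tloc)
        gflat = g.reshape(3, -1)
        ny, nz = shape[1], shape[2]
        # per-axis support indices, clipped once
        ix = np.clip(base[:, 0, None] + np.arange(-1, 3), 0, shape[0] - 1)
        iy = np.clip(base[:, 1, None] + np.arange(-1, 3), 0, ny - 1)
        iz = np.clip(base[:, 2, None] + np.arange(-1, 3), 0, nz - 1)
        for dx in range(4):
            px = ix[:, dx] * ny
            wx = w[:, dx, 0]
            for dy in range(4):
                pxy = (px + iy[:, dy]) * nz
                wxy = wx * w[:, dy, 1]
                for dz in range(4):
                    flat = pxy + iz[:, dz]
                    ww = wxy * w[:, dz, 2]
                    for a in range(3):
                        np.add.at(gflat[a], flat, ww * dLdT[:, a])
        return g.ravel()

    def transform(self) -> BSplineTransform:
        return self.bspl


# ---------------------------------------------------------------------------
# Stochastic gradient descent optimizer

#: The mean-landmark-distance cost is smoothed as sqrt(|r|^2 + delta^2) - delta
#: during optimization so its gradient vanishes at a perfect fit (the raw mean
#: of norms has a kink at zero that stalls line searches); reported costs use
#: the exact mean distance.
_LM_DELTA = 0.1  # mm


def optimize_step(
    terms,
    weights,
    params,
    config: RegistrationConfig,
    rng: np.random.Generator,
    initial: SpatialTransform | None = None,
) -> StepResult:
    """Minimize the weighted cost over a multi-resolution pyramid.

    ``params`` is an :class:`_AffineParams` or :class:`_BSplineParams` whose
    transform acts AFTER the frozen ``initial`` transform: the optimized
    mapping is ``T(x) = params(initial(x))``.  Each iteration takes a
    normalized gradient step from a random voxel subsample; a deterministic
    validation subset implements a best-seen guard so the returned cost never
    exceeds the initial one.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(terms) or weights.sum() <= 0:
        raise ValueError("invalid weights")
    wnorm = weights / weights.sum()
    opt = config.optimizer
    factors = config.pyramid_factors
    log: list[str] = []

    # --- precompute per-term, per-level data -------------------------------
    ssd_levels = []   # list over terms of list over levels of dicts
    lm_data = []
    for term in terms:
        if term.kind == "ssd":
            fpyr = gaussian_pyramid(term.fixed, factors)
            mpyr = gaussian_pyramid(term.moving, factors)
            dpyr = _mask_pyramid(term.domain, factors)
            per_level = []
            for flv, mlv, dlv in zip(fpyr, mpyr, dpyr):
                sel = dlv.as_bool()
                if not sel.any():  # domain vanished at coarse scale: use full-res points
                    sel = None
                if sel is None:
                    pts = _domain_points(term.domain)
                    fvals = term.fixed.values[term.domain.as_bool()]
                else:
                    pts = dlv.grid.index_to_physical(np.argwhere(sel))
                    fvals = flv.values[sel]
                z = pts if initial is None else initial(pts)
                grad = np.stack(np.gradient(mlv.values, *mlv.spacing), axis=0)
                per_level.append(
                    {"z": z, "f": fvals, "mov": mlv, "grad": grad, "n": len(fvals)}
                )
            ssd_levels.append(per_level)
            lm_data.append(None)
        else:
            zf = term.pairs.fixed if initial is None else initial(term.pairs.fixed)
            ssd_levels.append(None)
            lm_data.append({"z": zf, "y": term.pairs.moving, "n": len(term.pairs)})

    # --- validation subsets (deterministic) --------------------------------
    def _validation_cost(level: int = -1) -> float:
        """Deterministic subsample cost at the given pyramid level.

        Coarse levels are judged on their own (smoothed) data: progress on a
        coarse level need not register immediately on the finest level, and
        reverting it there would discard real alignment.
        """
        total = 0.0
        for ti, term in enumerate(terms):
            if wnorm[ti] == 0:
                continue
            if term.kind == "ssd":
                lv = ssd_levels[ti][level]
                stride = max(1, lv["n"] // opt.validation_samples)
                z = lv["z"][::stride]
                f = lv["f"][::stride]
                tz = params.apply(z)
                m = _sample_volume(lv["mov"], tz, fill=term.fill)
                total += wnorm[ti] * float(np.mean((f - m) ** 2))
            else:
                d = lm_data[ti]
                tz = params.apply(d["z"])
                total += wnorm[ti] * float(np.mean(np.linalg.norm(d["y"] - tz, axis=1)))
        return total

    initial_cost = _validation_cost()
    p_init = params.get()  # initial parameters; also the polish penalty anchor
    if not np.isfinite(initial_cost):
        raise RuntimeError("non-finite initial cost")

    k_global = 0  # decay continues across levels so late steps stay small
    for level in range(len(factors)):
        best_cost = _validation_cost(level)
        best_p = params.get()
        run_max = 0.0
        for _k_level in range(opt.iterations_per_level):
            k = k_global
            k_global += 1
            g = np.zeros_like(params.get())
            for ti, term in enumerate(terms):
                if wnorm[ti] == 0:
                    continue
                if term.kind == "ssd":
                    lv = ssd_levels[ti][level]
                    n = min(opt.samples_per_iteration, lv["n"])
                    sel = rng.integers(0, lv["n"], size=n)
                    z = lv["z"][sel]
                    tz = params.apply(z)
                    mov = lv["mov"]
                    idx = mov.grid.physical_to_index(tz).T
                    mvals = ndimage.map_coordinates(
                        mov.values, idx, order=1, mode="constant", cval=term.fill
                    )
                    resid = mvals - lv["f"][sel]
                    gi = np.stack(
                        [
                            ndimage.map_coordinates(lv["grad"][a], idx, order=1, mode="constant")
                            for a in range(3)
                        ],
                        axis=-1,
                    )
                    dLdT = (2.0 * wnorm[ti] / n) * resid[:, None] * gi
                    g += params.gradient(z, dLdT)
                else:
                    d = lm_data[ti]
                    n = min(opt.samples_per_iteration, d["n"])
                    sel = rng.integers(0, d["n"], size=n) if n < d["n"] else slice(None)
                    z = d["z"][sel]
                    tz = params.apply(z)
                    diff = tz - d["y"][sel]
                    norm = np.sqrt((diff**2).sum(axis=1) + _LM_DELTA**2)
                    dLdT = (wnorm[ti] / len(norm)) * diff / norm[:, None]
                    g += params.gradient(z, dLdT)
            if not np.all(np.isfinite(g)):
                raise RuntimeError(f"non-finite gradient at level {level}, iteration {k}")
            gmax = float(np.abs(g).max())
            if gmax <= 0:
                continue  # exactly at a stationary point on this sample
            a_k = opt.step_size_mm * (opt.decay_A / (k + opt.decay_A)) ** opt.decay_alpha
            params.set(params.get() - a_k * g / gmax)
            if (k + 1) % opt.validation_interval == 0:
                c = _validation_cost(level)
                if c < best_cost:
                    best_cost = c
                    best_p = params.get()
        c = _validation_cost(level)
        if c < best_cost:
            best_cost = c
            best_p = params.get()
        params.set(best_p)
        log.append(f"level {level} (factor {factors[level]}): cost {best_cost:.6g}")

    best_cost = _validation_cost()
    best_p = params.get()

    if len(best_p) <= opt.polish_max_params and opt.polish_maxiter > 0:
        # deterministic quasi-Newton finish on the validation subsample
        from scipy.optimize import minimize

        shrink = opt.bspline_shrinkage if isinstance(params, _BSplineParams) else 0.0

        def _fun(p):
            params.set(p)
            dp = p - p_init
            cost = shrink * float(np.mean(dp**2))
            grad = (2.0 * shrink / len(dp)) * dp
            for ti, term in enumerate(terms):
                if wnorm[ti] == 0:
                    continue
                if term.kind == "ssd":
                    lv = ssd_levels[ti][-1]
                    stride = max(1, lv["n"] // opt.validation_samples)
                    z = lv["z"][::stride]
                    f = lv["f"][::stride]
                    tz = params.apply(z)
                    mov = lv["mov"]
                    idx = mov.grid.physical_to_index(tz).T
                    m = ndimage.map_coordinates(
                        mov.values, idx, order=1, mode="constant", cval=term.fill
                    )
                    resid = m - f
                    cost += wnorm[ti] * float(np.mean(resid**2))
                    gi = np.stack(
                        [
                            ndimage.map_coordinates(
                                lv["grad"][a], idx, order=1, mode="constant"
                            )
                            for a in range(3)
                        ],
                        axis=-1,
                    )
                    dLdT = (2.0 * wnorm[ti] / len(resid)) * resid[:, None] * gi
                    grad += params.gradient(z, dLdT)
                else:
                    d = lm_data[ti]
                    tz = params.apply(d["z"])
                    diff = tz - d["y"]
                    norm = np.sqrt((diff**2).sum(axis=1) + _LM_DELTA**2)
                    cost += wnorm[ti] * float(np.mean(norm) - _LM_DELTA)
                    dLdT = (wnorm[ti] / len(norm)) * diff / norm[:, None]
                    grad += params.gradient(d["z"], dLdT)
            return cost, grad

        sol = minimize(
            _fun, best_p, jac=True, method="L-BFGS-B",
            options={"maxiter": opt.polish_maxiter, "ftol": 1e-14, "gtol": 1e-10},
        )
        params.set(sol.x)
        c = _validation_cost()
        if c < best_cost:
            best_cost = c
            best_p = params.get()
            log.append(f"polish: cost {best_cost:.6g}")
        def _cost_only(p):
            params.set(p)
            cost = shrink * float(np.mean((p - p_init) ** 2))
            for ti, term in enumerate(terms):
                if wnorm[ti] == 0:
                    continue
                if term.kind == "ssd":
                    lv = ssd_levels[ti][-1]
                    stride = max(1, lv["n"] // opt.validation_samples)
                    z = lv["z"][::stride]
                    tz = params.apply(z)
                    m = _sample_volume(lv["mov"], tz, fill=term.fill)
                    cost += wnorm[ti] * float(np.mean((lv["f"][::stride] - m) ** 2))
                else:
                    d = lm_data[ti]
                    diff = params.apply(d["z"]) - d["y"]
                    norm = np.sqrt((diff**2).sum(axis=1) + _LM_DELTA**2)
                    cost += wnorm[ti] * float(np.mean(norm) - _LM_DELTA)
            return cost

        if len(best_p) <= 16:
            # trilinear interpolation makes the cost only C0; a derivative-free
            # simplex finish escapes the sub-voxel kinks quasi-Newton stalls on
            nm = minimize(
                _cost_only, best_p, method="Nelder-Mead",
                options={"maxiter": 800, "xatol": 1e-3, "fatol": 1e-12},
            )
            params.set(nm.x)
            c = _validation_cost()
            if c < best_cost:
                best_cost = c
                best_p = params.get()
                log.append(f"simplex finish: cost {best_cost:.6g}")
        params.set(best_p)

    if best_cost > initial_cost:  # final guard on the finest level
        params.set(p_init)
        best_cost = initial_cost
        log.append("reverted to initial parameters (no finest-level improvement)")

    inner = params.transform()
    result_transform = (
        inner if initial is None else CompositeTransform([inner, initial])
    )
    term_costs = tuple(evaluate_term(t, result_transform) for t in terms)
    return StepResult(
        transform=result_transform,
        initial_cost=initial_cost,
        final_cost=best_cost,
        term_costs=term_costs,
        log=log,
    )


# ---------------------------------------------------------------------------
# Step 1: articulated bone registration


def _procrustes_init(fixed: SubjectRecord, moving: SubjectRecord):
    pairs = PointPairs.from_landmarks(fixed.landmarks, moving.landmarks)
    return fit_procrustes(pairs)


def register_bone(fixed: SubjectRecord, moving: SubjectRecord, config: RegistrationConfig):
    """Step 1: per-bodypart affine (B-spline for the torso/spine) on bone DTs.

    Returns ``(results, lm_bone)`` where ``results`` maps bodypart id to its
    :class:`StepResult` and ``lm_bone`` are the sampled bone point pairs.
    """
    sim = _procrustes_init(fixed, moving)
    results: dict[int, StepResult] = {}
    rng = np.random.default_rng([config.seed, 1])
    bone_cfg = replace(config, optimizer=config.bone_optimizer)

    def _box(mask: np.ndarray, ref, margin_mm: float = 48.0):
        idx = np.argwhere(mask)
        spacing = np.asarray(ref.spacing)
        pad = np.ceil(margin_mm / spacing).astype(int)
        lo = np.maximum(idx.min(axis=0) - pad, 0)
        hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
        return lo, hi

    def _crop(mask: np.ndarray, ref, box):
        """Bounding-box crop as a mask volume; Grid origins keep physical
        coordinates consistent, so downstream code is unaffected."""
        lo, hi = box
        sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        origin = np.asarray(ref.origin) + lo * np.asarray(ref.spacing)
        return BinaryMask(sub.astype(np.uint8), ref.spacing, tuple(origin))

    for part in sorted(BODYPART_NAMES):
        name = BODYPART_NAMES[part]
        part_region = fixed.bodyparts.values == part
        if not part_region.any():
            raise ValueError(f"bodypart {name!r} is empty in the fixed subject")
        seg_f = fixed.bone.as_bool() & part_region
        seg_m = moving.bone.as_bool() & (moving.bodyparts.values == part)
        if not seg_f.any():
            raise ValueError(f"no bone voxels in bodypart {name!r} of the fixed subject")
        if not seg_m.any():
            raise ValueError(f"no bone voxels in bodypart {name!r} of the moving subject")
        # Distance transforms of this section's bone only (a neighbouring
        # section's motion must not perturb this section's cost), computed on
        # a bounding-box crop: distances far from the section are never
        # sampled, and the crop keeps the per-section cost cheap.
        box_f = _box(part_region, fixed.bodyparts)
        domain = _crop(part_region, fixed.bodyparts, box_f)
        dt_f = distance_transform(_crop(seg_f, fixed.bone, box_f))
        # the moving crop must cover everywhere the domain can plausibly map,
        # so take the union of both sections' boxes
        box_m = _box(seg_m, moving.bone)
        box_u = (np.minimum(box_f[0], box_m[0]), np.maximum(box_f[1], box_m[1]))
        dt_m = distance_transform(_crop(seg_m, moving.bone, box_u))
        lm_names = PART_LANDMARKS[part]
        pairs = PointPairs(
            fixed.landmarks.array(lm_names), moving.landmarks.array(lm_names)
        )
        terms = [
            # outside the moving crop the distance to this section's bone is
            # at least the crop margin
            CostTerm("ssd", fixed=dt_f, moving=dt_m, domain=domain, fill=48.0),
            CostTerm("landmark", pairs=pairs),
        ]
        pts = _domain_points(domain)
        center = pts.mean(axis=0)
        radius = float(np.linalg.norm(pts - center, axis=1).mean())
        params = _AffineParams(sim(center), radius)
        res = optimize_step(terms, config.w_bone, params, bone_cfg, rng, initial=sim)
        if part == SPINE_PART or config.elastic_bone_sections:
            # a slightly elastic deformation composed onto the section's
            # affine (always used for the spine, whose articulation is not
            # affine; for long bones it refines the within-section residual
            # so that the LM_BONE pairs sampled below are not biased by the
            # affine approximation)
            z = res.transform(pts)
            lo, hi = z.min(axis=0), z.max(axis=0)
            bspl = BSplineTransform.zero(lo, hi, config.grid_spine_mm)
            res = optimize_step(
                terms, config.w_bone, _BSplineParams(bspl), bone_cfg, rng,
                initial=res.transform,
            )
        results[part] = res

    segments = LabelVolume(
        fixed.bodyparts.values * fixed.bone.values,
        fixed.bodyparts.spacing,
        fixed.bodyparts.origin,
    )
    lm_bone = sample_bone_pairs(
        segments,
        {p: r.transform for p, r in results.items()},
        config.n_bone_pairs_per_segment,
        np.random.default_rng([config.seed, 2]),
    )
    return results, lm_bone


def sample_bone_pairs(
    bone_segments: LabelVolume,
    transforms: dict,
    n_per_segment: int,
    rng: np.random.Generator,
) -> PointPairs:
    """Uniform random points in each fixed bone segment, mapped to the moving
    image by that segment's transform; provenance ``LM_BONE``."""
    labels = bone_segments.labels()
    if labels.size == 0:
        raise ValueError("no bone segments to sample from")
    grid = bone_segments.grid
    fixed_pts = []
    moving_pts = []
    for lab in labels:
        idx = np.argwhere(bone_segments.values == lab)
        replace_draw = len(idx) < n_per_segment
        if replace_draw:
            warnings.warn(
                f"bone segment {int(lab)} has {len(idx)} voxels < {n_per_segment}; "
                "sampling with replacement"
            )
        sel = rng.choice(len(idx), size=n_per_segment, replace=True)
        jitter = rng.uniform(-0.5, 0.5, size=(n_per_segment, 3))
        pts = grid.index_to_physical(idx[sel] + jitter)
        fixed_pts.append(pts)
        moving_pts.append(transforms[int(lab)](pts))
    return PointPairs(
        np.concatenate(fixed_pts), np.concatenate(moving_pts), provenance="LM_BONE"
    )


# ---------------------------------------------------------------------------
# Step 2: water registration


def register_water(
    fixed: SubjectRecord,
    moving: SubjectRecord,
    lm_bone: PointPairs,
    config: RegistrationConfig,
):
    """Step 2: whole-body 64 mm B-spline on water content, constrained by
    ``LM_BONE``.  Returns ``(StepResult, lm_water)``."""
    if len(lm_bone) == 0:
        raise ValueError("LM_BONE is empty")
    sim = _procrustes_init(fixed, moving)
    rng = np.random.default_rng([config.seed, 3])
    terms = [
        CostTerm("ssd", fixed=fixed.water, moving=moving.water, domain=fixed.body),
        CostTerm("landmark", pairs=lm_bone),
    ]
    pts = _domain_points(fixed.body)
    z = sim(pts)
    bspl = BSplineTransform.zero(z.min(axis=0), z.max(axis=0), config.grid_water_mm)
    res = optimize_step(terms, config.w_water, _BSplineParams(bspl), config, rng, initial=sim)

    eligible = np.argwhere((fixed.water.values > config.water_cutoff) & fixed.body.as_bool())
    if len(eligible) == 0:
        raise ValueError("no voxels with high water signal to sample LM_WATER from")
    if len(eligible) < config.n_water_pairs:
        warnings.warn(
            f"only {len(eligible)} high-water voxels < {config.n_water_pairs}; "
            "sampling with replacement"
        )
    rng_w = np.random.default_rng([config.seed, 4])
    sel = rng_w.choice(len(eligible), size=config.n_water_pairs, replace=True)
    jitter = rng_w.uniform(-0.5, 0.5, size=(config.n_water_pairs, 3))
    fpts = fixed.grid.index_to_physical(eligible[sel] + jitter)
    lm_water = PointPairs(fpts, res.transform(fpts), provenance="LM_WATER")
    res.pairs = lm_water
    return res, lm_water


# ---------------------------------------------------------------------------
# Step 3: fat registration


def register_fat(
    fixed: SubjectRecord,
    moving: SubjectRecord,
    lm_bone: PointPairs,
    lm_water: PointPairs,
    config: RegistrationConfig,
    water_transform: SpatialTransform | None = None,
) -> StepResult:
    """Step 3: whole-body 32 mm B-spline on fat content + body-mask agreement,
    constrained by ``LM_BONE`` and ``LM_WATER``.

    Initialized by refining the water-step control grid to the fat grid
    spacing when ``water_transform`` is given (a composite whose elastic part
    is a B-spline); this transform is the final fixed→moving mapping.
    """
    if len(lm_bone) == 0 or len(lm_water) == 0:
        raise ValueError("both LM_BONE and LM_WATER are required")
    sim = _procrustes_init(fixed, moving)
    rng = np.random.default_rng([config.seed, 5])
    body_f = ScalarVolume.like(fixed.body, fixed.body.values * 100.0)
    body_m = ScalarVolume.like(moving.body, moving.body.values * 100.0)
    terms = [
        CostTerm("ssd", fixed=fixed.fat, moving=moving.fat, domain=fixed.body),
        CostTerm("ssd", fixed=body_f, moving=body_m, domain=fixed.body),
        CostTerm("landmark", pairs=lm_bone),
        CostTerm("landmark", pairs=lm_water),
    ]
    bspl = None
    if water_transform is not None:
        elastic = water_transform
        if isinstance(elastic, CompositeTransform):
            elastic = next(
                (t for t in elastic.transforms if isinstance(t, BSplineTransform)), None
            )
        if isinstance(elastic, BSplineTransform):
            bspl = elastic.refine(config.grid_fat_mm)
    if bspl is None:
        pts = _domain_points(fixed.body)
        z = sim(pts)
        bspl = BSplineTransform.zero(z.min(axis=0), z.max(axis=0), config.grid_fat_mm)
    return optimize_step(terms, config.w_fat, _BSplineParams(bspl), config, rng, initial=sim)


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class WholeBodyResult:
    """Final fixed→moving mapping plus all per-step diagnostics."""

    transform: SpatialTransform
    bone_results: dict
    water_result: StepResult
    fat_result: StepResult
    lm_bone: PointPairs
    lm_water: PointPairs


def register_whole_body(
    fixed: SubjectRecord, moving: SubjectRecord, config: RegistrationConfig | None = None
) -> WholeBodyResult:
    """Run steps 1→3; the step-3 transform maps the fixed (common) coordinate
    system into the moving subject and is used to resample the subject."""
    if config is None:
        config = RegistrationConfig()
    bone_results, lm_bone = register_bone(fixed, moving, config)
    water_result, lm_water = register_water(fixed, moving, lm_bone, config)
    fat_result = register_fat(
        fixed, moving, lm_bone, lm_water, config, water_transform=water_result.transform
    )
    return WholeBodyResult(
        transform=fat_result.transform,
        bone_results=bone_results,
        water_result=water_result,
        fat_result=fat_result,
        lm_bone=lm_bone,
        lm_water=lm_water,
    )
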