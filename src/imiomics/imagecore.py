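"""Volume containers and the geometric primitives shared by all modules.

Volumes live on regular 3-D grids with anisotropic physical spacing.  All
coordinates handed between modules are physical millimetres; voxel indices
are 0-based and map to physical space through ``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import nibabel as nib
from scipy import ndimage


@dataclass(frozen=True)
class Grid:
    """Regular 3-D sampling grid: shape (voxels), spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return self.origin + idx * self.spacing

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.origin) / self.spacing

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center physical coordinates, shape ``(*shape, 3)``."""
        ii = [np.arange(n) for n in self.shape]
        idx = np.stack(np.meshgrid(*ii, indexing="ij"), axis=-1)
        return self.index_to_physical(idx)

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box (low corner, high corner) of voxel centers."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi


@dataclass
class ScalarVolume:
    """One scalar per voxel on a :class:`Grid`.

    Depending on role the values are fat/water content (percent, 0-100),
    P-values, correlation coefficients or Jacobian determinants.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def grid(self) -> Grid:
        return Grid(self.values.shape, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def same_geometry(self, other: "ScalarVolume", atol: float = 1e-6) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy(self) -> "ScalarVolume":
        return type(self)(self.values.copy(), self.spacing, self.origin)

    @classmethod
    def like(cls, other: "ScalarVolume", values: np.ndarray) -> "ScalarVolume":
        return cls(values, other.spacing, other.origin)


class BinaryMask(ScalarVolume):
    """Volume whose values are exactly 0 or 1 (body mask, bone mask, ...)."""

    def __post_init__(self):
        super().__post_init__()
        vals = np.unique(self.values)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("mask values must be exactly 0 or 1")
        self.values = self.values.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)


class LabelVolume(ScalarVolume):
    """Integer label per voxel; 0 = background, 1..9 = bodyparts/bone segments."""

    def __post_init__(self):
        ScalarVolume.__post_init__(self)
        if not np.allclose(self.values, np.round(self.values)):
            raise ValueError("labels must be integers")
        self.values = np.round(self.values).astype(np.int32)

    def labels(self) -> np.ndarray:
        lab = np.unique(self.values)
        return lab[lab != 0]

    def region(self, label: int) -> BinaryMask:
        return BinaryMask((self.values == label).astype(np.uint8), self.spacing, self.origin)


# ---------------------------------------------------------------------------
# Sampling


def interpolate(
    volume: ScalarVolume,
    points: np.ndarray,
    mode: str = "linear",
    fill: float = 0.0,
) -> np.ndarray:
    """Sample ``volume`` at physical points (mm).

    ``mode`` is ``"linear"`` (trilinear) or ``"nearest"``.  Points outside the
    grid return ``fill`` (default 0, the MR background).  Accepts a single
    point or an ``(..., 3)`` array; returns matching shape.
    """
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite sample point")
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 3:
        raise ValueError("points must have three components")
    order = {"linear": 1, "nearest": 0}[mode]
    idx = volume.grid.physical_to_index(pts.reshape(-1, 3))
    out = ndimage.map_coordinates(
        volume.values.astype(float), idx.T, order=order, mode="constant", cval=fill
    )
    out = out.reshape(pts.shape[:-1])
    return float(out[0]) if single else out


def resample(
    volume: ScalarVolume,
    transform,
    reference: Grid,
    mode: str = "linear",
    fill: float = 0.0,
) -> ScalarVolume:
    """Pull ``volume`` (moving) onto ``reference`` through a fixed-to-moving map.

    Each output voxel at fixed-space center ``x`` holds ``volume`` sampled at
    ``T(x)``; ``transform=None`` means identity.
    """
    if any(n <= 0 for n in reference.shape):
        raise ValueError("reference grid has a zero-size axis")
    centers = reference.voxel_centers().reshape(-1, 3)
    if transform is not None:
        centers = transform.apply(centers)
    vals = interpolate(volume, centers, mode=mode, fill=fill)
    out = vals.reshape(reference.shape)
    cls = type(volume)
    if cls is BinaryMask and mode == "linear":
        cls = ScalarVolume  # linear sampling breaks the 0/1 invariant
    return cls(out, reference.spacing, reference.origin)


def distance_transform(mask: BinaryMask) -> ScalarVolume:
    """Euclidean distance (mm) to the nearest object voxel, 0 inside objects.

    Anisotropic spacing is honoured; an empty mask has no defined distance
    and raises.
    """
    obj = mask.as_bool()
    if not obj.any():
        raise ValueError("distance transform of an empty mask is undefined")
    dist = ndimage.distance_transform_edt(~obj, sampling=mask.spacing)
    return ScalarVolume(dist, mask.spacing, mask.origin)


def threshold_mask(volume: ScalarVolume, cutoff: float) -> BinaryMask:
    """Binary mask of voxels with value strictly greater than ``cutoff`` (%)."""
    if not 0 < cutoff < 100:
        raise ValueError("cutoff must lie in (0, 100)")
    return BinaryMask((volume.values > cutoff).astype(np.uint8), volume.spacing, volume.origin)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    if not a.same_geometry(b):
        raise ValueError("dice requires masks on the same grid")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.as_bool() & b.as_bool()))
    return 2.0 * inter / (na + nb)


# ---------------------------------------------------------------------------
# NIfTI I/O


def write_nifti(volume: ScalarVolume, path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    data = volume.values
    if isinstance(volume, BinaryMask):
        data = data.astype(np.uint8)
    elif isinstance(volume, LabelVolume):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_nifti(path, kind: type = ScalarVolume) -> ScalarVolume:
    img = nib.load(str(path))
    affine = img.affine
    lin = affine[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-4):
        raise ValueError(f"{path}: oblique acquisitions are not supported")
    spacing = tuple(np.abs(np.diag(lin)))
    origin = tuple(affine[:3, 3])
    return kind(np.asanyarray(img.dataobj).astype(float), spacing, origin)
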