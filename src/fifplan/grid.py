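"""Voxel grid container, mask morphology, and the plain grid file format.

The whole toolkit works on axis-aligned voxel grids in a fixed patient
coordinate frame: x = patient-left, y = patient-anterior, z = patient-superior,
all in millimetres.  A :class:`VoxelGrid` carries a 3D scalar array indexed
``values[ix, iy, iz]`` together with the world position of the first voxel
centre (``origin``) and the per-axis voxel pitch (``spacing``).  The same
container holds densities (g/cm³ analog), doses (Gy) and binary masks {0, 1}.

Uniform expansions and erosions of binary masks are Euclidean, implemented on
the exact distance transform, so a 3 cm expansion really is the set of points
within 3 cm of the mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class GridError(ValueError):
    """Raised for invalid grid construction or incompatible grid algebra."""


@dataclass
class VoxelGrid:
    """A 3D scalar field on a regular grid.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)``; densities, dose in Gy, or a
        binary mask containing only {0, 1}.
    origin
        World coordinates (mm) of the centre of voxel ``(0, 0, 0)``.
    spacing
        Voxel pitch (mm) per axis; strictly positive.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.values.ndim != 3:
            raise GridError("VoxelGrid requires a 3D array")
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise GridError("origin and spacing must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise GridError("spacing must be strictly positive on all axes")

    # -- basic geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def world_points(self, index_mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of voxel centres; optionally only where mask>0."""
        if index_mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(index_mask)
        return self.origin + idx * self.spacing

    def like(self, values: np.ndarray) -> "VoxelGrid":
        """A new grid with the same frame and the given values."""
        if values.shape != self.shape:
            raise GridError("values shape does not match grid shape")
        return VoxelGrid(values, self.origin.copy(), self.spacing.copy())

    def zeros_like(self, dtype=float) -> "VoxelGrid":
        return self.like(np.zeros(self.shape, dtype=dtype))

    def compatible(self, other: "VoxelGrid") -> bool:
        """Grid-algebra compatibility: identical frame and shape."""
        return (
            self.shape == other.shape
            and np.array_equal(self.origin, other.origin)
            and np.array_equal(self.spacing, other.spacing)
        )

    def require_compatible(self, other: "VoxelGrid") -> None:
        if not self.compatible(other):
            raise GridError("grids are not algebra-compatible (origin/spacing/shape differ)")

    # -- mask helpers -------------------------------------------------------

    def as_bool(self) -> np.ndarray:
        vals = np.unique(self.values)
        if not np.all(np.isin(vals, (0, 1))):
            raise GridError("mask grid must contain only {0, 1}")
        return self.values.astype(bool)

    def checksum(self) -> str:
        """Order-stable content hash: frame plus raw voxel bytes."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.origin).tobytes())
        h.update(np.ascontiguousarray(self.spacing).tobytes())
        h.update(str(self.values.dtype).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()


def expand_mask(mask: VoxelGrid, margin_mm: float) -> VoxelGrid:
    """Uniform Euclidean expansion of a binary mask by ``margin_mm``.

    The result contains every voxel whose centre lies within ``margin_mm`` of
    some voxel centre of the input (exact Euclidean distance transform with
    anisotropic spacing).
    """
    if margin_mm < 0:
        raise GridError("expansion margin must be non-negative")
    m = mask.as_bool()
    if margin_mm == 0 or not m.any():
        return mask.like(m.astype(np.uint8))
    dist = ndimage.distance_transform_edt(~m, sampling=mask.spacing)
    return mask.like((dist <= margin_mm).astype(np.uint8))


def erode_mask(mask: VoxelGrid, margin_mm: float) -> VoxelGrid:
    """Uniform Euclidean erosion by ``margin_mm``.

    Keeps voxels whose distance to the nearest outside voxel centre exceeds
    the margin.  An erosion that empties the mask returns an empty mask and
    emits a warning rather than raising.
    """
    if margin_mm < 0:
        raise GridError("erosion margin must be non-negative")
    m = mask.as_bool()
    if margin_mm == 0 or not m.any():
        return mask.like(m.astype(np.uint8))
    dist = ndimage.distance_transform_edt(m, sampling=mask.spacing)
    out = dist > margin_mm
    if m.any() and not out.any():
        warnings.warn("erosion emptied the mask", stacklevel=2)
    return mask.like(out.astype(np.uint8))


def mask_union(*masks: VoxelGrid) -> VoxelGrid:
    base = masks[0]
    acc = base.as_bool().copy()
    for m in masks[1:]:
        base.require_compatible(m)
        acc |= m.as_bool()
    return base.like(acc.astype(np.uint8))


def mask_intersection(*masks: VoxelGrid) -> VoxelGrid:
    base = masks[0]
    acc = base.as_bool().copy()
    for m in masks[1:]:
        base.require_compatible(m)
        acc &= m.as_bool()
    return base.like(acc.astype(np.uint8))


def mask_difference(a: VoxelGrid, b: VoxelGrid) -> VoxelGrid:
    a.require_compatible(b)
    return a.like((a.as_bool() & ~b.as_bool()).astype(np.uint8))


# -- grid file format -------------------------------------------------------
#
# Plain interchange format: one ASCII magic line, one JSON header line
# (shape, origin, spacing, dtype), then the raw little-endian C-order payload.

_MAGIC = b"FIFGRID1\n"


def save_grid(grid: VoxelGrid, path) -> None:
    arr = np.ascontiguousarray(grid.values)
    header = {
        "shape": list(arr.shape),
        "origin": grid.origin.tolist(),
        "spacing": grid.spacing.tolist(),
        "dtype": arr.dtype.newbyteorder("<").str,
    }
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write((json.dumps(header, sort_keys=True) + "\n").encode())
        fh.write(arr.astype(arr.dtype.newbyteorder("<")).tobytes())


def load_grid(path) -> VoxelGrid:
    with open(path, "rb") as fh:
        magic = fh.readline()
        if magic != _MAGIC:
            raise GridError(f"not a grid file: {path}")
        header = json.loads(fh.readline().decode())
        payload = fh.read()
    arr = np.frombuffer(payload, dtype=np.dtype(header["dtype"]))
    arr = arr.reshape(header["shape"]).astype(np.dtype(header["dtype"]).newbyteorder("="))
    return VoxelGrid(arr, np.array(header["origin"]), np.array(header["spacing"]))
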