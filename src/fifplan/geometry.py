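"""Beams, the beam's-eye-view (BEV) frame, ray-trace projection, and DRRs.

Machine convention (IEC-style, coplanar): the source sits at
``isocenter + SAD * (sin g, cos g, 0)`` for gantry angle ``g`` in degrees, so
gantry 0 is anterior, 90 patient-left, 180 posterior, 270 patient-right.
The BEV frame lives on the isocentric plane (through the isocenter,
perpendicular to the beam axis): BEV-y is patient-superior for every coplanar
beam; BEV-x completes the frame as ``ẑ × â`` with â the source→isocenter
direction.  A point at distance d from the source along the axis projects
with divergent magnification SAD/d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid


class BeamError(ValueError):
    pass


MAX_FIELD_MM = 400.0  # maximum aperture bounding square (mm at isoplane)


@dataclass
class Wedge:
    """Physical wedge: nominal isodose tilt angle and heel direction.

    ``heel`` is the sign of the BEV-x direction toward the thick end; dose is
    reduced on the heel side.
    """

    angle_deg: float
    heel: int = +1  # +1: heel toward +BEV-x, -1: toward -BEV-x

    def mirrored(self) -> "Wedge":
        return Wedge(self.angle_deg, -self.heel)


@dataclass
class MLCModel:
    """Leaf-pair layout along BEV-y (a standard 120-leaf Millennium MLC).

    60 pairs spanning 400 mm: ten 10 mm peripheral pairs, forty 5 mm central
    pairs, ten 10 mm peripheral pairs.  Leaves travel along BEV-x within
    ``travel_mm``.
    """

    boundaries: np.ndarray = field(default_factory=lambda: _millennium_boundaries())
    travel_mm: float = 200.0

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if np.any(np.diff(b) <= 0):
            raise BeamError("leaf boundaries must be strictly increasing")
        self.boundaries = b

    @property
    def n_pairs(self) -> int:
        return len(self.boundaries) - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.boundaries[:-1] + self.boundaries[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    def pair_index(self, y_mm: np.ndarray) -> np.ndarray:
        """Leaf-pair index containing each BEV-y value (clipped to range)."""
        idx = np.searchsorted(self.boundaries, y_mm, side="right") - 1
        return np.clip(idx, 0, self.n_pairs - 1)


def _millennium_boundaries() -> np.ndarray:
    outer = np.arange(-200.0, -100.0, 10.0)
    central = np.arange(-100.0, 100.0, 5.0)
    outer2 = np.arange(100.0, 200.0 + 1e-9, 10.0)
    return np.concatenate([outer, central, outer2])


@dataclass
class Beam:
    """One treatment field (or FIF subfield referencing a parent beam)."""

    id: str
    role: str  # PA | LT | RT | AP | BstLT | BstRT | subfield
    gantry_angle: float
    isocenter: np.ndarray
    source_axis_distance: float = 1000.0
    jaws: tuple[float, float, float, float] | None = None  # (x1, x2, y1, y2) mm
    mlc_a: np.ndarray | None = None  # bank A (low-x) positions per pair
    mlc_b: np.ndarray | None = None  # bank B (high-x)
    wedge: Wedge | None = None
    weight: float = 0.0
    parent_id: str | None = None

    def __post_init__(self) -> None:
        self.isocenter = np.asarray(self.isocenter, dtype=float)
        if not (0 <= self.gantry_angle < 360):
            raise BeamError("gantry angle must be in [0, 360)")
        if self.source_axis_distance <= 0:
            raise BeamError("SAD must be positive")
        if self.mlc_a is not None and self.mlc_b is not None:
            if np.any(np.asarray(self.mlc_a) > np.asarray(self.mlc_b) + 1e-9):
                raise BeamError("MLC bank collision: bank A must not pass bank B")

    @property
    def sad(self) -> float:
        return self.source_axis_distance


def source_position(beam: Beam) -> np.ndarray:
    g = np.deg2rad(beam.gantry_angle)
    return beam.isocenter + beam.sad * np.array([np.sin(g), np.cos(g), 0.0])


def beam_axis(beam: Beam) -> np.ndarray:
    """Unit vector from source toward the isocenter."""
    g = np.deg2rad(beam.gantry_angle)
    return -np.array([np.sin(g), np.cos(g), 0.0])


def bev_frame(beam: Beam) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(x̂_bev, ŷ_bev, â): orthonormal BEV axes and the beam axis."""
    a = beam_axis(beam)
    y_hat = np.array([0.0, 0.0, 1.0])
    x_hat = np.cross(y_hat, a)
    n = np.linalg.norm(x_hat)
    if n < 1e-12:
        raise BeamError("non-coplanar beam axis")
    return x_hat / n, y_hat, a


def project_points(points: np.ndarray, beam: Beam) -> np.ndarray:
    """Divergent projection of world points onto the isocentric plane.

    Returns (N, 2) BEV mm.  Raises for points at or behind the source plane.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    src = source_position(beam)
    x_hat, y_hat, a = bev_frame(beam)
    v = pts - src
    d = v @ a
    if np.any(d <= 1e-9):
        raise BeamError("point at or behind the source")
    scale = beam.sad / d
    return np.stack([(v @ x_hat) * scale, (v @ y_hat) * scale], axis=-1)


def project_point(point, beam: Beam) -> np.ndarray:
    return project_points(np.asarray(point)[None, :], beam)[0]


@dataclass
class Aperture2D:
    """Binary field shape on the isocentric plane.

    ``mask[i, j]`` covers BEV pixel centre
    ``(x, y) = ((i + 0.5) px - half, (j + 0.5) px - half)``.
    """

    mask: np.ndarray
    pixel_mm: float = 2.0
    half_mm: float = MAX_FIELD_MM / 2

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        n = int(round(2 * self.half_mm / self.pixel_mm))
        if self.mask.shape != (n, n):
            raise BeamError("aperture mask shape inconsistent with extent")

    @classmethod
    def blank(cls, pixel_mm: float = 2.0, half_mm: float = MAX_FIELD_MM / 2) -> "Aperture2D":
        n = int(round(2 * half_mm / pixel_mm))
        return cls(np.zeros((n, n), dtype=np.uint8), pixel_mm, half_mm)

    @property
    def n(self) -> int:
        return self.mask.shape[0]

    def coords(self) -> np.ndarray:
        return -self.half_mm + self.pixel_mm * (np.arange(self.n) + 0.5)

    def to_index(self, mm: np.ndarray) -> np.ndarray:
        """Continuous pixel index of BEV mm values (centre of pixel i at i)."""
        return (np.asarray(mm) + self.half_mm) / self.pixel_mm - 0.5

    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.pixel_mm**2

    def bbox_mm(self) -> tuple[float, float, float, float] | None:
        """(x_min, x_max, y_min, y_max) over pixel *edges*; None if empty."""
        if not self.mask.any():
            return None
        ii, jj = np.nonzero(self.mask)
        px, h = self.pixel_mm, self.half_mm
        return (
            ii.min() * px - h,
            (ii.max() + 1) * px - h,
            jj.min() * px - h,
            (jj.max() + 1) * px - h,
        )

    def extent_x(self) -> tuple[float, float] | None:
        bb = self.bbox_mm()
        return None if bb is None else (bb[0], bb[1])

    def extent_y(self) -> tuple[float, float] | None:
        bb = self.bbox_mm()
        return None if bb is None else (bb[2], bb[3])

    def polygon(self) -> list[tuple[float, float]]:
        """Ordered boundary vertices (mm), for export to a planning system."""
        padded = np.zeros((self.n + 2, self.n + 2), dtype=np.uint8)
        padded[1:-1, 1:-1] = self.mask
        # marching around the boundary of the largest component via contour
        from skimage import measure  # local import: only needed for export

        contours = measure.find_contours(padded.astype(float), 0.5)
        if not contours:
            return []
        contour = max(contours, key=len)
        px, h = self.pixel_mm, self.half_mm
        return [((i - 1 + 0.5) * px - h, (j - 1 + 0.5) * px - h) for i, j in contour]


def project_mask(
    mask: VoxelGrid,
    beam: Beam,
    truncate_distal: bool = False,
    pixel_mm: float = 2.0,
) -> Aperture2D:
    """Project a 3D binary mask onto the isocentric plane.

    Every masked voxel's eight corners are projected and the voxel's BEV
    bounding box is filled — a conservative footprint (identical to the
    convex-hull footprint for cardinal coplanar gantry angles, a superset
    otherwise).  With ``truncate_distal`` set, voxels whose along-axis source
    distance exceeds the SAD (i.e. distal to the isocentric plane) are
    removed before projection.
    """
    ap = Aperture2D.blank(pixel_mm=pixel_mm)
    m = mask.as_bool()
    if not m.any():
        return ap
    pts = mask.world_points(m)
    if truncate_distal:
        src = source_position(beam)
        _, _, a = bev_frame(beam)
        d = (pts - src) @ a
        pts = pts[d <= beam.sad]
        if len(pts) == 0:
            return ap
    half = 0.5 * mask.spacing
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
    ) * half
    n = ap.n
    lo = np.full((len(pts), 2), np.inf)
    hi = np.full((len(pts), 2), -np.inf)
    for c in corners:
        bev = project_points(pts + c, beam)
        np.minimum(lo, bev, out=lo)
        np.maximum(hi, bev, out=hi)
    i0 = np.clip(np.floor(ap.to_index(lo[:, 0]) + 0.5).astype(int), 0, n)
    i1 = np.clip(np.ceil(ap.to_index(hi[:, 0]) + 0.5).astype(int), 0, n)
    j0 = np.clip(np.floor(ap.to_index(lo[:, 1]) + 0.5).astype(int), 0, n)
    j1 = np.clip(np.ceil(ap.to_index(hi[:, 1]) + 0.5).astype(int), 0, n)
    out = np.zeros((n, n), dtype=np.uint8)
    for a0, a1, b0, b1 in zip(i0, i1, j0, j1):
        if a1 > a0 and b1 > b0:
            out[a0:a1, b0:b1] = 1
    ap.mask = out
    return ap


def project_landmark(point, beam: Beam) -> np.ndarray:
    """Convenience: BEV coordinates (mm) of one named world point."""
    return project_point(point, beam)


def generate_drr(
    density: VoxelGrid,
    beam: Beam,
    pixel_mm: float = 4.0,
    step_mm: float = 2.0,
    half_mm: float = MAX_FIELD_MM / 2,
) -> np.ndarray:
    """Digitally reconstructed radiograph: per-pixel density line integral.

    Each isoplane pixel's value is the ray sum of density (g/cm³ · mm) from
    the source through that pixel, sampled every ``step_mm`` by trilinear
    interpolation.  Purely geometric — no energy model.
    """
    n = int(round(2 * half_mm / pixel_mm))
    coords = -half_mm + pixel_mm * (np.arange(n) + 0.5)
    src = source_position(beam)
    x_hat, y_hat, a = bev_frame(beam)
    XX, YY = np.meshgrid(coords, coords, indexing="ij")
    pix_world = (
        beam.isocenter[None, None, :]
        + XX[..., None] * x_hat[None, None, :]
        + YY[..., None] * y_hat[None, None, :]
    )
    dirs = pix_world - src
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)

    # march from upstream of the volume to past the isoplane
    diag = float(np.linalg.norm(np.array(density.shape) * density.spacing))
    t0 = beam.sad - 0.6 * diag
    t1 = beam.sad + 0.6 * diag
    ts = np.arange(t0, t1, step_mm)
    image = np.zeros((n, n))
    for t in ts:  # chunked along the ray to bound memory
        pts = src + t * dirs
        idx = (pts - density.origin) / density.spacing
        vals = ndimage.map_coordinates(
            density.values, idx.reshape(-1, 3).T, order=1, mode="constant", cval=0.0
        )
        image += vals.reshape(n, n)
    return image * step_mm
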