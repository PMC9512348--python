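"""Synthetic pelvis phantoms for exercising the planning chain.

A phantom is an elliptic-cylinder "body" of unit-density soft tissue with
analytic bony structures (sacrum, iliac wings), a spherical gross tumor
volume (GTV) in the presacral space, an optional nodal volume (GTVn), and
optional bowel-gas pockets.  Because the geometry is analytic, the bony
landmarks the aperture rules consume (L5/S1 junction, obturator foramen
bottom, pelvic brim, sacral extents) are specification parameters rather than
image-derived features, which makes every downstream rule exactly testable.

Densities are analog g/cm³: air 0, soft tissue 1.0, cortical bone shell 1.8
over a trabecular interior of 1.08 (an elderly, often osteopenic pelvis).
Identical specs (including the seed) produce bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .grid import VoxelGrid, expand_mask, erode_mask  # noqa: F401  (re-export)


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is geometrically invalid."""


@dataclass
class LandmarkSet:
    """Named bony landmarks in world mm.

    All points lie inside the body; the L5/S1 junction is superior to the
    obturator foramen bottom by construction.
    """

    L5S1_junction: np.ndarray
    obturator_foramen_bottom: np.ndarray
    pelvic_brim_left: np.ndarray
    pelvic_brim_right: np.ndarray
    sacrum_posterior_extent: np.ndarray
    sacral_promontory_anterior: np.ndarray
    sacrum_superior: float
    sacrum_inferior: float

    def __post_init__(self) -> None:
        for name in (
            "L5S1_junction",
            "obturator_foramen_bottom",
            "pelvic_brim_left",
            "pelvic_brim_right",
            "sacrum_posterior_extent",
            "sacral_promontory_anterior",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not self.L5S1_junction[2] > self.obturator_foramen_bottom[2]:
            raise PhantomSpecError("L5/S1 junction must be superior to obturator foramen bottom")

    def as_dict(self) -> dict:
        d = asdict(self)
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic pelvis.  Defaults give the reference phantom.

    Sizes follow typical adult pelvis dimensions: body half-width 170 mm,
    half-thickness 125 mm, 240 mm of scanned length at 2.5 mm isotropic
    voxels (a conventional dose-grid scale).
    """

    shape: tuple[int, int, int] = (144, 112, 96)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    body_halfwidth_mm: float = 170.0    # x semi-axis
    body_halfthickness_mm: float = 125.0  # y semi-axis
    # sacrum slab (posterior midline bone, thin cortical-equivalent shell)
    sacrum_halfwidth_mm: float = 55.0
    sacrum_posterior_y: float = -85.0
    sacrum_z_range: tuple[float, float] = (-55.0, 85.0)
    sacrum_anterior_y_top: float = -42.0   # promontory level
    sacrum_anterior_y_bottom: float = -62.0
    # iliac wings
    iliac_center_x: float = 107.0
    iliac_radii_mm: tuple[float, float, float] = (20.0, 70.0, 65.0)
    iliac_center_yz: tuple[float, float] = (-15.0, 15.0)
    # landmarks not tied to modeled bone (brim = pelvic inlet half-width)
    pelvic_brim_x: float = 68.0
    obturator_bottom_z: float = -60.0
    # targets
    gtv_center: tuple[float, float, float] = (0.0, -38.0, 5.0)
    gtv_radius_mm: float = 22.0
    gtvn_center: tuple[float, float, float] = (30.0, -35.0, 45.0)
    gtvn_radius_mm: float = 14.0
    # bowel gas
    n_air_pockets: int = 0
    air_pocket_radius_mm: float = 12.0
    seed: int = 0

    bone_density: float = 1.8        # cortical shell
    trabecular_density: float = 1.08  # cancellous interior (elderly, osteopenic)
    cortical_thickness_mm: float = 2.0
    tissue_density: float = 1.0


def _coord_grids(spec: PhantomSpec):
    nx, ny, nz = spec.shape
    sp = np.asarray(spec.spacing_mm, dtype=float)
    origin = -0.5 * sp * (np.array(spec.shape) - 1)
    xs = origin[0] + sp[0] * np.arange(nx)
    ys = origin[1] + sp[1] * np.arange(ny)
    zs = origin[2] + sp[2] * np.arange(nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    return origin, sp, X, Y, Z


def _sphere(X, Y, Z, center, radius) -> np.ndarray:
    cx, cy, cz = center
    return (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= radius**2


def generate_phantom(spec: PhantomSpec):
    """Build density, body/GTV/GTVn masks and landmarks from a spec.

    Returns
    -------
    (density, body, gtv, gtvn, landmarks)
        Four :class:`VoxelGrid` objects on the same frame and a
        :class:`LandmarkSet`.
    """
    origin, sp, X, Y, Z = _coord_grids(spec)

    body = (X / spec.body_halfwidth_mm) ** 2 + (Y / spec.body_halfthickness_mm) ** 2 <= 1.0

    # sacrum: midline slab, posterior face flat, anterior face sloping forward
    # toward the promontory at the top
    z0, z1 = spec.sacrum_z_range
    frac = np.clip((Z - z0) / (z1 - z0), 0.0, 1.0)
    y_ant = spec.sacrum_anterior_y_bottom + frac * (
        spec.sacrum_anterior_y_top - spec.sacrum_anterior_y_bottom
    )
    sacrum = (
        (np.abs(X) <= spec.sacrum_halfwidth_mm)
        & (Y >= spec.sacrum_posterior_y)
        & (Y <= y_ant)
        & (Z >= z0)
        & (Z <= z1)
    )

    ry, rz = spec.iliac_radii_mm[1], spec.iliac_radii_mm[2]
    rx = spec.iliac_radii_mm[0]
    cy, cz = spec.iliac_center_yz
    iliac = (
        ((np.abs(X) - spec.iliac_center_x) / rx) ** 2
        + ((Y - cy) / ry) ** 2
        + ((Z - cz) / rz) ** 2
    ) <= 1.0
    bone = (sacrum | iliac) & body

    gtv = _sphere(X, Y, Z, spec.gtv_center, spec.gtv_radius_mm)
    gtvn = (
        _sphere(X, Y, Z, spec.gtvn_center, spec.gtvn_radius_mm)
        if spec.gtvn_radius_mm > 0
        else np.zeros_like(gtv)
    )

    def _inside_body(pt) -> bool:
        x, y, _ = pt
        return (x / spec.body_halfwidth_mm) ** 2 + (y / spec.body_halfthickness_mm) ** 2 <= 1.0

    if not _inside_body(spec.gtv_center):
        raise PhantomSpecError("GTV center lies outside the body")
    if spec.gtvn_radius_mm > 0 and not _inside_body(spec.gtvn_center):
        raise PhantomSpecError("GTVn center lies outside the body")
    gtv &= body
    gtvn &= body

    # bone = thin cortical shell (1.8) over trabecular interior (1.15),
    # giving realistic water-equivalent excess along beam paths
    density = np.where(body, spec.tissue_density, 0.0)
    if bone.any():
        from scipy import ndimage as _ndi

        interior_dist = _ndi.distance_transform_edt(bone, sampling=sp)
        interior = interior_dist > spec.cortical_thickness_mm
        density = np.where(bone, spec.bone_density, density)
        density = np.where(interior, spec.trabecular_density, density)

    # bowel gas: seeded ellipsoidal pockets in the anterior abdomen, away
    # from targets and bone
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.n_air_pockets):
        cx = rng.uniform(-60.0, 60.0)
        cyp = rng.uniform(20.0, 70.0)
        czp = rng.uniform(-40.0, 80.0)
        r = spec.air_pocket_radius_mm * rng.uniform(0.7, 1.3)
        pocket = _sphere(X, Y, Z, (cx, cyp, czp), r) & body & ~bone & ~gtv & ~gtvn
        density = np.where(pocket, 0.0, density)

    z_top_sacrum = z1
    landmarks = LandmarkSet(
        L5S1_junction=np.array([0.0, spec.sacrum_anterior_y_top, z_top_sacrum]),
        obturator_foramen_bottom=np.array([0.0, -20.0, spec.obturator_bottom_z]),
        pelvic_brim_left=np.array([spec.pelvic_brim_x, -10.0, 20.0]),
        pelvic_brim_right=np.array([-spec.pelvic_brim_x, -10.0, 20.0]),
        sacrum_posterior_extent=np.array([0.0, spec.sacrum_posterior_y, 0.5 * (z0 + z1)]),
        sacral_promontory_anterior=np.array([0.0, spec.sacrum_anterior_y_top, z_top_sacrum]),
        sacrum_superior=z1,
        sacrum_inferior=z0,
    )
    for name, pt in (
        ("L5S1_junction", landmarks.L5S1_junction),
        ("obturator_foramen_bottom", landmarks.obturator_foramen_bottom),
        ("pelvic_brim_left", landmarks.pelvic_brim_left),
        ("pelvic_brim_right", landmarks.pelvic_brim_right),
        ("sacrum_posterior_extent", landmarks.sacrum_posterior_extent),
    ):
        if not _inside_body(pt):
            raise PhantomSpecError(f"landmark {name} lies outside the body")

    mk = lambda arr, dt: VoxelGrid(arr.astype(dt), origin, sp)
    return (
        mk(density, np.float64),
        mk(body, np.uint8),
        mk(gtv, np.uint8),
        mk(gtvn, np.uint8),
        landmarks,
    )


def reference_phantom(seed: int = 0, spacing_mm: float | None = None):
    """The default study phantom; optionally at a coarser isotropic spacing."""
    if spacing_mm is None:
        spec = PhantomSpec(seed=seed)
    else:
        base = PhantomSpec()
        extent = np.array(base.shape) * np.array(base.spacing_mm)
        shape = tuple(int(round(e / spacing_mm)) for e in extent)
        spec = PhantomSpec(shape=shape, spacing_mm=(spacing_mm,) * 3, seed=seed)
    return generate_phantom(spec)
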