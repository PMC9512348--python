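"""Simplified divergent-photon dose engine and planning-ROI algebra.

The engine is a documented surrogate for a commercial treatment planning
system's collapsed-cone calculation.  It keeps exactly the features the
field-in-field loop exploits and nothing else:

* depth dose — linear build-up to ``d_max`` = 25 mm then exponential falloff
  with an effective attenuation ``mu_eff`` = 0.027 /cm (matching the ~2.7%/cm
  depth-dose falloff of a 15 MV beam beyond build-up), evaluated at the
  radiological depth (cumulative density along the beam direction);
* divergence — inverse-square weighting on the along-axis source distance,
  and divergent projection of each voxel into the aperture;
* collimation — unit transmission inside the MLC opening, configurable leaf
  transmission (default 2%) under leaves inside the jaws, zero outside the
  jaws, with a Gaussian isoplane blur standing in for penumbra;
* wedges — a linear BEV-x gradient whose slope makes the mid-depth isodose
  tilt by the nominal wedge angle under the same depth-dose model.

Radiological depth uses parallel rays along the (cardinal) beam axis; the
divergent geometry is retained in the inverse-square term and aperture
projection.  Per-beam dose is strictly linear in beam weight, which is what
the quadratic weight optimizer relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import (
    VoxelGrid,
    GridError,
    erode_mask,
    expand_mask,
    mask_difference,
    mask_intersection,
)
from .apertures import mlc_opening
from .geometry import Beam, BeamError, MLCModel, bev_frame, source_position


@dataclass
class DoseModel:
    """Tunable physics constants of the surrogate engine."""

    d_max_mm: float = 25.0
    mu_eff_per_mm: float = 0.0027   # 0.027 /cm, 15 MV
    leaf_transmission: float = 0.02
    penumbra_sigma_mm: float = 3.0
    wedge_floor: float = 0.2
    aperture_pixel_mm: float = 2.0


@dataclass
class BeamDose:
    """Per-beam dose grid in Gy per unit beam weight (the B_ij column)."""

    beam_id: str
    dose: VoxelGrid


def _cardinal_axis(beam: Beam) -> tuple[int, int]:
    """(grid axis, direction) the beam travels along; cardinal angles only."""
    _, _, a = bev_frame(beam)
    axis = int(np.argmax(np.abs(a)))
    if abs(a[axis]) < 0.999:
        raise BeamError("dose engine supports cardinal (0/90/180/270°) gantry angles")
    return axis, int(np.sign(a[axis]))


def radiological_depth(density: VoxelGrid, beam: Beam) -> np.ndarray:
    """Cumulative density (mm water-equivalent) along the beam direction."""
    axis, sign = _cardinal_axis(beam)
    rho = density.values
    if sign < 0:
        rho = np.flip(rho, axis=axis)
    depth = (np.cumsum(rho, axis=axis) - 0.5 * rho) * density.spacing[axis]
    if sign < 0:
        depth = np.flip(depth, axis=axis)
    return depth


def pdd(depth_mm: np.ndarray, model: DoseModel) -> np.ndarray:
    """Percent-depth-dose curve: linear build-up then exponential falloff."""
    d = np.clip(depth_mm, 0.0, None)
    build = d / model.d_max_mm
    fall = np.exp(-model.mu_eff_per_mm * (d - model.d_max_mm))
    return np.where(d < model.d_max_mm, build, fall)


def wedge_gradient_per_mm(angle_deg: float, model: DoseModel) -> float:
    """Linear wedge slope g so the mid-depth profile tilts by the wedge angle.

    Along a tilted isodose, (1 + g x) exp(-mu (d0 + x tan w)) is stationary at
    the axis, giving g = mu_eff * tan(w).
    """
    return model.mu_eff_per_mm * np.tan(np.deg2rad(angle_deg))


def wedge_factor(beam: Beam, bev_x_mm: np.ndarray, model: DoseModel | None = None) -> np.ndarray:
    """Multiplicative wedge profile, 1 at the central axis, lower on the heel."""
    model = model or DoseModel()
    x = np.asarray(bev_x_mm, dtype=float)
    if beam.wedge is None or beam.wedge.angle_deg == 0:
        return np.ones_like(x)
    g = wedge_gradient_per_mm(beam.wedge.angle_deg, model)
    return np.clip(1.0 - g * beam.wedge.heel * x, model.wedge_floor, None)


def _bev_coordinates(grid: VoxelGrid, beam: Beam):
    """Divergent BEV (x, y) mm and along-axis source distance for all voxels."""
    src = source_position(beam)
    x_hat, y_hat, a = bev_frame(beam)
    xs = grid.axis_coords(0) - src[0]
    ys = grid.axis_coords(1) - src[1]
    zs = grid.axis_coords(2) - src[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    d = X * a[0] + Y * a[1] + Z * a[2]
    scale = beam.sad / np.maximum(d, 1e-6)
    bev_x = (X * x_hat[0] + Y * x_hat[1] + Z * x_hat[2]) * scale
    bev_y = (X * y_hat[0] + Y * y_hat[1] + Z * y_hat[2]) * scale
    return bev_x, bev_y, d


def transmission_image(
    beam: Beam, mlc: MLCModel | None = None, model: DoseModel | None = None, blur: bool = True
) -> "tuple[np.ndarray, float, float]":
    """Isoplane transmission map (open=1, leaf=transmission, outside jaws=0)."""
    model = model or DoseModel()
    opening = mlc_opening(beam, mlc, pixel_mm=model.aperture_pixel_mm)
    t = np.zeros_like(opening.mask, dtype=float)
    if beam.jaws is not None:
        x1, x2, y1, y2 = beam.jaws
        c = opening.coords()
        in_jaws = (
            (c[:, None] >= x1) & (c[:, None] <= x2)
            & (c[None, :] >= y1) & (c[None, :] <= y2)
        )
        t[in_jaws] = model.leaf_transmission
    t[opening.mask.astype(bool)] = 1.0
    if blur and model.penumbra_sigma_mm > 0:
        t = ndimage.gaussian_filter(t, model.penumbra_sigma_mm / opening.pixel_mm)
    return t, opening.pixel_mm, opening.half_mm


def beam_dose(
    beam: Beam,
    density: VoxelGrid,
    model: DoseModel | None = None,
    mlc: MLCModel | None = None,
) -> BeamDose:
    """Dose per unit beam weight on the density grid."""
    model = model or DoseModel()
    depth = radiological_depth(density, beam)
    bev_x, bev_y, d = _bev_coordinates(density, beam)
    t_img, px, half = transmission_image(beam, mlc, model, blur=True)
    ix = (bev_x + half) / px - 0.5
    iy = (bev_y + half) / px - 0.5
    T = ndimage.map_coordinates(
        t_img, np.stack([ix.ravel(), iy.ravel()]), order=1, mode="constant", cval=0.0
    ).reshape(density.shape)
    W = wedge_factor(beam, bev_x, model)
    dose = pdd(depth, model) * (beam.sad / np.maximum(d, 1e-6)) ** 2 * T * W
    dose[d <= 0] = 0.0
    return BeamDose(beam.id, density.like(dose))


def in_field_mask(
    beam: Beam,
    grid: VoxelGrid,
    mlc: MLCModel | None = None,
    model: DoseModel | None = None,
) -> VoxelGrid:
    """Voxels whose divergent projection lies inside the beam's MLC opening."""
    model = model or DoseModel()
    opening = mlc_opening(beam, mlc, pixel_mm=model.aperture_pixel_mm)
    bev_x, bev_y, d = _bev_coordinates(grid, beam)
    ix = np.round((bev_x + opening.half_mm) / opening.pixel_mm - 0.5).astype(int)
    iy = np.round((bev_y + opening.half_mm) / opening.pixel_mm - 0.5).astype(int)
    valid = (ix >= 0) & (ix < opening.n) & (iy >= 0) & (iy < opening.n) & (d > 0)
    out = np.zeros(grid.shape, dtype=np.uint8)
    out[valid] = opening.mask[ix[valid], iy[valid]]
    return grid.like(out)


def plan_dose(beam_doses: list[BeamDose], weights) -> VoxelGrid:
    """Weighted sum over beams: D(i) = sum_j alpha_j B_ij.  Linear in weights."""
    weights = np.asarray(weights, dtype=float)
    if len(beam_doses) != len(weights):
        raise GridError("weights/beam count mismatch")
    base = beam_doses[0].dose
    total = np.zeros(base.shape)
    for bd, w in zip(beam_doses, weights):
        base.require_compatible(bd.dose)
        total += w * bd.dose.values
    return base.like(total)


# -- planning-ROI algebra ---------------------------------------------------

@dataclass
class PlanningROIs:
    """RHD, pROI and the penalty regions, with per-ROI optimizer settings.

    RHD is the geometric overlap of all primary in-field frustums within the
    body; pROI (the PTV surrogate) is the RHD eroded 1 cm; LTRT is the
    lateral-overlap flank region minus the 1 cm-expanded RHD; APPA the PA
    (or AP+PA) region minus the same expansion.
    """

    rhd: VoxelGrid
    proi: VoxelGrid
    ltrt: VoxelGrid
    appa: VoxelGrid
    erosion_mm: float = 10.0

    def masks(self) -> dict[str, VoxelGrid]:
        return {"pROI": self.proi, "RHD": self.rhd, "LTRT": self.ltrt, "APPA": self.appa}


def build_planning_rois(
    primary_beams: list[Beam],
    body: VoxelGrid,
    erosion_mm: float = 10.0,
    mlc: MLCModel | None = None,
    model: DoseModel | None = None,
) -> PlanningROIs:
    """Construct the ROI set from fitted primary beams (3- or 4-field)."""
    if len(primary_beams) < 2:
        raise GridError("planning ROIs require at least two primary beams")
    frustums = {b.role: in_field_mask(b, body, mlc, model) for b in primary_beams}
    masks = [mask_intersection(f, body) for f in frustums.values()]
    rhd = masks[0]
    for m in masks[1:]:
        rhd = mask_intersection(rhd, m)
    if not rhd.values.any():
        raise GridError("primary beams do not intersect: empty RHD")
    proi = erode_mask(rhd, erosion_mm)
    rhd_exp = expand_mask(rhd, erosion_mm)

    def _get(role: str) -> VoxelGrid | None:
        return frustums.get(role)

    lt, rt, pa, ap = _get("LT"), _get("RT"), _get("PA"), _get("AP")
    if lt is not None and rt is not None:
        ltrt = mask_difference(mask_intersection(lt, rt, body), rhd_exp)
    else:
        ltrt = body.like(np.zeros(body.shape, dtype=np.uint8))
    if pa is not None:
        appa_src = mask_intersection(pa, ap, body) if ap is not None else mask_intersection(pa, body)
        appa = mask_difference(appa_src, rhd_exp)
    else:
        appa = body.like(np.zeros(body.shape, dtype=np.uint8))
    return PlanningROIs(rhd, proi, ltrt, appa, erosion_mm)


# -- dose metrics -----------------------------------------------------------

def v_percent(dose: VoxelGrid, roi: VoxelGrid, p: float, rx: float) -> float:
    """Fraction (%) of ROI volume receiving at least p% of Rx."""
    dose.require_compatible(roi)
    vals = dose.values[roi.as_bool()]
    if vals.size == 0:
        raise GridError("empty ROI")
    return 100.0 * float(np.mean(vals >= p / 100.0 * rx))


def d_percent(dose: VoxelGrid, roi: VoxelGrid, q: float) -> float:
    """Dose (Gy) exceeded by exactly q% of the ROI volume (descending sort)."""
    dose.require_compatible(roi)
    vals = dose.values[roi.as_bool()]
    if vals.size == 0:
        raise GridError("empty ROI")
    srt = np.sort(vals)[::-1]
    k = max(1, int(np.ceil(q / 100.0 * srt.size)))
    return float(srt[k - 1])


def dose_metrics(dose: VoxelGrid, roi: VoxelGrid, rx: float) -> dict[str, float]:
    """Summary for one ROI: V100/V107 (% of ROI), D50/D99 (Gy), max dose."""
    return {
        "V100_pct": v_percent(dose, roi, 100.0, rx),
        "V107_pct": v_percent(dose, roi, 107.0, rx),
        "D50_Gy": d_percent(dose, roi, 50.0),
        "D99_Gy": d_percent(dose, roi, 99.0),
        "max_Gy": float(dose.values[roi.as_bool()].max()),
    }
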