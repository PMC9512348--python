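"""Rule-based field apertures and MLC fitting.

Implements the clinical guideline the planner follows for rectal 3DCRT
fields, operating on projected (BEV) tumor masks and projected bony
landmarks:

* PA field — superior border at the L5/S1 junction or 2 cm above the
  GTV/GTVn, whichever is more superior; inferior border at the obturator
  foramen bottom or 3 cm below the GTV, whichever is more inferior; lateral
  borders 2 cm beyond the pelvic brim; four corner blocks.
* Opposed laterals — superior/inferior copied from the PA field; posterior
  border 1 cm behind the sacrum; anterior border 3 cm anterior to the sacral
  promontory or 2 cm anterior to GTV/GTVn, whichever is more anterior.
* Boost laterals — convex hull of the 2 cm-expanded GTV∪GTVn, extended
  posteriorly to 1 cm behind the sacrum (presacral coverage).

Each border records its provenance (landmark-derived vs tumor-derived), so
the extremum rule that fired is auditable.  Lateral fields are built in the
right-lateral frame and the left field is produced by mirroring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Aperture2D, Beam, BeamError, MLCModel, project_points


class ApertureRuleError(ValueError):
    pass


@dataclass
class ApertureMargins:
    """Guideline margins in mm (the '~2 cm' brim rule is taken as exactly 20)."""

    sup_gtv: float = 20.0        # superior: 2 cm above GTV/GTVn
    inf_gtv: float = 30.0        # inferior: 3 cm below GTV
    brim: float = 20.0           # lateral: 2 cm beyond pelvic brim
    post_sacrum: float = 10.0    # lateral/boost posterior: 1 cm behind sacrum
    ant_promontory: float = 30.0 # lateral anterior: 3 cm anterior to promontory
    ant_gtv: float = 20.0        # lateral anterior: 2 cm anterior to GTV/GTVn
    corner_leg: float = 20.0     # PA corner-block leg length


@dataclass
class BorderSet:
    """Field borders in BEV mm with per-border rule provenance.

    ``x_min``/``x_max`` are the BEV-x borders: lateral left/right for a PA
    field, posterior/anterior for a right-lateral field.
    """

    superior: float
    inferior: float
    x_min: float
    x_max: float
    kind: str  # "PA" | "LAT"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.superior > self.inferior and self.x_max > self.x_min):
            raise ApertureRuleError("degenerate border rectangle")


def project_landmarks(landmarks, beam: Beam) -> dict[str, np.ndarray]:
    """BEV coordinates of every point landmark for the given beam."""
    names = [
        "L5S1_junction",
        "obturator_foramen_bottom",
        "pelvic_brim_left",
        "pelvic_brim_right",
        "sacrum_posterior_extent",
        "sacral_promontory_anterior",
    ]
    pts = np.stack([getattr(landmarks, n) for n in names])
    bev = project_points(pts, beam)
    return {n: bev[k] for k, n in enumerate(names)}


def _require(lm_bev: dict, *names: str) -> None:
    for n in names:
        if n not in lm_bev:
            raise ApertureRuleError(f"missing landmark: {n}")


def _top(ap: Aperture2D) -> float:
    ext = ap.extent_y()
    return -np.inf if ext is None else ext[1]


def _bottom(ap: Aperture2D) -> float:
    ext = ap.extent_y()
    return np.inf if ext is None else ext[0]


def _front(ap: Aperture2D) -> float:
    """Anterior (max BEV-x, right-lateral frame) extent; -inf if empty."""
    ext = ap.extent_x()
    return -np.inf if ext is None else ext[1]


def pa_borders(
    lm_bev: dict[str, np.ndarray],
    gtv_bev: Aperture2D,
    gtvn_bev: Aperture2D,
    margins: ApertureMargins | None = None,
) -> BorderSet:
    """PA field borders from projected landmarks and expanded-target masks.

    The tumor masks are the 3 cm-expanded GTV and 2 cm-expanded GTVn already
    projected into the PA BEV; margins beyond them are the guideline's
    2 cm superior / 3 cm inferior offsets from the *unexpanded* target, so
    callers pass unexpanded-target projections here (expansion margins are
    part of the border rules, not the masks).
    """
    m = margins or ApertureMargins()
    _require(lm_bev, "L5S1_junction", "obturator_foramen_bottom",
             "pelvic_brim_left", "pelvic_brim_right")
    prov: dict[str, str] = {}

    top_t = max(_top(gtv_bev), _top(gtvn_bev))
    sup_bone = float(lm_bev["L5S1_junction"][1])
    sup_tumor = top_t + m.sup_gtv
    if sup_tumor > sup_bone:
        superior, prov["superior"] = sup_tumor, "tumor-derived"
    else:
        superior, prov["superior"] = sup_bone, "landmark-derived"

    bot_t = _bottom(gtv_bev)
    inf_bone = float(lm_bev["obturator_foramen_bottom"][1])
    inf_tumor = bot_t - m.inf_gtv
    if inf_tumor < inf_bone:
        inferior, prov["inferior"] = inf_tumor, "tumor-derived"
    else:
        inferior, prov["inferior"] = inf_bone, "landmark-derived"

    bl = float(lm_bev["pelvic_brim_left"][0])
    br = float(lm_bev["pelvic_brim_right"][0])
    borders = sorted((bl + np.sign(bl) * m.brim, br + np.sign(br) * m.brim))
    prov["x_min"] = prov["x_max"] = "landmark-derived"
    return BorderSet(superior, inferior, borders[0], borders[1], "PA", prov)


def rectangle_aperture(
    borders: BorderSet, corner_leg: float = 0.0, pixel_mm: float = 2.0
) -> Aperture2D:
    """Border rectangle, minus four 45° triangular corner blocks if requested."""
    ap = Aperture2D.blank(pixel_mm=pixel_mm)
    c = ap.coords()
    X, Y = np.meshgrid(c, c, indexing="ij")
    inside = (
        (X >= borders.x_min) & (X <= borders.x_max)
        & (Y >= borders.inferior) & (Y <= borders.superior)
    )
    if corner_leg > 0:
        for cx in (borders.x_min, borders.x_max):
            for cy in (borders.inferior, borders.superior):
                inside &= np.abs(X - cx) + np.abs(Y - cy) >= corner_leg
    if not inside.any():
        raise ApertureRuleError("borders produce an empty aperture")
    ap.mask = inside.astype(np.uint8)
    return ap


def pa_aperture(
    borders: BorderSet, margins: ApertureMargins | None = None, pixel_mm: float = 2.0
) -> Aperture2D:
    """PA aperture: border rectangle with sacroiliac/femoral-head corner blocks."""
    m = margins or ApertureMargins()
    return rectangle_aperture(borders, corner_leg=m.corner_leg, pixel_mm=pixel_mm)


def lateral_borders(
    lm_bev: dict[str, np.ndarray],
    pa: BorderSet | None,
    gtv_bev: Aperture2D,
    gtvn_bev: Aperture2D,
    margins: ApertureMargins | None = None,
) -> BorderSet:
    """Right-lateral borders (BEV-x: posterior = x_min, anterior = x_max).

    Sequential on the PA result: superior and inferior are copied from the PA
    border set, mirroring the guideline's matched longitudinal borders.
    """
    if pa is None:
        raise ApertureRuleError("lateral borders require the PA border set first")
    m = margins or ApertureMargins()
    _require(lm_bev, "sacrum_posterior_extent", "sacral_promontory_anterior")
    prov = {"superior": "pa-matched", "inferior": "pa-matched"}

    posterior = float(lm_bev["sacrum_posterior_extent"][0]) - m.post_sacrum
    prov["x_min"] = "landmark-derived"

    ant_bone = float(lm_bev["sacral_promontory_anterior"][0]) + m.ant_promontory
    ant_tumor = max(_front(gtv_bev), _front(gtvn_bev)) + m.ant_gtv
    if ant_tumor > ant_bone:
        anterior, prov["x_max"] = ant_tumor, "tumor-derived"
    else:
        anterior, prov["x_max"] = ant_bone, "landmark-derived"
    return BorderSet(pa.superior, pa.inferior, posterior, anterior, "LAT", prov)


def boost_aperture(
    gtv_bev_2cm: Aperture2D,
    gtvn_bev_2cm: Aperture2D,
    lm_bev: dict[str, np.ndarray],
    margins: ApertureMargins | None = None,
) -> Aperture2D:
    """Boost aperture in the right-lateral frame.

    Convex hull of the combined 2 cm-expanded GTV/GTVn projections, extended
    posteriorly (toward -BEV-x) to 1 cm behind the sacrum so the presacral
    space stays covered.
    """
    m = margins or ApertureMargins()
    _require(lm_bev, "sacrum_posterior_extent")
    combined = gtv_bev_2cm.mask.astype(bool) | gtvn_bev_2cm.mask.astype(bool)
    if not combined.any():
        raise ApertureRuleError("boost aperture requires a nonempty GTV or GTVn mask")
    from skimage.morphology import convex_hull_image

    hull = convex_hull_image(combined)
    ap = Aperture2D(hull.astype(np.uint8), gtv_bev_2cm.pixel_mm, gtv_bev_2cm.half_mm)
    sac_line = float(lm_bev["sacrum_posterior_extent"][0]) - m.post_sacrum
    i_sac = int(np.clip(np.floor(ap.to_index(sac_line) + 0.5), 0, ap.n - 1))
    out = ap.mask.astype(bool)
    for j in range(ap.n):
        col = np.nonzero(out[:, j])[0]
        if len(col) and col[0] > i_sac:
            out[i_sac : col[0], j] = True
    ap.mask = out.astype(np.uint8)
    return ap


# -- MLC fitting ------------------------------------------------------------

def fit_mlc(
    aperture: Aperture2D,
    mlc: MLCModel | None = None,
    mode: str = "cover",
):
    """Fit leaf positions to an aperture.

    ``mode="cover"`` (out-field fit, treatment apertures): each leaf pair
    opens to the full BEV-x extent of the aperture on its rows, so the MLC
    opening is a superset of the aperture with at most one leaf width of
    excess at edge rows.  ``mode="within"`` (in-field fit, blocking
    subfields): each pair opens only over the largest x-interval open across
    all of its rows, so the opening is a subset of the aperture.

    Returns ``(bank_a, bank_b, jaws)`` with jaws the tight bounding box of
    the leaf openings; an empty aperture closes every pair at the midline.
    """
    mlc = mlc or MLCModel()
    n_pairs = mlc.n_pairs
    bank_a = np.zeros(n_pairs)
    bank_b = np.zeros(n_pairs)
    ext = aperture.extent_x()
    if ext is not None and (abs(ext[0]) > mlc.travel_mm or abs(ext[1]) > mlc.travel_mm):
        raise BeamError("aperture exceeds MLC travel limit")

    ys = aperture.coords()
    xs = aperture.coords()
    px = aperture.pixel_mm
    open_any = False
    for p in range(n_pairs):
        y0, y1 = mlc.boundaries[p], mlc.boundaries[p + 1]
        rows = np.nonzero((ys >= y0) & (ys < y1))[0]
        if len(rows) == 0:
            continue
        sub = aperture.mask[:, rows].astype(bool)
        if mode == "cover":
            cols = np.nonzero(sub.any(axis=1))[0]
        elif mode == "within":
            cols = np.nonzero(sub.all(axis=1))[0]
            if len(cols):  # largest contiguous run
                splits = np.split(cols, np.nonzero(np.diff(cols) > 1)[0] + 1)
                cols = max(splits, key=len)
        else:
            raise ValueError(f"unknown MLC fit mode: {mode}")
        if len(cols) == 0:
            continue
        bank_a[p] = xs[cols[0]] - 0.5 * px
        bank_b[p] = xs[cols[-1]] + 0.5 * px
        open_any = True

    if not open_any:
        jaws = (0.0, 0.0, 0.0, 0.0)
        return bank_a, bank_b, jaws
    open_pairs = np.nonzero(bank_b > bank_a)[0]
    jaws = (
        float(bank_a[open_pairs].min()),
        float(bank_b[open_pairs].max()),
        float(mlc.boundaries[open_pairs.min()]),
        float(mlc.boundaries[open_pairs.max() + 1]),
    )
    return bank_a, bank_b, jaws


def mlc_opening(beam: Beam, mlc: MLCModel | None = None, pixel_mm: float = 2.0) -> Aperture2D:
    """Rasterize a beam's jaw-clipped MLC opening back onto the isoplane."""
    mlc = mlc or MLCModel()
    ap = Aperture2D.blank(pixel_mm=pixel_mm)
    if beam.mlc_a is None or beam.jaws is None:
        return ap
    x1, x2, y1, y2 = beam.jaws
    xs = ap.coords()
    ys = ap.coords()
    out = np.zeros((ap.n, ap.n), dtype=bool)
    pair_of_row = mlc.pair_index(ys)
    for j, y in enumerate(ys):
        if not (y1 <= y <= y2):
            continue
        p = pair_of_row[j]
        a, b = beam.mlc_a[p], beam.mlc_b[p]
        if b <= a:
            continue
        out[:, j] = (xs >= max(a, x1)) & (xs <= min(b, x2))
    ap.mask = out.astype(np.uint8)
    return ap


def mirror_lateral(beam: Beam) -> Beam:
    """The opposed lateral: gantry reflected, MLC/jaws/wedge mirrored in BEV-x."""
    role_map = {"LT": "RT", "RT": "LT", "BstLT": "BstRT", "BstRT": "BstLT"}
    new = replace(
        beam,
        gantry_angle=(360.0 - beam.gantry_angle) % 360.0,
        role=role_map.get(beam.role, beam.role),
        mlc_a=None if beam.mlc_b is None else -np.asarray(beam.mlc_b),
        mlc_b=None if beam.mlc_a is None else -np.asarray(beam.mlc_a),
        jaws=None if beam.jaws is None else (
            -beam.jaws[1], -beam.jaws[0], beam.jaws[2], beam.jaws[3]
        ),
        wedge=None if beam.wedge is None else beam.wedge.mirrored(),
    )
    return new
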