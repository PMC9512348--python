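"""The iterative field-in-field loop: hotspot detection, blocking subfields,
weight re-optimization, and the three termination conditions.

Each pass renormalizes the plan, measures the hotspot dose percentage (the
highest threshold at which a fully connected supra-threshold volume of at
least the minimum size — default 8 cm³ — still exists), optimizes beam
weights, and if the plan is still hot adds one blocking subfield to the next
lateral in an LT/RT alternation.  A tentative subfield that *raises* the
renormalized hotspot dose percentage is removed again (condition 3), after
which the loop either stops or relaxes the target by a configured increment
(default 1%).  The loop also stops when the target percentage is reached
(condition 1) or the subfield budget (default 6) is exhausted (condition 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .apertures import mlc_opening
from .geometry import Beam, Wedge, bev_frame, project_mask
from .grid import VoxelGrid, erode_mask, mask_intersection
from .dose import beam_dose, in_field_mask, plan_dose, v_percent
from .optimize import NormalizationSpec, OptimizerConfig, normalize, optimize_weights
from .plan import Plan


@dataclass
class Hotspot:
    """One fully connected supra-threshold dose component."""

    indices: np.ndarray           # (N, 3) voxel indices
    volume_cm3: float
    max_dose: float
    threshold_percent: float
    connectivity: int

    def mask(self, grid: VoxelGrid) -> VoxelGrid:
        out = np.zeros(grid.shape, dtype=np.uint8)
        out[tuple(self.indices.T)] = 1
        return grid.like(out)


@dataclass
class FIFConfig:
    """Every configurable variable of the FIF loop."""

    hotspot_percent: float | list = 107.0   # scalar, or a decreasing schedule
    target_percent: float = 107.0
    min_hotspot_volume_cm3: float = 8.0
    max_subfields: int = 6
    connectivity: int = 26
    keep_largest_only: bool = True
    alternate_sides: bool = True
    first_side: str = "LT"
    relax_on_stall: bool = False
    relax_increment: float = 1.0
    max_iterations: int = 25

    def __post_init__(self) -> None:
        if self.target_percent < 100:
            raise ValueError("target percentage must be at least 100")
        if self.max_subfields < 0:
            raise ValueError("max_subfields must be non-negative")

    def hotspot_percent_at(self, iteration: int) -> float:
        if np.isscalar(self.hotspot_percent):
            return float(self.hotspot_percent)  # type: ignore[arg-type]
        sched = list(self.hotspot_percent)  # type: ignore[arg-type]
        return float(sched[min(iteration, len(sched) - 1)])


@dataclass
class IterationRecord:
    """One loop pass: what was measured and what action was taken."""

    iteration: int
    hotspot_dose_percent: float
    v107_proi_percent: float
    weights: list
    action: str       # init | weights_only | subfield_added | reverted | relaxed | stop
    n_subfields: int
    target_percent: float
    renormalized: bool = True
    termination_reason: int | None = None


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def find_hotspots(
    dose: VoxelGrid,
    rx: float,
    percent: float = 107.0,
    min_volume_cm3: float = 8.0,
    connectivity: int = 26,
) -> list[Hotspot]:
    """Connected components of {D > percent% of Rx} of at least the minimum
    volume, largest first."""
    supra = dose.values > percent / 100.0 * rx
    labels, n = ndimage.label(supra, structure=_structure(connectivity))
    if n == 0:
        return []
    vox = dose.voxel_volume_cm3
    counts = np.bincount(labels.ravel())[1:]
    out = []
    for lab in np.nonzero(counts * vox >= min_volume_cm3)[0] + 1:
        idx = np.argwhere(labels == lab)
        out.append(
            Hotspot(
                indices=idx,
                volume_cm3=float(counts[lab - 1] * vox),
                max_dose=float(dose.values[labels == lab].max()),
                threshold_percent=percent,
                connectivity=connectivity,
            )
        )
    out.sort(key=lambda h: h.volume_cm3, reverse=True)
    return out


def hotspot_dose_percent(
    dose: VoxelGrid,
    rx: float,
    min_volume_cm3: float = 8.0,
    connectivity: int = 26,
    resolution: float = 0.1,
) -> float:
    """The dose percentage indicated by the hottest fully connected
    ``min_volume_cm3``: the highest threshold at which a connected
    supra-threshold component of that size still exists (bisection)."""
    vox = dose.voxel_volume_cm3
    if float(np.count_nonzero(dose.values > 0)) * vox < min_volume_cm3:
        warnings.warn("dose support smaller than the minimum hotspot volume", stacklevel=2)
        return 0.0

    def exists(t: float) -> bool:
        supra = dose.values > t / 100.0 * rx
        labels, n = ndimage.label(supra, structure=_structure(connectivity))
        if n == 0:
            return False
        counts = np.bincount(labels.ravel())[1:]
        return bool((counts * vox >= min_volume_cm3).any())

    lo, hi = 0.0, 100.0 * float(dose.values.max()) / rx + resolution
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if exists(mid):
            lo = mid
        else:
            hi = mid
    return lo


def build_subfield(
    plan: Plan,
    parent: Beam,
    hotspots: list[Hotspot],
    sub_id: str,
    keep_largest_only: bool = True,
    pixel_mm: float = 2.0,
) -> Beam | None:
    """A blocking subfield on the parent beam from the current hotspots.

    The (largest-only by default) hotspot mask is distally truncated with
    respect to the isocenter, ray-trace projected into the parent's BEV, and
    each disconnected 2D hotspot object is covered by extending the nearer
    MLC bank across it; the subfield aperture is the parent opening minus
    that single blocking shape.  Returns None when the projected hotspot
    misses the parent opening entirely (the loop then falls back to a
    weights-only step).
    """
    if not hotspots:
        return None
    use = hotspots[:1] if keep_largest_only else hotspots
    mask3d = np.zeros(plan.density.shape, dtype=np.uint8)
    for h in use:
        mask3d[tuple(h.indices.T)] = 1
    projected = project_mask(
        plan.density.like(mask3d), parent, truncate_distal=True, pixel_mm=pixel_mm
    )
    opening = mlc_opening(parent, plan.mlc, pixel_mm=pixel_mm)
    overlap = projected.mask.astype(bool) & opening.mask.astype(bool)
    if not overlap.any():
        return None

    new_a = np.array(parent.mlc_a, dtype=float)
    new_b = np.array(parent.mlc_b, dtype=float)
    xs = projected.coords()
    ys = projected.coords()
    px = projected.pixel_mm
    x1p, x2p, _, _ = parent.jaws
    mid_open = 0.5 * (x1p + x2p)
    labels, n2d = ndimage.label(overlap, structure=np.ones((3, 3), dtype=int))
    pair_of_row = plan.mlc.pair_index(ys)
    for lab in range(1, n2d + 1):
        ii, jj = np.nonzero(labels == lab)
        cx = float(np.mean(xs[ii]))
        use_bank_a = (cx - x1p) <= (x2p - cx)
        for p in np.unique(pair_of_row[jj]):
            sel = pair_of_row[jj] == p
            if use_bank_a:  # extend bank A rightward across the object
                new_a[p] = max(new_a[p], float(xs[ii[sel]].max()) + 0.5 * px)
            else:           # extend bank B leftward across the object
                new_b[p] = min(new_b[p], float(xs[ii[sel]].min()) - 0.5 * px)
    closed = new_a >= new_b
    new_a[closed] = mid_open
    new_b[closed] = mid_open
    if not (new_b > new_a).any():
        return None
    return Beam(
        id=sub_id,
        role="subfield",
        gantry_angle=parent.gantry_angle,
        isocenter=parent.isocenter,
        source_axis_distance=parent.source_axis_distance,
        jaws=parent.jaws,
        mlc_a=new_a,
        mlc_b=new_b,
        wedge=None,
        parent_id=parent.id,
    )


def _measure(plan: Plan, config: FIFConfig):
    dose, _ = plan.normalized_dose()
    h = hotspot_dose_percent(
        dose, plan.rx, config.min_hotspot_volume_cm3, config.connectivity
    )
    v107 = v_percent(dose, plan.rois.proi, 107.0, plan.rx)
    return dose, h, v107


def fif_iterate(
    plan: Plan, config: FIFConfig, opt_config: OptimizerConfig
) -> tuple[Plan, list[IterationRecord]]:
    """Run the iterative FIF loop on a plan with fitted primary apertures.

    Renormalization precedes every hotspot check.  Weight optimizations or
    subfields that worsen the renormalized hotspot dose percentage are
    reverted, so across accepted iterations the hotspot percentage is
    non-increasing.  Exactly one subfield is added per accepted iteration,
    alternating LT/RT sides.
    """
    history: list[IterationRecord] = []
    target = config.target_percent
    side = config.first_side
    eps = 1e-9

    dose, h, v107 = _measure(plan, config)
    history.append(
        IterationRecord(0, h, v107, list(plan.weights), "init", plan.n_subfields(), target)
    )

    reason: int | None = None
    for it in range(1, config.max_iterations + 1):
        if h <= target + eps:
            reason = 1
            break

        # weights-only optimization; revert if it worsens the hotspot measure
        w_old = list(plan.weights)
        res = optimize_weights(
            plan.compute_beam_doses(), plan.rois, plan.rx, opt_config,
            np.asarray(plan.weights), plan.roles, scale=plan.norm_factor,
        )
        plan.weights = list(res.weights)
        dose2, h2, v2 = _measure(plan, config)
        if h2 > h + eps:
            plan.weights = w_old
            dose2, h2, v2 = dose, h, v107
            action = "weights_reverted"
        else:
            action = "weights_only"
        dose, h, v107 = dose2, h2, v2
        if h <= target + eps:
            history.append(IterationRecord(it, h, v107, list(plan.weights), action,
                                           plan.n_subfields(), target))
            reason = 1
            break
        if plan.n_subfields() >= config.max_subfields:
            history.append(IterationRecord(it, h, v107, list(plan.weights), action,
                                           plan.n_subfields(), target))
            reason = 2
            break

        # tentative subfield on the alternating side
        hotspots = find_hotspots(
            dose, plan.rx, config.hotspot_percent_at(plan.n_subfields()),
            config.min_hotspot_volume_cm3, config.connectivity,
        )
        sub = None
        tried: list[str] = []
        for _ in range(2 if config.alternate_sides else 1):
            parent = plan.beam_by_role(side)
            sub_id = f"SF{plan.n_subfields() + 1}_{side}"
            sub = build_subfield(plan, parent, hotspots, sub_id, config.keep_largest_only)
            tried.append(side)
            if config.alternate_sides:
                side = "RT" if side == "LT" else "LT"
            if sub is not None:
                break
        if sub is None:
            if config.relax_on_stall:
                target += config.relax_increment
                history.append(IterationRecord(it, h, v107, list(plan.weights), "relaxed",
                                               plan.n_subfields(), target))
                continue
            history.append(IterationRecord(it, h, v107, list(plan.weights), action,
                                           plan.n_subfields(), target))
            reason = 3
            break

        lo_sub = opt_config.bounds_for("subfield")[0]
        w_before_sub = list(plan.weights)
        plan.add_beam(sub, lo_sub)
        res = optimize_weights(
            plan.compute_beam_doses(), plan.rois, plan.rx, opt_config,
            np.asarray(plan.weights), plan.roles, scale=plan.norm_factor,
        )
        plan.weights = list(res.weights)
        dose3, h3, v3 = _measure(plan, config)
        if h3 > h + eps:  # condition (3): the subfield made things worse
            plan.remove_beam(sub.id)
            plan.weights = w_before_sub
            plan.norm_factor = plan.normalized_dose()[1]
            history.append(IterationRecord(it, h, v107, list(plan.weights), "reverted",
                                           plan.n_subfields(), target))
            if config.relax_on_stall:
                target += config.relax_increment
                history.append(IterationRecord(it, h, v107, list(plan.weights), "relaxed",
                                               plan.n_subfields(), target))
                continue
            reason = 3
            break
        dose, h, v107 = dose3, h3, v3
        history.append(IterationRecord(it, h, v107, list(plan.weights), "subfield_added",
                                       plan.n_subfields(), target))
    else:
        reason = 2 if plan.n_subfields() >= config.max_subfields else 3

    history.append(IterationRecord(len(history), h, v107, list(plan.weights), "stop",
                                   plan.n_subfields(), target, termination_reason=reason))
    plan.history = history
    return plan, history


# -- boost ------------------------------------------------------------------

@dataclass
class BoostConfig:
    rx: float = 5.4
    fractions: int = 3
    wedge_angle: float = 15.0
    coverage_q: float = 98.0
    erosion_mm: float = 10.0


@dataclass
class BoostResult:
    beams: list[Beam]
    weights: list[float]
    dose: VoxelGrid
    boost_volume: VoxelGrid
    norm_factor: float
    coverage_percent: float


def heel_posterior(beam: Beam) -> int:
    """Heel sign (BEV-x) putting the wedge's thick end posteriorly."""
    x_hat, _, _ = bev_frame(beam)
    return int(np.sign(-x_hat[1])) or 1


def add_boost(plan: Plan, boost_rt: Beam, config: BoostConfig | None = None) -> BoostResult:
    """Opposed lateral boost fields with wedges; no FIF subfields.

    The right boost beam (fitted to the boost aperture) is supplied; the left
    is its mirror.  The boost volume is the overlap of the boost frustums
    eroded by 1 cm, intersected with the pROI; the boost dose is normalized
    so the prescription covers 98% of that volume.
    """
    from .apertures import mirror_lateral

    config = config or BoostConfig()
    boost_rt = Beam(**{**boost_rt.__dict__})
    boost_rt.wedge = Wedge(config.wedge_angle, heel_posterior(boost_rt))
    boost_lt = mirror_lateral(boost_rt)
    boost_lt.id = boost_rt.id.replace("RT", "LT") if "RT" in boost_rt.id else boost_rt.id + "_LT"

    doses = [beam_dose(b, plan.density, plan.dose_model, plan.mlc) for b in (boost_rt, boost_lt)]
    frustums = [in_field_mask(b, plan.body, plan.mlc, plan.dose_model) for b in (boost_rt, boost_lt)]
    overlap = mask_intersection(frustums[0], frustums[1], plan.body)
    volume = mask_intersection(erode_mask(overlap, config.erosion_mm), plan.rois.proi)
    if not volume.values.any():
        raise ValueError("empty boost volume")
    weights = [0.5, 0.5]
    raw = plan_dose(doses, weights)
    spec = NormalizationSpec(rx=config.rx, mode="volume", q_percent=config.coverage_q)
    dose, factor = normalize(raw, spec, volume)
    coverage = v_percent(dose, volume, 100.0, config.rx)
    return BoostResult([boost_rt, boost_lt], weights, dose, volume, factor, coverage)
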