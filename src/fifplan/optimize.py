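"""Plan normalization and bound-constrained quadratic beam-weight optimization.

Normalization rescales every voxel by ``Rx / D_p`` where ``D_p`` is either
the dose at a named point or the dose covering a given percentage of an ROI
(volume mode, default: Rx covers 99% of the pROI).

The weight objective is a sum of one-sided quadratic penalties over ROIs:

    f(alpha) = sum_m w_m sum_i step_m(D_i - L_m) (D_i - L_m)^2,
    D_i = S * sum_j alpha_j B_ij,

with per-beam bounds min_MU/total_MU <= alpha_j <= max_MU/total_MU.  Targets
(pROI) are penalized only below their level, OAR-like flank/anterior regions
(LTRT/APPA) only above a tolerance, and the high-dose region (RHD) only above
the hotspot level — tying the optimizer directly to the field-in-field goal.
``S`` is the current plan normalization factor, held fixed during a solve and
refreshed by renormalization afterwards.  The objective is convex (one-sided
quadratics of affine functions) and is solved with a quasi-Newton
bound-constrained solver selected by name from a registry (L-BFGS-B by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize as sciopt

from .dose import BeamDose, PlanningROIs, d_percent
from .grid import VoxelGrid, GridError


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationSpec:
    """How the plan dose is rescaled to the prescription."""

    rx: float
    mode: str = "volume"            # "volume" | "point"
    q_percent: float = 99.0          # volume mode: Rx covers q% of the ROI
    point: np.ndarray | None = None  # point mode: world mm

    def __post_init__(self) -> None:
        if self.mode not in ("volume", "point"):
            raise NormalizationError(f"unknown normalization mode: {self.mode}")
        if self.mode == "volume" and not (0 < self.q_percent < 100):
            raise NormalizationError("volume-mode percentage must be in (0, 100)")


def normalize(
    dose: VoxelGrid, spec: NormalizationSpec, roi: VoxelGrid | None = None
) -> tuple[VoxelGrid, float]:
    """Rescale dose so the normalization dose equals Rx; returns (dose, factor)."""
    if spec.mode == "point":
        if spec.point is None:
            raise NormalizationError("point mode requires a point")
        idx = (np.asarray(spec.point) - dose.origin) / dose.spacing
        dp = float(
            ndimage.map_coordinates(dose.values, idx.reshape(3, 1), order=1, mode="nearest")[0]
        )
    else:
        if roi is None:
            raise NormalizationError("volume mode requires an ROI")
        dp = d_percent(dose, roi, spec.q_percent)
    if dp <= 0:
        raise NormalizationError("normalization unachievable: D_p is zero")
    factor = spec.rx / dp
    return dose.like(dose.values * factor), factor


@dataclass
class OptimizerConfig:
    """Solver choice, MU-fraction bounds and per-ROI penalty settings."""

    solver: str = "L-BFGS-B"
    total_mu: float = 100.0
    min_mu: float = 5.0              # primary beams
    max_mu: float = 100.0
    sub_min_mu: float = 1.0          # FIF subfields
    sub_max_mu: float = 30.0
    roi_weights: dict = field(
        default_factory=lambda: {"pROI": 1.0, "LTRT": 0.5, "APPA": 0.5, "RHD": 1.0}
    )
    oar_tolerance_fraction: float = 0.9   # LTRT/APPA level as a fraction of Rx
    hotspot_percent: float = 107.0        # RHD level as % of Rx
    sample_fraction: float = 0.1          # deterministic stride subsample per ROI
    max_iter: int = 300
    tol: float = 1e-10
    freeze_subfields: bool = False

    def __post_init__(self) -> None:
        if self.min_mu > self.max_mu or self.sub_min_mu > self.sub_max_mu:
            raise ValueError("MU bounds inverted")
        if any(w < 0 for w in self.roi_weights.values()):
            raise ValueError("ROI weights must be non-negative")

    def bounds_for(self, role: str) -> tuple[float, float]:
        if role == "subfield":
            return self.sub_min_mu / self.total_mu, self.sub_max_mu / self.total_mu
        return self.min_mu / self.total_mu, self.max_mu / self.total_mu


# penalty side per ROI class: +1 penalizes above the level, -1 below
_ROI_SIDE = {"pROI": -1, "LTRT": +1, "APPA": +1, "RHD": +1}


def _roi_level(name: str, rx: float, config: OptimizerConfig) -> float:
    if name == "pROI":
        return rx
    if name in ("LTRT", "APPA"):
        return config.oar_tolerance_fraction * rx
    if name == "RHD":
        return config.hotspot_percent / 100.0 * rx
    raise KeyError(name)


def _sample_indices(mask: np.ndarray, fraction: float) -> np.ndarray:
    """Deterministic stratified subsample: every k-th ROI voxel in scan order."""
    flat = np.flatnonzero(mask.ravel())
    if fraction >= 1.0 or flat.size == 0:
        return flat
    k = max(1, int(round(1.0 / fraction)))
    return flat[::k]


class WeightObjective:
    """Precomputed per-ROI beam-dose matrices for fast objective evaluation."""

    def __init__(
        self,
        beam_doses: list[BeamDose],
        rois: PlanningROIs,
        rx: float,
        config: OptimizerConfig,
        scale: float = 1.0,
        sample_fraction: float | None = None,
    ):
        if not rois.masks():
            raise GridError("no ROIs for the objective")
        frac = config.sample_fraction if sample_fraction is None else sample_fraction
        self.scale = scale
        self.terms: list[tuple[float, float, int, np.ndarray]] = []
        for name, mask in rois.masks().items():
            w = config.roi_weights.get(name, 0.0)
            if w == 0:
                continue
            idx = _sample_indices(mask.as_bool(), frac)
            if idx.size == 0:
                continue
            B = np.stack([bd.dose.values.ravel()[idx] for bd in beam_doses])
            self.terms.append((w, _roi_level(name, rx, config), _ROI_SIDE[name], B))
        if not self.terms:
            raise GridError("all ROIs empty or zero-weighted")

    def value_and_grad(self, alpha: np.ndarray) -> tuple[float, np.ndarray]:
        alpha = np.asarray(alpha, dtype=float)
        f = 0.0
        g = np.zeros_like(alpha)
        for w, level, side, B in self.terms:
            d = self.scale * (alpha @ B)
            r = d - level
            active = r > 0 if side > 0 else r < 0
            ra = np.where(active, r, 0.0)
            f += w * float(ra @ ra)
            g += 2.0 * w * self.scale * (B @ ra)
        return f, g

    def __call__(self, alpha: np.ndarray) -> float:
        return self.value_and_grad(alpha)[0]


def objective(
    weights,
    beam_doses: list[BeamDose],
    rois: PlanningROIs,
    rx: float,
    config: OptimizerConfig,
    scale: float = 1.0,
    sample_fraction: float | None = None,
) -> float:
    """One-shot objective value (full-voxel evaluation when fraction=1)."""
    obj = WeightObjective(beam_doses, rois, rx, config, scale, sample_fraction)
    return obj(np.asarray(weights, dtype=float))


SOLVERS: dict[str, str] = {
    "L-BFGS-B": "L-BFGS-B",
    "TNC": "TNC",
    "SLSQP": "SLSQP",
    "Powell": "Powell",
}


@dataclass
class OptimizeResult:
    weights: np.ndarray
    objective: float
    success: bool
    message: str = ""


def optimize_weights(
    beam_doses: list[BeamDose],
    rois: PlanningROIs,
    rx: float,
    config: OptimizerConfig,
    initial_weights,
    roles: list[str],
    scale: float = 1.0,
) -> OptimizeResult:
    """Minimize the one-sided quadratic objective within MU-fraction bounds.

    Deterministic given solver and inputs.  On solver failure (or if the
    solve did not improve the objective), the initial weights are returned
    with ``success=False`` so the surrounding loop can proceed.
    """
    x0 = np.asarray(initial_weights, dtype=float)
    if config.solver not in SOLVERS:
        raise KeyError(f"unknown solver: {config.solver}; registered: {sorted(SOLVERS)}")
    bounds = [config.bounds_for(r) for r in roles]
    if config.freeze_subfields:
        bounds = [
            (x0[j], x0[j]) if roles[j] == "subfield" else b for j, b in enumerate(bounds)
        ]
    for j, (lo, hi) in enumerate(bounds):
        if not (lo - 1e-12 <= x0[j] <= hi + 1e-12):
            raise ValueError(f"initial weight {j} outside bounds [{lo}, {hi}]")

    obj = WeightObjective(beam_doses, rois, rx, config, scale)
    f0 = obj(x0)
    method = SOLVERS[config.solver]
    budget_key = "maxfun" if method == "TNC" else "maxiter"
    kwargs: dict = {"bounds": bounds, "options": {budget_key: config.max_iter}}
    if method in ("L-BFGS-B", "TNC", "SLSQP"):
        kwargs["jac"] = True
        fun = obj.value_and_grad
    else:
        fun = obj
    try:
        res = sciopt.minimize(fun, x0, method=method, tol=config.tol, **kwargs)
    except Exception as exc:  # solver blow-up: fall back to initial weights
        return OptimizeResult(x0, f0, False, f"solver raised: {exc}")
    x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    f = obj(x)
    if not np.isfinite(f) or f > f0:
        return OptimizeResult(x0, f0, False, "solver did not improve the objective")
    return OptimizeResult(x, f, True, str(res.message))


DEFAULT_ROLE_RATIOS = {"PA": 2.0, "LT": 1.0, "RT": 1.0, "AP": 1.0}


def initialize_weights(roles: list[str], ratios: dict | None = None) -> np.ndarray:
    """Role-ratio initial weights (PA:LT:RT = 2:1:1), normalized to sum 1."""
    ratios = ratios or DEFAULT_ROLE_RATIOS
    out = np.empty(len(roles))
    for j, role in enumerate(roles):
        if role not in ratios:
            raise KeyError(f"no initial weight ratio for beam role: {role}")
        out[j] = ratios[role]
    return out / out.sum()
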