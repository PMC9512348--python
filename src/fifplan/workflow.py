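"""End-to-end orchestration: phantom → apertures → primary FIF → boost → report.

Stage order mirrors the forward-planning workflow: generate (or load) the
phantom; expand the targets (3 cm GTV, 2 cm GTVn); project landmarks and
masks into each beam's eye view; derive the PA borders, then the sequential
lateral borders; fit MLCs; build the right lateral first and mirror it to
the left; initialize weights 2:1:1 (PA:LT:RT); run the FIF loop with wedged
laterals; finally add opposed wedged boost fields normalized to cover 98% of
the boost volume.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import apertures as ar
from .dose import DoseModel, build_planning_rois, dose_metrics
from .fif import BoostConfig, FIFConfig, add_boost, fif_iterate, heel_posterior
from .geometry import Beam, MLCModel, Wedge, project_mask
from .grid import VoxelGrid, expand_mask, save_grid
from .optimize import NormalizationSpec, OptimizerConfig, initialize_weights
from .phantom import PhantomSpec, generate_phantom
from .plan import Plan

log = logging.getLogger("fifplan")


@dataclass
class RunConfig:
    """Everything a planning run needs; YAML round-trippable."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    geometry: str = "3-field"          # "3-field" | "4-field"
    rx: float = 45.0
    fractions: int = 25
    gtv_expansion_mm: float = 30.0
    gtvn_expansion_mm: float = 20.0
    boost_expansion_mm: float = 20.0
    wedge_angle: float = 60.0
    normalization_q: float = 99.0
    margins: ar.ApertureMargins = field(default_factory=ar.ApertureMargins)
    fif: FIFConfig = field(default_factory=FIFConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    boost: BoostConfig = field(default_factory=BoostConfig)
    dose_model: DoseModel = field(default_factory=DoseModel)
    with_boost: bool = True
    output_dir: str | None = None
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fractions <= 0:
            raise ValueError("fractions must be positive")
        if self.geometry not in ("3-field", "4-field"):
            raise ValueError("geometry must be 3-field or 4-field")


def config_to_yaml(config: RunConfig) -> str:
    return yaml.safe_dump(asdict(config), sort_keys=True)


def config_from_yaml(text: str) -> RunConfig:
    raw = yaml.safe_load(text) or {}
    kwargs = dict(raw)
    for key, cls in (
        ("phantom", PhantomSpec),
        ("margins", ar.ApertureMargins),
        ("fif", FIFConfig),
        ("optimizer", OptimizerConfig),
        ("boost", BoostConfig),
        ("dose_model", DoseModel),
    ):
        if key in kwargs and isinstance(kwargs[key], dict):
            sub = kwargs[key]
            for f_ in dataclasses.fields(cls):
                if f_.name in sub and isinstance(sub[f_.name], list):
                    if f_.name in ("shape", "spacing_mm", "sacrum_z_range",
                                   "iliac_radii_mm", "iliac_center_yz",
                                   "gtv_center", "gtvn_center"):
                        sub[f_.name] = tuple(sub[f_.name])
            kwargs[key] = cls(**sub)
    return RunConfig(**kwargs)


def build_primary_plan(config: RunConfig):
    """Stages 1–6: phantom, expanded masks, rule-based apertures, beams, ROIs."""
    log.info("stage: phantom generation")
    density, body, gtv, gtvn, landmarks = generate_phantom(config.phantom)
    iso = np.asarray(config.phantom.gtv_center, dtype=float)

    log.info("stage: target expansion and BEV projection")
    gtv_exp = expand_mask(gtv, config.gtv_expansion_mm)
    gtvn_exp = expand_mask(gtvn, config.gtvn_expansion_mm)

    pa_beam = Beam(id="PA", role="PA", gantry_angle=180.0, isocenter=iso)
    rt_beam = Beam(id="RT", role="RT", gantry_angle=270.0, isocenter=iso)

    lm_pa = ar.project_landmarks(landmarks, pa_beam)
    gtv_pa = project_mask(gtv, pa_beam)
    gtvn_pa = project_mask(gtvn, pa_beam)

    log.info("stage: PA borders and aperture")
    pa_b = ar.pa_borders(lm_pa, gtv_pa, gtvn_pa, config.margins)
    pa_ap = ar.pa_aperture(pa_b, config.margins)
    mlc = MLCModel()
    a, b, jaws = ar.fit_mlc(pa_ap, mlc, mode="cover")
    pa_beam.mlc_a, pa_beam.mlc_b, pa_beam.jaws = a, b, jaws

    log.info("stage: lateral borders, RT aperture, LT mirror")
    lm_rt = ar.project_landmarks(landmarks, rt_beam)
    gtv_rt = project_mask(gtv, rt_beam)
    gtvn_rt = project_mask(gtvn, rt_beam)
    lat_b = ar.lateral_borders(lm_rt, pa_b, gtv_rt, gtvn_rt, config.margins)
    lat_ap = ar.rectangle_aperture(lat_b, corner_leg=0.0)
    a, b, jaws = ar.fit_mlc(lat_ap, mlc, mode="cover")
    rt_beam.mlc_a, rt_beam.mlc_b, rt_beam.jaws = a, b, jaws
    if config.wedge_angle > 0:
        rt_beam.wedge = Wedge(config.wedge_angle, heel_posterior(rt_beam))
    lt_beam = ar.mirror_lateral(rt_beam)
    lt_beam.id = "LT"

    beams = [pa_beam, lt_beam, rt_beam]
    if config.geometry == "4-field":
        ap_beam = Beam(id="AP", role="AP", gantry_angle=0.0, isocenter=iso)
        ap_beam.mlc_a = None if pa_beam.mlc_b is None else -np.asarray(pa_beam.mlc_b)
        ap_beam.mlc_b = None if pa_beam.mlc_a is None else -np.asarray(pa_beam.mlc_a)
        ap_beam.jaws = (-pa_beam.jaws[1], -pa_beam.jaws[0], pa_beam.jaws[2], pa_beam.jaws[3])
        beams.append(ap_beam)

    log.info("stage: planning ROI construction")
    plan = Plan(
        density=density,
        body=body,
        rx=config.rx,
        fractions=config.fractions,
        normalization=NormalizationSpec(rx=config.rx, mode="volume",
                                        q_percent=config.normalization_q),
        dose_model=config.dose_model,
        mlc=mlc,
    )
    weights = initialize_weights([b_.role for b_ in beams])
    for beam, w in zip(beams, weights):
        plan.add_beam(beam, w)
    plan.rois = build_planning_rois(beams, body, mlc=mlc, model=config.dose_model)

    aux = {
        "landmarks": landmarks,
        "gtv": gtv, "gtvn": gtvn,
        "gtv_exp": gtv_exp, "gtvn_exp": gtvn_exp,
        "pa_borders": pa_b, "lat_borders": lat_b,
        "lm_rt": lm_rt,
    }
    return plan, aux


def run_end_to_end(config: RunConfig) -> dict:
    """Full chain; returns a machine-readable run report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    plan, aux = build_primary_plan(config)

    log.info("stage: field-in-field iteration")
    plan, history = fif_iterate(plan, config.fif, config.optimizer)
    dose, _ = plan.normalized_dose()

    report: dict = {
        "seed": config.seed,
        "geometry": config.geometry,
        "prescription": {"rx_gy": config.rx, "fractions": config.fractions},
        "primary": {
            "n_beams": len(plan.beams),
            "n_subfields": plan.n_subfields(),
            "weights": [round(w, 6) for w in plan.weights],
            "termination_reason": history[-1].termination_reason,
            "hotspot_percent_before": round(history[0].hotspot_dose_percent, 2),
            "hotspot_percent_after": round(history[-1].hotspot_dose_percent, 2),
            "v107_proi_before": round(history[0].v107_proi_percent, 3),
            "v107_proi_after": round(history[-1].v107_proi_percent, 3),
            "proi_metrics": {k: round(v, 4) for k, v in
                             dose_metrics(dose, plan.rois.proi, config.rx).items()},
            "iterations": [
                {
                    "iteration": r.iteration,
                    "hotspot_dose_percent": round(r.hotspot_dose_percent, 2),
                    "v107_proi_percent": round(r.v107_proi_percent, 3),
                    "action": r.action,
                    "n_subfields": r.n_subfields,
                    "target_percent": r.target_percent,
                }
                for r in history
            ],
        },
    }

    if config.with_boost:
        log.info("stage: boost fields")
        gtv2 = expand_mask(aux["gtv"], config.boost_expansion_mm)
        gtvn2 = expand_mask(aux["gtvn"], config.boost_expansion_mm)
        rt = plan.beam_by_role("RT")
        bst_rt = Beam(id="BstRT", role="BstRT", gantry_angle=270.0, isocenter=rt.isocenter)
        gtv2_rt = project_mask(gtv2, bst_rt)
        gtvn2_rt = project_mask(gtvn2, bst_rt)
        bst_ap = ar.boost_aperture(gtv2_rt, gtvn2_rt, aux["lm_rt"], config.margins)
        a, b, jaws = ar.fit_mlc(bst_ap, plan.mlc, mode="cover")
        bst_rt.mlc_a, bst_rt.mlc_b, bst_rt.jaws = a, b, jaws
        boost = add_boost(plan, bst_rt, config.boost)
        report["boost"] = {
            "rx_gy": config.boost.rx,
            "fractions": config.boost.fractions,
            "wedge_angle": config.boost.wedge_angle,
            "n_beams": len(boost.beams),
            "coverage_percent": round(boost.coverage_percent, 3),
            "boost_volume_cm3": round(
                float(boost.boost_volume.values.sum()) * boost.boost_volume.voxel_volume_cm3, 2
            ),
        }
        aux["boost"] = boost

    report["success"] = True
    if config.output_dir:
        export_plan(plan, dose, plan.rois, config.output_dir, report=report,
                    boost=aux.get("boost"))
    return report


def export_plan(plan: Plan, dose: VoxelGrid, rois, directory: str,
                report: dict | None = None, boost=None, dicom: bool = False) -> list[str]:
    """Write grids (one dose file per beam plus the plan total), ROIs, report.

    DICOM RT export is attempted only when requested; a missing pydicom
    dependency downgrades to a logged notice.
    """
    os.makedirs(directory, exist_ok=True)
    written: list[str] = []

    def _w(name: str, grid: VoxelGrid):
        path = os.path.join(directory, name)
        save_grid(grid, path)
        written.append(path)

    for bd in plan.compute_beam_doses():
        _w(f"beamdose_{bd.beam_id}.fgrid", bd.dose)
    _w("plan_dose.fgrid", dose)
    _w("density.fgrid", plan.density)
    for name, mask in rois.masks().items():
        _w(f"roi_{name}.fgrid", mask)
    if boost is not None:
        _w("boost_dose.fgrid", boost.dose)
        _w("roi_boost_volume.fgrid", boost.boost_volume)
    if report is not None:
        path = os.path.join(directory, "report.json")
        with open(path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(path)
    if dicom:
        try:
            from .dicom_export import export_rt_series

            written += export_rt_series(plan, dose, directory)
        except ImportError:
            log.info("pydicom not available: skipping DICOM RT export")
    return written
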