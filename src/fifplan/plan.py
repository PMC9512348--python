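"""Plan container: ordered beams, prescription, normalization, dose cache."""

from __future__ import annotations

from dataclasses import dataclass, field

from .dose import BeamDose, DoseModel, PlanningROIs, beam_dose, plan_dose
from .geometry import Beam, MLCModel
from .grid import VoxelGrid
from .optimize import NormalizationSpec, normalize


@dataclass
class Plan:
    """An ordered beam set on a phantom, with its prescription and dose cache.

    ``beams`` holds primaries first, then FIF subfields in creation order;
    ``weights`` are MU fractions aligned with ``beams``.  Per-beam dose grids
    (dose per unit weight) are cached and recomputed only for new beams.
    """

    density: VoxelGrid
    body: VoxelGrid
    beams: list[Beam] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)
    rx: float = 45.0
    fractions: int = 25
    normalization: NormalizationSpec | None = None
    rois: PlanningROIs | None = None
    dose_model: DoseModel = field(default_factory=DoseModel)
    mlc: MLCModel = field(default_factory=MLCModel)
    beam_doses: dict = field(default_factory=dict)
    norm_factor: float = 1.0
    history: list = field(default_factory=list)

    def add_beam(self, beam: Beam, weight: float) -> None:
        self.beams.append(beam)
        self.weights.append(float(weight))

    def remove_beam(self, beam_id: str) -> None:
        idx = next(i for i, b in enumerate(self.beams) if b.id == beam_id)
        self.beams.pop(idx)
        self.weights.pop(idx)
        self.beam_doses.pop(beam_id, None)

    @property
    def roles(self) -> list[str]:
        return [b.role for b in self.beams]

    def beam_by_role(self, role: str) -> Beam:
        return next(b for b in self.beams if b.role == role)

    def n_subfields(self) -> int:
        return sum(1 for b in self.beams if b.role == "subfield")

    def compute_beam_doses(self) -> list[BeamDose]:
        """Per-beam dose grids, computing any beam not yet cached."""
        out = []
        for b in self.beams:
            if b.id not in self.beam_doses:
                self.beam_doses[b.id] = beam_dose(b, self.density, self.dose_model, self.mlc)
            out.append(self.beam_doses[b.id])
        return out

    def raw_dose(self) -> VoxelGrid:
        return plan_dose(self.compute_beam_doses(), self.weights)

    def normalized_dose(self) -> tuple[VoxelGrid, float]:
        """Plan dose after renormalization; updates the stored MU factor."""
        if self.normalization is None or self.rois is None:
            raise ValueError("plan has no normalization spec or ROIs")
        dose, factor = normalize(self.raw_dose(), self.normalization, self.rois.proi)
        self.norm_factor = factor
        return dose, factor
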