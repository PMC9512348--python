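import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fifplan import PhantomSpec, VoxelGrid, generate_phantom
from fifplan.workflow import RunConfig, build_primary_plan


def coarse_spec(seed: int = 0, **kw) -> PhantomSpec:
    """Reference anatomy at 5 mm voxels: fast enough for unit tests."""
    base = PhantomSpec()
    extent = np.array(base.shape) * np.array(base.spacing_mm)
    shape = tuple(int(round(e / 5.0)) for e in extent)
    return PhantomSpec(shape=shape, spacing_mm=(5.0, 5.0, 5.0), seed=seed, **kw)


@pytest.fixture(scope="session")
def coarse_phantom():
    return generate_phantom(coarse_spec())


@pytest.fixture(scope="session")
def coarse_plan_built():
    """A primary plan on the coarse phantom; treat as read-only."""
    cfg = RunConfig()
    cfg.phantom = coarse_spec()
    plan, aux = build_primary_plan(cfg)
    return cfg, plan, aux


@pytest.fixture()
def coarse_plan_factory():
    """Fresh (mutable) coarse primary plan per call."""

    def _make(**cfg_kw):
        cfg = RunConfig(**cfg_kw)
        cfg.phantom = coarse_spec()
        plan, aux = build_primary_plan(cfg)
        return cfg, plan, aux

    return _make


def small_grid(shape=(8, 8, 8), spacing=2.0, fill=0.0) -> VoxelGrid:
    sp = np.full(3, float(spacing))
    origin = -0.5 * sp * (np.array(shape) - 1)
    return VoxelGrid(np.full(shape, fill), origin, sp)


def mask_from(grid: VoxelGrid, predicate) -> VoxelGrid:
    idx = np.indices(grid.shape).reshape(3, -1).T
    pts = grid.origin + idx * grid.spacing
    vals = predicate(pts).reshape(grid.shape)
    return grid.like(vals.astype(np.uint8))
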