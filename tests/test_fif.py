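import numpy as np
import pytest

from fifplan import (
    Beam,
    FIFConfig,
    add_boost,
    build_subfield,
    fif_iterate,
    find_hotspots,
    heel_posterior,
    hotspot_dose_percent,
    project_mask,
)
from fifplan.apertures import mlc_opening
from fifplan.fif import BoostConfig

from conftest import small_grid

RX = 45.0


def dose_grid(shape=(20, 20, 20), spacing=2.0, level=1.0):
    g = small_grid(shape, spacing, fill=level * RX)
    return g


def blob_of_voxels(grid, n_voxels, start=(2, 2, 2)):
    """A face-connected snake of exactly n voxels."""
    out = np.zeros(grid.shape, dtype=bool)
    i, j, k = start
    for step in range(n_voxels):
        out[i, j, k] = True
        i += 1
        if i >= grid.shape[0] - 2:
            i = start[0]
            j += 1
            if j >= grid.shape[1] - 2:
                j = start[1]
                k += 1
    return out


class TestFindHotspots:
    def test_uniform_dose_at_rx_has_no_hotspot(self):
        g = dose_grid(level=1.0)
        assert find_hotspots(g, RX, 107.0) == []

    @pytest.mark.parametrize("vol_cm3,expected", [(7.0, 0), (9.0, 1)])
    def test_minimum_volume_boundary_voxel_exact(self, vol_cm3, expected):
        # 2 mm voxels: 0.008 cm3 each; construct the blob voxel-exactly
        g = dose_grid(shape=(24, 24, 24), spacing=2.0, level=1.0)
        n = int(round(vol_cm3 / g.voxel_volume_cm3))
        blob = blob_of_voxels(g, n)
        g.values[blob] = 1.10 * RX
        found = find_hotspots(g, RX, 107.0, min_volume_cm3=8.0)
        assert len(found) == expected

    def test_blob_of_exactly_minimum_volume_reported(self):
        g = dose_grid(shape=(24, 24, 24), spacing=2.0)
        n = int(round(8.0 / g.voxel_volume_cm3))
        g.values[blob_of_voxels(g, n)] = 1.2 * RX
        found = find_hotspots(g, RX, 107.0, min_volume_cm3=8.0)
        assert len(found) == 1
        assert found[0].volume_cm3 == pytest.approx(8.0)

    def test_two_blobs_sorted_by_volume(self):
        g = dose_grid(shape=(40, 20, 20), spacing=2.5)
        g.values[2:10, 2:10, 2:10] = 1.2 * RX      # 8^3 voxels
        g.values[25:31, 4:10, 4:10] = 1.3 * RX     # 6^3 voxels
        found = find_hotspots(g, RX, 107.0, min_volume_cm3=1.0)
        assert len(found) == 2
        assert found[0].volume_cm3 > found[1].volume_cm3
        assert found[1].max_dose == pytest.approx(1.3 * RX)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_diagonal_voxels_connectivity(self, connectivity):
        g = dose_grid(shape=(10, 10, 10), spacing=10.0)  # 1 cm3 voxels
        g.values[2, 2, 2] = 1.2 * RX
        g.values[3, 3, 3] = 1.2 * RX  # corner-adjacent only
        found = find_hotspots(g, RX, 107.0, min_volume_cm3=2.0,
                              connectivity=connectivity)
        assert len(found) == (1 if connectivity == 26 else 0)


class TestHotspotDosePercent:
    def test_uniform_110_percent(self):
        g = dose_grid(shape=(15, 15, 15), spacing=2.5, level=1.10)
        h = hotspot_dose_percent(g, RX)
        assert h == pytest.approx(110.0, abs=0.11)

    def test_invariant_to_cold_voxels(self):
        g = dose_grid(shape=(20, 20, 20), spacing=2.5, level=1.10)
        h0 = hotspot_dose_percent(g, RX)
        g.values[:4] = 0.1 * RX
        assert hotspot_dose_percent(g, RX) == pytest.approx(h0, abs=0.11)

    def test_two_level_construction(self):
        # broad 105% region plus a 9 cm3 island at 112% -> 112%
        g = dose_grid(shape=(30, 30, 30), spacing=2.5, level=1.05)
        n = int(round(9.0 / g.voxel_volume_cm3))
        g.values[blob_of_voxels(g, n)] = 1.12 * RX
        assert hotspot_dose_percent(g, RX) == pytest.approx(112.0, abs=0.11)

    def test_island_below_minimum_volume_ignored(self):
        g = dose_grid(shape=(30, 30, 30), spacing=2.5, level=1.05)
        n = int(round(4.0 / g.voxel_volume_cm3))  # too small to count
        g.values[blob_of_voxels(g, n)] = 1.30 * RX
        assert hotspot_dose_percent(g, RX) == pytest.approx(105.0, abs=0.11)

    def test_insufficient_support_returns_zero_with_warning(self):
        g = dose_grid(shape=(4, 4, 4), spacing=2.0, level=0.0)
        g.values[0, 0, 0] = RX
        with pytest.warns(UserWarning):
            assert hotspot_dose_percent(g, RX) == 0.0


class TestConnectedComponentOracle:
    @staticmethod
    def flood_fill_components(mask, connectivity):
        """Brute-force BFS flood fill, independent of scipy labeling."""
        offsets = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if (di, dj, dk) == (0, 0, 0):
                        continue
                    if connectivity == 6 and abs(di) + abs(dj) + abs(dk) != 1:
                        continue
                    offsets.append((di, dj, dk))
        seen = np.zeros_like(mask, dtype=bool)
        comps = []
        for idx in np.argwhere(mask):
            t = tuple(idx)
            if seen[t]:
                continue
            stack, comp = [t], []
            seen[t] = True
            while stack:
                cur = stack.pop()
                comp.append(cur)
                for off in offsets:
                    nb = tuple(np.array(cur) + off)
                    if any(c < 0 or c >= s for c, s in zip(nb, mask.shape)):
                        continue
                    if mask[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
            comps.append(sorted(comp))
        return sorted(comps)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_labeling_equals_flood_fill(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(25):
            shape = tuple(rng.integers(6, 14, size=3))
            g = small_grid(shape, 5.0)
            mask = rng.random(shape) < 0.25
            g.values[:] = np.where(mask, 1.2 * RX, 0.5 * RX)
            found = find_hotspots(g, RX, 107.0, min_volume_cm3=0.0,
                                  connectivity=connectivity)
            got = sorted(sorted(map(tuple, h.indices)) for h in found)
            expected = self.flood_fill_components(mask, connectivity)
            assert got == expected


class TestBuildSubfield:
    def test_hotspot_outside_parent_opening_is_noop(self, coarse_plan_built):
        _, plan, _ = coarse_plan_built
        import copy

        plan = copy.deepcopy(plan)
        dose = dose_grid(plan.density.shape, 1.0)
        dose = plan.density.like(np.full(plan.density.shape, RX))
        # hotspot far outside every aperture (superior corner of the grid)
        dose.values[2:4, 2:4, -3:] = 1.5 * RX
        hs = find_hotspots(dose, RX, 107.0, min_volume_cm3=0.0)
        plan.density = plan.density  # unchanged
        sub = build_subfield(plan, plan.beam_by_role("LT"), hs, "SF")
        assert sub is None

    def test_central_hotspot_blocked_within_leaf_resolution(self, coarse_plan_built):
        _, plan, _ = coarse_plan_built
        import copy

        plan = copy.deepcopy(plan)
        g = plan.density
        iso = plan.beams[0].isocenter
        dose = g.like(np.zeros(g.shape))
        idx = np.round((iso - g.origin) / g.spacing).astype(int)
        dose.values[idx[0] - 2 : idx[0] + 6, idx[1] - 2 : idx[1] + 3, idx[2] - 2 : idx[2] + 3] = 1.2 * RX
        hs = find_hotspots(dose, RX, 107.0, min_volume_cm3=0.0)
        parent = plan.beam_by_role("LT")
        sub = build_subfield(plan, parent, hs, "SF")
        assert sub is not None
        parent_open = mlc_opening(parent, plan.mlc)
        sub_open = mlc_opening(sub, plan.mlc)
        # subfield strictly inside parent, jaws identical
        assert np.all(parent_open.mask.astype(bool) >= sub_open.mask.astype(bool))
        assert sub_open.area_mm2() < parent_open.area_mm2()
        assert sub.jaws == parent.jaws
        # blocked region covers the projected (truncated) hotspot up to one
        # leaf width per row
        mask3d = hs[0].mask(g)
        proj = project_mask(mask3d, parent, truncate_distal=True)
        blocked = parent_open.mask.astype(bool) & ~sub_open.mask.astype(bool)
        uncovered = proj.mask.astype(bool) & parent_open.mask.astype(bool) & ~blocked
        assert uncovered.sum() <= 0.05 * proj.mask.sum() + 25

    def test_two_objects_covered_from_nearest_banks(self, coarse_plan_built):
        _, plan, _ = coarse_plan_built
        import copy

        plan = copy.deepcopy(plan)
        g = plan.density
        parent = plan.beam_by_role("LT")
        x1, x2, y1, y2 = parent.jaws
        dose = g.like(np.zeros(g.shape))
        iso = parent.isocenter
        # two hot slabs near opposite BEV-x edges of the LT field
        # (BEV-x for LT is -patient-y)
        idx = np.round((iso - g.origin) / g.spacing).astype(int)
        dose.values[idx[0]: idx[0] + 4, idx[1] - 9: idx[1] - 6, idx[2] - 3: idx[2] + 3] = 1.3 * RX
        dose.values[idx[0]: idx[0] + 4, idx[1] + 5: idx[1] + 8, idx[2] - 3: idx[2] + 3] = 1.3 * RX
        hs = find_hotspots(dose, RX, 107.0, min_volume_cm3=0.0)
        sub = build_subfield(plan, parent, hs, "SF", keep_largest_only=False)
        assert sub is not None
        # each bank moved somewhere relative to the parent: one object per side
        assert np.any(np.asarray(sub.mlc_a) > np.asarray(parent.mlc_a) + 1e-9)
        assert np.any(np.asarray(sub.mlc_b) < np.asarray(parent.mlc_b) - 1e-9)


class TestFIFLoop:
    def test_loop_contract_on_coarse_phantom(self, coarse_plan_factory):
        cfg, plan, _ = coarse_plan_factory()
        plan, hist = fif_iterate(plan, cfg.fif, cfg.optimizer)
        assert hist[-1].action == "stop"
        assert hist[-1].termination_reason in (1, 2, 3)
        assert plan.n_subfields() <= cfg.fif.max_subfields
        # monotone acceptance: accepted records never increase the hotspot
        accepted = [r for r in hist
                    if r.action in ("init", "weights_only", "subfield_added", "stop")]
        hs = [r.hotspot_dose_percent for r in accepted]
        assert all(a >= b - 1e-6 for a, b in zip(hs, hs[1:]))
        # renormalization precedes every hotspot check
        assert all(r.renormalized for r in hist)

    def test_subfields_contained_in_parents(self, coarse_plan_factory):
        cfg, plan, _ = coarse_plan_factory()
        plan, _ = fif_iterate(plan, cfg.fif, cfg.optimizer)
        parents = {b.id: b for b in plan.beams if b.role != "subfield"}
        for b in plan.beams:
            if b.role != "subfield":
                continue
            parent = parents[b.parent_id]
            assert b.jaws == parent.jaws
            po = mlc_opening(parent, plan.mlc).mask.astype(bool)
            so = mlc_opening(b, plan.mlc).mask.astype(bool)
            assert np.all(po >= so)
            assert b.wedge is None

    def test_zero_max_subfields_reduces_to_weights_only(self, coarse_plan_factory):
        cfg, plan, _ = coarse_plan_factory()
        cfg.fif.max_subfields = 0
        plan, hist = fif_iterate(plan, cfg.fif, cfg.optimizer)
        assert plan.n_subfields() == 0
        assert all(r.action in ("init", "weights_only", "weights_reverted", "stop")
                   for r in hist)

    def test_relaxation_raises_target_by_increment(self, coarse_plan_factory):
        cfg, plan, _ = coarse_plan_factory(wedge_angle=0.0)
        cfg.fif.relax_on_stall = True
        cfg.fif.max_iterations = 8
        plan, hist = fif_iterate(plan, cfg.fif, cfg.optimizer)
        relaxed = [r for r in hist if r.action == "relaxed"]
        if relaxed:  # stall occurred: target stepped by exactly 1%
            steps = {round(b.target_percent - a.target_percent, 6)
                     for a, b in zip(hist, hist[1:]) if b.action == "relaxed"}
            assert steps == {cfg.fif.relax_increment}

    def test_history_weights_match_beam_count(self, coarse_plan_factory):
        cfg, plan, _ = coarse_plan_factory()
        plan, hist = fif_iterate(plan, cfg.fif, cfg.optimizer)
        assert len(hist[-1].weights) == len(plan.beams)


class TestBoost:
    def make_boost_parent(self, plan, aux, cfg):
        from fifplan import boost_aperture, expand_mask, fit_mlc

        rt = plan.beam_by_role("RT")
        bst = Beam(id="BstRT", role="BstRT", gantry_angle=270.0, isocenter=rt.isocenter)
        gtv2 = expand_mask(aux["gtv"], 20.0)
        gtvn2 = expand_mask(aux["gtvn"], 20.0)
        ap = boost_aperture(
            project_mask(gtv2, bst), project_mask(gtvn2, bst), aux["lm_rt"]
        )
        bst.mlc_a, bst.mlc_b, bst.jaws = fit_mlc(ap, plan.mlc, mode="cover")
        return bst

    def test_boost_beams_mirrored_and_coverage(self, coarse_plan_built):
        cfg, plan, aux = coarse_plan_built
        import copy

        plan = copy.deepcopy(plan)
        bst = self.make_boost_parent(plan, aux, cfg)
        result = add_boost(plan, bst, BoostConfig())
        assert len(result.beams) == 2
        roles = {b.role for b in result.beams}
        assert roles == {"BstRT", "BstLT"}
        assert result.beams[0].wedge.angle_deg == 15.0
        assert result.beams[1].wedge.angle_deg == 15.0
        assert result.beams[0].wedge.heel == -result.beams[1].wedge.heel
        assert result.coverage_percent >= 98.0

    def test_boost_leaves_primary_weights_untouched(self, coarse_plan_built):
        cfg, plan, aux = coarse_plan_built
        import copy

        plan = copy.deepcopy(plan)
        before = list(plan.weights)
        bst = self.make_boost_parent(plan, aux, cfg)
        add_boost(plan, bst, BoostConfig())
        assert plan.weights == before

    def test_empty_boost_volume_rejected(self, coarse_plan_built):
        cfg, plan, aux = coarse_plan_built
        import copy

        plan = copy.deepcopy(plan)
        bst = self.make_boost_parent(plan, aux, cfg)
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            add_boost(plan, bst, BoostConfig(erosion_mm=500.0))

    def test_heel_posterior_signs(self):
        rt = Beam(id="RT", role="RT", gantry_angle=270.0, isocenter=np.zeros(3))
        lt = Beam(id="LT", role="LT", gantry_angle=90.0, isocenter=np.zeros(3))
        assert heel_posterior(rt) == -1
        assert heel_posterior(lt) == +1
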