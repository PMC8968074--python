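"""Phantom geometry: rasterization, flow assignment, grouping, merging."""

import numpy as np
import pytest

from speckletomo.phantom import (
    FlowMap,
    OpticalProperties,
    Strand,
    assign_flows,
    bifurcation_graph_from_strands,
    build_grid_phantom,
    group_capillaries,
    merge_superstrands,
    rasterize_strands,
)


def straight_strand(sid, p0, p1, radius, **kw):
    return Strand(id=sid, centerline=np.array([p0, p1], dtype=float), radius=radius, **kw)


class TestBuildGridPhantom:
    def test_grid_shape_matches_extent_over_pitch(self):
        geometry, _ = build_grid_phantom(
            (2000.0, 2000.0, 1000.0), 5.0, [100.0], (500.0, 200.0), [20.0]
        )
        assert geometry.shape == (400, 400, 200)

    def test_empty_vessel_list_gives_empty_volume(self):
        geometry, strands = build_grid_phantom((100.0, 100.0, 100.0), 5.0, [], (50.0, 50.0), [])
        assert strands == []
        assert not geometry.label.any()

    def test_rasterized_cylinder_volume_matches_analytic(self):
        # one straight horizontal vessel: pi r^2 L within 15%
        pitch = 5.0
        s = straight_strand(1, (50.0, 250.0, 250.0), (550.0, 250.0, 250.0), 10.0)
        geometry = rasterize_strands((120, 100, 100), pitch, [s])
        voxels = int((geometry.label == 1).sum())
        analytic = np.pi * 10.0**2 * 500.0 / pitch**3
        assert abs(voxels - analytic) / analytic < 0.15

    def test_rasterization_converges_with_pitch(self):
        # relative volume error shrinks as the grid is refined
        # the voxel-center-within-radius rule fills a capsule around the
        # centerline segment: cylinder plus two hemispherical end caps
        capsule = np.pi * 12.0**2 * 400.0 + 4.0 / 3.0 * np.pi * 12.0**3
        errs = []
        for pitch, n in [(10.0, 60), (2.5, 240)]:
            s = straight_strand(1, (100.0, 300.0, 300.0), (500.0, 300.0, 300.0), 12.0)
            geometry = rasterize_strands((n, n, n), pitch, [s])
            voxels = int((geometry.label == 1).sum())
            errs.append(abs(voxels - capsule / pitch**3) / (capsule / pitch**3))
        assert errs[1] < errs[0]

    def test_label_strand_bijection(self):
        geometry, strands = build_grid_phantom(
            (600.0, 600.0, 400.0), 10.0, [100.0, 250.0], (300.0, 600.0), [20.0, 15.0]
        )
        ids_in_labels = set(np.unique(geometry.label)) - {0}
        assert ids_in_labels == {s.id for s in strands}

    def test_overlapping_parallel_vessels_rejected(self):
        # layers 0 and 2 run parallel (both along x) and interpenetrate
        with pytest.raises(ValueError, match="overlap"):
            build_grid_phantom(
                (600.0, 600.0, 400.0), 10.0, [100.0, 250.0, 108.0],
                (300.0, 600.0), [30.0, 15.0, 30.0],
            )

    def test_descending_vessels_start_below_first_layer(self):
        _, strands = build_grid_phantom(
            (600.0, 600.0, 400.0), 10.0, [100.0, 250.0], (300.0, 600.0), [20.0, 15.0]
        )
        desc = [s for s in strands if s.orientation == "descending"]
        assert len(desc) == 2
        for s in desc:
            assert s.centerline[0, 2] == 100.0
            assert np.allclose(s.directions, [0, 0, 1])


class TestOpticalProperties:
    @pytest.mark.parametrize(
        "kw", [dict(mu_a=-0.1, mu_s=10, g=0.9), dict(mu_a=0.1, mu_s=0, g=0.9),
               dict(mu_a=0.1, mu_s=10, g=1.0)]
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ValueError):
            OpticalProperties(**kw)


class TestAssignFlows:
    def test_uniform_random_within_range(self, small_phantom):
        _, strands = small_phantom
        flows = assign_flows(strands, "uniform_random", lo=0.3, hi=5.0, seed=42)
        assert np.all((flows.v >= 0.3) & (flows.v <= 5.0))
        again = assign_flows(strands, "uniform_random", lo=0.3, hi=5.0, seed=42)
        assert np.array_equal(flows.v, again.v)

    def test_single_entry_table_constant(self, small_phantom):
        _, strands = small_phantom
        with pytest.warns(UserWarning):
            flows = assign_flows(strands, "radius_lookup", table=[(1.0, 1.0)])
        assert np.allclose(flows.v, 1.0)

    def test_monotone_table_respects_radius_order(self):
        strands = [
            straight_strand(1, (0, 50, 50), (100, 50, 50), 4.0, tissue_class="capillary"),
            straight_strand(2, (0, 80, 50), (100, 80, 50), 20.0),
        ]
        flows = assign_flows(strands, "radius_lookup")
        assert flows[1] <= flows[2]

    def test_non_monotone_table_rejected(self, small_phantom):
        _, strands = small_phantom
        with pytest.raises(ValueError):
            assign_flows(strands, "radius_lookup", table=[(1.0, 2.0), (5.0, 1.0)])

    def test_flow_map_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError):
            FlowMap(group_ids=[1], v=[-0.1])
        with pytest.raises(ValueError):
            FlowMap(group_ids=[1], v=[np.nan])


class TestGroupCapillaries:
    def _caps(self):
        return [
            straight_strand(1, (10, 10, 10), (60, 10, 10), 3.0, tissue_class="capillary"),
            straight_strand(2, (10, 60, 10), (60, 60, 10), 3.0, tissue_class="capillary"),
            straight_strand(3, (400, 400, 10), (450, 400, 10), 3.0, tissue_class="capillary"),
            straight_strand(4, (10, 30, 10), (60, 30, 10), 20.0),
        ]

    def test_same_cube_shares_group(self):
        out = group_capillaries(self._caps(), 250.0)
        by_id = {s.id: s for s in out}
        assert by_id[1].group_id == by_id[2].group_id
        assert by_id[3].group_id != by_id[1].group_id

    def test_noncapillary_untouched_even_in_same_cube(self):
        out = group_capillaries(self._caps(), 250.0)
        by_id = {s.id: s for s in out}
        assert by_id[4].group_id == 4

    def test_never_increases_unknowns_and_idempotent(self):
        out1 = group_capillaries(self._caps(), 250.0)
        n_groups = len({s.group_id for s in out1})
        assert n_groups <= len(out1)
        out2 = group_capillaries(out1, 250.0)
        assert [s.group_id for s in out1] == [s.group_id for s in out2]

    def test_degenerate_cubes_keep_every_capillary_separate(self):
        out = group_capillaries(self._caps(), 1e-9)
        caps = [s for s in out if s.is_capillary]
        assert len({s.group_id for s in caps}) == len(caps)


class TestMergeSuperstrands:
    def _y_junction(self, radii):
        node = (100.0, 100.0, 100.0)
        return [
            straight_strand(1, (0.0, 100.0, 100.0), node, radii[0]),
            straight_strand(2, node, (200.0, 100.0, 100.0), radii[1]),
            straight_strand(3, node, (100.0, 200.0, 100.0), radii[2]),
        ]

    def test_two_largest_merge_at_bifurcation(self):
        merged = merge_superstrands(self._y_junction((20.0, 19.0, 5.0)))
        assert len(merged) == 2
        big = next(s for s in merged if s.id == 1)
        assert len(big.centerline) == 3  # concatenated trace
        assert any(s.radius == 5.0 for s in merged)

    def test_chain_without_bifurcations_unchanged(self):
        chain = [
            straight_strand(1, (0, 0, 50), (100, 0, 50), 10.0),
            straight_strand(2, (100, 0, 50), (200, 0, 50), 10.0),
        ]
        merged = merge_superstrands(chain)
        assert sorted(s.id for s in merged) == [1, 2]

    def test_radius_tie_breaks_to_lower_ids(self):
        merged = merge_superstrands(self._y_junction((10.0, 10.0, 10.0)))
        merged_ids = {s.id for s in merged}
        # strands 1 and 2 merge (lowest ids), strand 3 survives alone
        assert merged_ids == {1, 3}
        assert len(next(s for s in merged if s.id == 1).centerline) == 3

    def test_graph_construction_finds_bifurcation(self):
        graph = bifurcation_graph_from_strands(self._y_junction((20.0, 19.0, 5.0)))
        degrees = sorted(len(v) for v in graph.values())
        assert degrees[-1] == 3
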