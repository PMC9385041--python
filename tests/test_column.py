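"""Column generator: determinism, periodicity, assembly and statistics."""

import numpy as np
import pytest

from cortox.column import (BEAD_DIAMETER, BranchingSpec, DiameterLaw,
                           assemble_column, bead_volume_arithmetic,
                           generate_arteriole_tree, generate_capillary_cube,
                           generate_column, network_stats)
from cortox.graph import VesselGraph


class TestCapillaryCube:
    def test_segment_count_matches_target_density(self):
        cube = generate_capillary_cube(375.0, 10846.0, seed=3)
        expected = 10846.0 * 0.375**3  # ~572
        assert abs(cube.n_segments - expected) <= 0.1 * expected

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            generate_capillary_cube(375.0, 0.0, seed=0)

    def test_unattainable_density_raises(self):
        # too sparse for any connected lattice: explicit failure, not a
        # silent undershoot
        with pytest.raises(RuntimeError):
            generate_capillary_cube(375.0, 80.0, seed=0)

    def test_same_seed_identical_graphs(self):
        a = generate_capillary_cube(seed=11)
        b = generate_capillary_cube(seed=11)
        assert np.array_equal(a.node_xyz, b.node_xyz)
        assert np.array_equal(a.seg_nodes, b.seg_nodes)
        assert np.array_equal(a.diameters, b.diameters)

    def test_minimum_image_lengths(self):
        """Periodicity: stored lengths equal minimum-image distances, and
        wrapped segments are shorter than the naive in-box distance."""
        cube = generate_capillary_cube(seed=5)
        assert np.allclose(cube.lengths, cube.euclidean_lengths())
        naive = np.linalg.norm(
            cube.node_xyz[cube.seg_nodes[:, 1]]
            - cube.node_xyz[cube.seg_nodes[:, 0]], axis=1)
        assert np.any(naive > cube.lengths + 1.0)  # some segments wrap

    def test_diameters_below_bead_size(self):
        cube = generate_capillary_cube(seed=7)
        assert np.all(cube.diameters < BEAD_DIAMETER)


class TestArterioleTree:
    def test_descends_with_decreasing_diameters(self):
        tree = generate_arteriole_tree(seed=4)
        assert tree.inlet == 0
        assert np.all(tree.node_xyz[0] == 0)
        assert np.any(tree.diameters < BEAD_DIAMETER)
        assert tree.diameters.max() > BEAD_DIAMETER

    @pytest.mark.parametrize("seed", range(10))
    def test_six_to_fifteen_trap_sites_per_tree(self, seed):
        """Each tree presents 6-15 distinct first-trap sites: the drawn
        supra-threshold branches plus the first sub-bead trunk segment."""
        tree = generate_arteriole_tree(seed=seed)
        n_b = tree.meta["n_supra_branches"]
        assert 6 <= n_b + 1 <= 15

    def test_zero_generations_single_trap_site(self):
        """Without supra-threshold branches the trunk tapers through the
        bead size exactly once: one trapping site, all offshoots shadowed."""
        tree = generate_arteriole_tree(
            branching=BranchingSpec(n_supra_branches=(0, 0)), seed=1)
        assert tree.meta["n_supra_branches"] == 0
        supra = tree.diameters >= BEAD_DIAMETER
        supra_nodes = set(tree.seg_nodes[supra].ravel())
        first_sub = [i for i in range(tree.n_segments)
                     if not supra[i] and (tree.seg_nodes[i][0] in supra_nodes
                                          or tree.seg_nodes[i][1] in supra_nodes)]
        assert len(first_sub) == 1

    def test_inlet_diameter_at_or_below_bead_rejected(self):
        with pytest.raises(ValueError):
            generate_arteriole_tree(inlet_diameter=20.0, seed=0)

    def test_same_seed_identical_tree(self):
        a = generate_arteriole_tree(seed=9)
        b = generate_arteriole_tree(seed=9)
        assert np.array_equal(a.node_xyz, b.node_xyz)
        assert np.array_equal(a.diameters, b.diameters)


class TestAssembly:
    def test_column_connected_inside_box_with_single_inlet(self, default_column):
        col = default_column
        assert col.is_connected()
        assert col.inlet is not None
        assert np.all(col.node_xyz >= -1e-9)
        assert np.all(col.node_xyz <= col.box + 1e-9)
        # inlet on the top face at the lateral centre
        assert col.node_xyz[col.inlet][2] == 0.0
        assert np.allclose(col.node_xyz[col.inlet][:2], col.box[:2] / 2)

    def test_connector_segments_join_arteriole_to_capillaries(self, default_column):
        kinds = default_column.kinds
        assert np.count_nonzero(kinds == "connector") >= 1
        assert np.count_nonzero(kinds == "arteriole") >= 10
        assert np.count_nonzero(kinds == "capillary") >= 1000

    def test_assembly_preserves_trap_site_count(self):
        """Trimming/stacking never increases the number of first sub-bead
        arteriole segments beyond the untrimmed tree's count plus cuts."""
        cube = generate_capillary_cube(seed=2)
        tree = generate_arteriole_tree(seed=2)
        col = assemble_column(tree, cube)
        n_tree = tree.meta["n_supra_branches"] + 1
        art = col.kinds == "arteriole"
        # loose upper bound: sub-bead arteriole segments whose other end
        # continues a supra-bead segment
        sub = (col.diameters < BEAD_DIAMETER) & art
        sup = (col.diameters >= BEAD_DIAMETER) & art
        sup_nodes = set(col.seg_nodes[sup].ravel())
        first_sub = {tuple(sn) for sn, s in zip(col.seg_nodes, sub) if s
                     and (sn[0] in sup_nodes or sn[1] in sup_nodes)}
        assert len(first_sub) <= n_tree + 1


class TestNetworkStats:
    def test_single_arteriole_surface_density(self, default_column):
        st = network_stats(default_column)
        assert st.surface_density_per_mm2 == pytest.approx(1 / 0.375**2)
        assert st.surface_density_per_mm2 == pytest.approx(7.111, abs=0.001)

    def test_three_cylinder_volume_fraction_oracle(self):
        """Hand-built graph of three cylinders against hand arithmetic."""
        from conftest import toy_graph

        g = toy_graph(
            node_xyz=[[50, 50, 0], [50, 50, 40], [20, 50, 40], [80, 50, 40]],
            seg_nodes=[[0, 1], [1, 2], [1, 3]],
            diameters=[10.0, 6.0, 8.0],
        )
        st = network_stats(g)
        vol = (np.pi * 5**2 * 40 + np.pi * 3**2 * 30 + np.pi * 4**2 * 30)
        assert st.volume_fraction == pytest.approx(vol / 100.0**3, rel=1e-12)
        assert st.vessel_density_per_mm3 == pytest.approx(3 / 1e-3)

    def test_empty_graph_zero_stats(self):
        g = VesselGraph(
            node_xyz=np.empty((0, 3)), seg_nodes=np.empty((0, 2), dtype=int),
            diameters=np.empty(0), lengths=np.empty(0),
            kinds=np.empty(0, dtype=object), inlet=None,
            box=np.array([375.0, 375.0, 1500.0]))
        st = network_stats(g)
        assert st.vessel_density_per_mm3 == 0.0
        assert st.volume_fraction == 0.0


class TestBeadArithmetic:
    def test_microsphere_load_worked_example(self):
        """2.03 beads/mm^3 of 25 um beads: volume fraction 1.66e-5,
        1.66e-3 mL in a 100 mL territory, ~1% of a 0.17 mL thrombus."""
        frac, total, pct = bead_volume_arithmetic(2.03, 25.0, 100.0, 0.17)
        assert frac == pytest.approx(1.66e-5, rel=5e-3)
        assert total == pytest.approx(1.66e-3, rel=5e-3)
        assert pct == pytest.approx(1.0, abs=0.05)

    def test_rejects_non_positive_inputs(self):
        with pytest.raises(ValueError):
            bead_volume_arithmetic(0.0, 25.0, 100.0, 0.17)


class TestRoundTrip:
    def test_graph_csv_round_trip_lossless(self, tmp_path, default_column):
        default_column.write(tmp_path, "g")
        back = VesselGraph.read(tmp_path, "g")
        assert np.array_equal(back.node_xyz, default_column.node_xyz)
        assert np.array_equal(back.seg_nodes, default_column.seg_nodes)
        assert np.array_equal(back.diameters, default_column.diameters)
        assert np.array_equal(back.lengths, default_column.lengths)
        assert back.inlet == default_column.inlet
        assert np.array_equal(back.box, default_column.box)
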