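"""Oxygen transport: dissociation laws, kernel, and the Green's solver."""

import numpy as np
import pytest
from scipy.integrate import quad

from cortox.flow import apparent_viscosity, segment_conductance, solve_flow
from cortox.graph import VesselGraph
from cortox.oxygen import (GreensSolver, OxyParams, TissueGrid,
                           blood_oxygen_content, content_to_po2,
                           discretize_sources, greens_kernel, hill_saturation,
                           hypoxia_mask, metabolic_rate)
from cortox.units import UM_TO_CM


class TestHillCurve:
    def test_half_saturation_at_p50(self):
        assert hill_saturation(38.0, 3.0, 38.0) == 0.5

    def test_zero_at_zero(self):
        assert hill_saturation(0.0) == 0.0

    def test_value_at_arterial_po2(self):
        # S(90; n=3, P50=38) = 90^3 / (38^3 + 90^3), exact rational value
        expected = 729000 / (54872 + 729000)
        assert hill_saturation(90.0, 3.0, 38.0) == pytest.approx(
            expected, rel=1e-14)

    def test_strictly_increasing(self):
        p = np.linspace(0, 150, 400)
        s = hill_saturation(p)
        assert np.all(np.diff(s) > 0)

    def test_negative_po2_rejected(self):
        with pytest.raises(ValueError):
            hill_saturation(-1.0)


class TestBloodContent:
    def test_zero_po2_zero_content(self):
        assert blood_oxygen_content(0.0) == 0.0

    @pytest.mark.parametrize("po2", [1.0, 10.0, 50.0, 90.0])
    def test_inversion_round_trip(self, po2):
        c = blood_oxygen_content(po2)
        assert content_to_po2(c) == pytest.approx(po2, abs=1e-9)

    def test_dissolved_only_without_haemoglobin(self):
        p = OxyParams(C_Hb=1e-300)
        assert blood_oxygen_content(50.0, p) == pytest.approx(
            p.alpha_b * 50.0, rel=1e-9)


class TestMetabolicRate:
    def test_half_maximal_at_michaelis_constant(self):
        assert metabolic_rate(1.0, 6.72e-4, 1.0) == 6.72e-4 / 2

    def test_zero_at_zero(self):
        assert metabolic_rate(0.0) == 0.0

    def test_saturates_at_m0(self):
        assert metabolic_rate(1e6, 6.72e-4, 1.0) == pytest.approx(
            6.72e-4, rel=1e-5)


class TestGreensKernel:
    def test_inverse_distance_decay(self):
        a = greens_kernel([0, 0, 0], [100, 0, 0])
        b = greens_kernel([0, 0, 0], [200, 0, 0])
        assert a / b == pytest.approx(2.0, rel=1e-12)

    def test_symmetric_in_arguments(self):
        x, y = [10.0, 20.0, 30.0], [50.0, 5.0, 70.0]
        assert greens_kernel(x, y) == greens_kernel(y, x)

    def test_matches_closed_form_at_ten_radii(self):
        D_t, alpha_t = 2.41e-5, 3.89e-5
        for r_um in np.linspace(10, 1000, 10):
            expected = 1.0 / (4 * np.pi * D_t * alpha_t * r_um * UM_TO_CM)
            got = greens_kernel([0, 0, 0], [r_um, 0, 0], D_t, alpha_t)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_singular_at_zero_separation(self):
        with pytest.raises(ValueError):
            greens_kernel([1, 2, 3], [1, 2, 3])


class TestDiscretizeSources:
    def test_equal_elements_under_length_cap(self):
        g = VesselGraph(
            node_xyz=np.array([[0, 0, 0], [0, 0, 100.0]]),
            seg_nodes=np.array([[0, 1]]), diameters=np.array([10.0]),
            lengths=np.array([100.0]),
            kinds=np.array(["arteriole"], dtype=object), inlet=0)
        el = discretize_sources(g, 25.0)
        assert el.n == 4
        assert np.allclose(el.lengths, 25.0)

    def test_total_length_conserved(self, default_column):
        el = discretize_sources(default_column, 60.0)
        assert el.lengths.sum() == pytest.approx(
            default_column.lengths.sum(), rel=1e-9)
        assert np.all(el.lengths <= 60.0 + 1e-9)


def straight_vessel_fixture(box, diameter, flow_um3_s):
    g = VesselGraph(
        node_xyz=np.array([[box[0] / 2, box[1] / 2, 0.0],
                           [box[0] / 2, box[1] / 2, box[2]]]),
        seg_nodes=np.array([[0, 1]]), diameters=np.array([diameter]),
        lengths=np.array([box[2]]), kinds=np.array(["arteriole"], dtype=object),
        inlet=0, box=np.asarray(box, dtype=float))
    cond = segment_conductance(diameter, box[2], apparent_viscosity(diameter))
    fl = solve_flow(g, inlet_pressure=flow_um3_s / float(cond))
    return g, fl


class TestGreensSolver:
    def test_zero_metabolism_uniform_at_inlet_po2(self):
        box = (120.0, 120.0, 240.0)
        g, fl = straight_vessel_fixture(box, 8.0, 5e5)
        params = OxyParams(voxel_um=12.0, M0=1e-300)
        ox = GreensSolver(g, params).solve(fl)
        assert np.all(np.abs(ox.grid.po2 - 90.0) < 1e-3)

    def test_global_oxygen_balance_under_one_percent(self, default_column,
                                                     calibrated_flow):
        _, fl = calibrated_flow
        ox = GreensSolver(default_column, OxyParams(voxel_um=30.0)).solve(fl)
        assert ox.balance < 1e-2
        assert ox.converged

    def test_healthy_column_hypoxic_fraction_small(self, default_column,
                                                   calibrated_flow):
        """Under normal perfusion only a small share of tissue falls below
        the 10 mmHg hypoxia threshold."""
        _, fl = calibrated_flow
        ox = GreensSolver(default_column, OxyParams(voxel_um=30.0)).solve(fl)
        assert ox.hypoxic_fraction(10.0) < 0.05

    def test_blood_po2_non_increasing_along_flow(self):
        box = (120.0, 120.0, 480.0)
        g, fl = straight_vessel_fixture(box, 8.0, 2e5)
        ox = GreensSolver(g, OxyParams(voxel_um=12.0)).solve(fl)
        pb = ox.element_po2[~np.isnan(ox.element_po2)]
        assert np.all(np.diff(pb) <= 1e-9)

    def test_source_superposition_is_linear(self, default_column):
        """Doubling all source strengths doubles the source-term field."""
        gs = GreensSolver(default_column, OxyParams(voxel_um=30.0))
        rng = np.random.default_rng(0)
        q = rng.random(gs.elements.n).astype(np.float32)
        f1 = q @ gs.Gsv
        f2 = (2.0 * q) @ gs.Gsv
        assert np.allclose(f2, 2.0 * f1, rtol=1e-6)

    def test_krogh_radial_profile(self):
        """Single straight vessel in a tissue block with near-constant
        consumption: the mid-plane radial PO2 profile follows the
        closed-form line-source + uniform-sink solution."""
        box = np.array([120.0, 120.0, 480.0])
        g, fl = straight_vessel_fixture(box, 6.0, 1e6)
        params = OxyParams(voxel_um=4.0, P0=1e-6, max_element_um=4.0)
        grid = TissueGrid.for_box(box, 4.0)
        ox = GreensSolver(g, params, grid).solve(fl)

        centers = grid.centers().reshape(*grid.shape, 3)
        zmid = grid.shape[2] // 2
        sl = ox.grid.po2[:, :, zmid]
        cxy = centers[:, :, zmid, :2]
        r = np.hypot(cxy[..., 0] - 60.0, cxy[..., 1] - 60.0)

        K, M = params.kappa, params.M0
        a = 3.0 * UM_TO_CM
        qprime = M * (120.0 * UM_TO_CM) ** 2  # conservation per unit length

        def oracle_drop(r_um):
            return -quad(
                lambda rc: (qprime - M * np.pi * (rc**2 - a**2))
                / (2 * np.pi * K * rc), a, r_um * UM_TO_CM)[0]

        sel = (r >= 6.0) & (r <= 30.0)  # 2-10 vessel radii
        orc = np.array([oracle_drop(rv) for rv in r[sel]])
        sim = sl[sel]
        sim0, orc0 = sim - sim.mean(), orc - orc.mean()
        span = orc0.max() - orc0.min()
        rms = np.sqrt(((sim0 - orc0) ** 2).mean()) / span
        assert rms < 0.02
        assert np.abs(sim0 - orc0).max() / span < 0.05

    def test_grid_refinement_consistency(self):
        """Halving the voxel edge changes the hypoxic fraction of a
        single-cube column only moderately (documents discretisation
        sensitivity)."""
        from cortox.column import (BranchingSpec, generate_arteriole_tree,
                                   generate_capillary_cube, assemble_column)
        from cortox.flow import calibrate_perfusion

        cube = generate_capillary_cube(seed=21)
        tree = generate_arteriole_tree(
            depth=330.0, branching=BranchingSpec(
                n_supra_branches=(3, 3), first_branch_depth=(40.0, 60.0),
                trunk_cross_depth=(180.0, 260.0),
                side_total_length=(120.0, 200.0)), seed=21)
        col = assemble_column(tree, cube, n_stack=1)
        _, fl = calibrate_perfusion(col)
        fr = []
        for vox in (30.0, 15.0):
            ox = GreensSolver(col, OxyParams(voxel_um=vox)).solve(fl)
            fr.append(ox.hypoxic_fraction(10.0))
        coarse, fine = fr
        assert abs(fine - coarse) < 0.2 * max(fine, coarse, 1e-3)


class TestHypoxiaMask:
    def _grid(self, po2):
        po2 = np.asarray(po2, dtype=float)
        return TissueGrid(origin=np.zeros(3), spacing=np.full(3, 15.0),
                          shape=po2.shape, po2=po2)

    def test_zero_threshold_empty_mask(self):
        g = self._grid(np.full((3, 3, 3), 5.0))
        assert not hypoxia_mask(g, 0.0).any()

    def test_uniformly_low_grid_fully_masked(self):
        g = self._grid(np.full((3, 3, 3), 5.0))
        assert hypoxia_mask(g, 10.0).all()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        g = self._grid(rng.uniform(0, 60, (6, 6, 6)))
        m1 = hypoxia_mask(g, 8.0)
        m2 = hypoxia_mask(g, 20.0)
        assert np.all(m2[m1])

    def test_out_of_domain_voxels_never_hypoxic(self):
        po2 = np.zeros((4, 4, 4))
        g = self._grid(po2)
        g.in_domain = np.zeros((4, 4, 4), dtype=bool)
        g.in_domain[0, 0, 0] = True
        m = hypoxia_mask(g, 10.0)
        assert m.sum() == 1


class TestTissueGridIO:
    def test_tiff_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        g = TissueGrid(origin=np.zeros(3), spacing=np.full(3, 15.0),
                       shape=(5, 6, 7),
                       po2=rng.uniform(0, 90, (5, 6, 7)).astype(np.float32)
                       .astype(float))
        g.write(tmp_path / "po2.tif")
        back = TissueGrid.read(tmp_path / "po2.tif")
        assert back.shape == g.shape
        assert np.allclose(back.po2, g.po2, atol=1e-6)
        assert np.allclose(back.spacing, g.spacing)
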