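"""Spatial statistics: Gx, hypoxic intensity, classification, controls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cortox.spatial import (GxCurve, HypoxicIntensityCurve, PointSet,
                            aggregate_column, classify_intensity,
                            gx_from_distances, hypoxic_intensity,
                            monte_carlo_controls, nearest_point_distances,
                            pixel_gx, voxel_centers)

SPACING = (15.0, 15.0, 15.0)


def brute_force_gx(mask, points, spacing, grid, domain=None, baseline=None):
    sel = np.asarray(mask, dtype=bool).copy()
    if domain is not None:
        sel &= domain
    if baseline is not None:
        sel &= ~baseline
    cs = voxel_centers(sel.shape, spacing)[sel.ravel()]
    d = np.min(np.linalg.norm(cs[:, None, :] - points[None, :, :], axis=2),
               axis=1)
    return np.array([(d <= g).mean() for g in grid])


class TestPixelGx:
    def test_voxel_at_bead_jumps_to_one_at_zero(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        centre = voxel_centers(mask.shape, SPACING)[
            np.ravel_multi_index((1, 1, 1), mask.shape)]
        gx = pixel_gx(mask, PointSet(centre.reshape(1, 3)), spacing=SPACING)
        assert gx.fraction[0] == 1.0

    def test_two_voxel_cdf(self):
        """Voxels at 100 and 300 um from the only bead give the two-step
        empirical CDF."""
        mask = np.zeros((40, 1, 1), dtype=bool)
        mask[0, 0, 0] = True   # centre at 7.5
        mask[20, 0, 0] = True  # centre at 307.5
        bead = np.array([[107.5, 7.5, 7.5]])  # 100 and 200 um away
        gx = pixel_gx(mask, PointSet(bead), spacing=SPACING)
        d = gx.distance_um
        assert np.all(gx.fraction[d < 100] == 0.0)
        assert np.all(gx.fraction[(d >= 100) & (d < 200)] == 0.5)
        assert np.all(gx.fraction[d >= 200] == 1.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((10, 10, 10)) < 0.12
        domain = rng.random((10, 10, 10)) < 0.9
        baseline = rng.random((10, 10, 10)) < 0.05
        pts = rng.uniform(0, 150, (5, 3))
        gx = pixel_gx(mask, PointSet(pts), domain=domain, baseline=baseline,
                      spacing=SPACING)
        expected = brute_force_gx(mask, pts, SPACING, gx.distance_um,
                                  domain, baseline)
        assert np.array_equal(gx.fraction, expected)

    def test_anisotropic_spacing_respected(self):
        mask = np.zeros((1, 1, 3), dtype=bool)
        mask[0, 0, 2] = True  # z centre at 125 for 50 um slabs
        half = 15.165 / 2
        gx = pixel_gx(mask, PointSet(np.array([[half, half, 25.0]])),
                      spacing=(15.165, 15.165, 50.0))
        assert gx.crossing(0.99) == pytest.approx(100.0)

    def test_no_points_rejected(self):
        with pytest.raises(ValueError):
            pixel_gx(np.ones((2, 2, 2), dtype=bool), PointSet(np.empty((0, 3))))

    def test_empty_hypoxia_flagged(self):
        gx = pixel_gx(np.zeros((2, 2, 2), dtype=bool),
                      PointSet(np.array([[10.0, 10, 10]])), spacing=SPACING)
        assert gx.empty
        assert np.all(gx.fraction == 0)

    @given(st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_curve_monotone_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 900, size=rng.integers(1, 200))
        gx = gx_from_distances(d)
        assert np.all(np.diff(gx.fraction) >= 0)
        assert gx.fraction[-1] == 1.0


class TestHypoxicIntensity:
    def test_fully_hypoxic_domain_is_one_everywhere(self):
        mask = np.ones((20, 20, 20), dtype=bool)
        c = hypoxic_intensity(mask, (150, 150, 150), spacing=SPACING)
        assert np.all(c.fraction == 1.0)

    def test_no_hypoxia_is_zero_everywhere(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        c = hypoxic_intensity(mask, (150, 150, 150), spacing=SPACING)
        assert np.all(c.fraction == 0.0)

    def test_matches_exhaustive_counting_oracle(self):
        rng = np.random.default_rng(7)
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:5, 3:6, 4:7] = True  # one blob
        domain = rng.random((10, 10, 10)) < 0.85
        centre = np.array([60.0, 70.0, 80.0])
        c = hypoxic_intensity(mask, centre, domain=domain, spacing=SPACING)
        cs = voxel_centers(mask.shape, SPACING)
        d = np.linalg.norm(cs - centre, axis=1)
        for r, f in zip(c.radius_um, c.fraction):
            inside = d <= r
            denom = np.count_nonzero(inside & domain.ravel())
            numer = np.count_nonzero(inside & (mask & domain).ravel())
            assert f == (numer / denom if denom else pytest.approx(np.nan, nan_ok=True))

    def test_empty_sphere_reports_nan_not_zero(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        domain = np.zeros((3, 3, 3), dtype=bool)
        domain[2, 2, 2] = True
        c = hypoxic_intensity(mask, (0.0, 0.0, 0.0), domain=domain,
                              spacing=SPACING, radii=(50.0, 100.0))
        assert np.isnan(c.fraction[0])

    def test_fractions_within_unit_interval(self):
        rng = np.random.default_rng(11)
        mask = rng.random((12, 12, 12)) < 0.3
        c = hypoxic_intensity(mask, (90, 90, 90), spacing=SPACING)
        ok = ~np.isnan(c.fraction)
        assert np.all((c.fraction[ok] >= 0) & (c.fraction[ok] <= 1))


def curve(f50, f100, rest=0.3):
    radii = np.arange(50.0, 501.0, 50.0)
    frac = np.full(10, rest)
    frac[0], frac[1] = f50, f100
    return HypoxicIntensityCurve(radii, frac)


class TestClassification:
    @pytest.mark.parametrize("f50,f100,expected", [
        (0.8, 0.4, ("A", "local")),       # falling slope, hypoxia nearby
        (0.0, 0.15, ("B", "local")),      # rising slope
        (1.0, 1.0, ("A", "local")),       # full hypoxia within 100 um
        (0.0, 0.0, ("B", "no-local")),    # no hypoxia within 100 um
        (0.4, 0.4, ("B", "local")),       # tie with partial hypoxia -> B
    ])
    def test_slope_rule(self, f50, f100, expected):
        assert classify_intensity(curve(f50, f100)) == expected

    def test_zero_inside_nonzero_beyond_is_distal(self):
        c = curve(0.0, 0.0, rest=0.2)
        assert classify_intensity(c) == ("B", "no-local")

    def test_missing_required_radius_rejected(self):
        c = HypoxicIntensityCurve(np.array([200.0, 300.0]), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            classify_intensity(c)


class TestAggregate:
    def test_single_scenario_is_identity(self):
        c = curve(0.2, 0.5)
        agg = aggregate_column([[100.0, 200.0]], [c])
        assert np.allclose(agg.intensity.fraction, c.fraction)
        assert agg.type_counts["B"] == 1

    def test_mean_of_two_intensities(self):
        agg = aggregate_column(
            [[100.0], [300.0]], [curve(0.2, 0.2, 0.2), curve(0.4, 0.4, 0.4)])
        assert np.allclose(agg.intensity.fraction[2:], 0.3)

    def test_gx_pools_distances_before_cdf(self):
        agg = aggregate_column([[100.0] * 3, [500.0]], [curve(0.1, 0.2)])
        # 3 of 4 pooled distances lie at 100 um
        assert agg.gx.fraction[agg.gx.distance_um == 100.0][0] == 0.75


class TestMonteCarloControls:
    def test_count_follows_density_times_volume(self):
        dom = np.ones((10, 10, 10), dtype=bool)  # 3.375e-3 mm^3 at 15 um
        vol = 1000 * 15.0**3 * 1e-9
        reps = monte_carlo_controls(dom, 25.0 / vol, 3, seed=0, spacing=SPACING)
        assert all(r.n == 25 for r in reps)

    def test_points_respect_domain_mask(self):
        dom = np.zeros((8, 8, 8), dtype=bool)
        dom[:, :4, :] = True
        reps = monte_carlo_controls(dom, 5e4, 2, seed=1, spacing=SPACING)
        for r in reps:
            assert np.all(r.xyz[:, 1] < 60.0)

    def test_large_radius_intensity_approaches_global_fraction(self):
        """Law of large numbers: the control-point intensity at large radius
        estimates the domain's overall hypoxic volume fraction."""
        rng = np.random.default_rng(5)
        mask = rng.random((20, 20, 20)) < 0.25
        dom = np.ones_like(mask)
        reps = monte_carlo_controls(dom, 3e3, 40, seed=2, spacing=SPACING)
        vals = []
        for r in reps:
            for c in r.xyz:
                ci = hypoxic_intensity(mask, c, spacing=SPACING,
                                       radii=(250.0,))
                vals.append(ci.fraction[0])
        assert np.nanmean(vals) == pytest.approx(mask.mean(), abs=0.02)

    def test_reproducible_per_seed(self):
        dom = np.ones((6, 6, 6), dtype=bool)
        a = monte_carlo_controls(dom, 1e5, 2, seed=9, spacing=SPACING)
        b = monte_carlo_controls(dom, 1e5, 2, seed=9, spacing=SPACING)
        assert np.array_equal(a[0].xyz, b[0].xyz)
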