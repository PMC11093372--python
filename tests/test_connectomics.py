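"""Connectomic statistics: densities, histograms, profiles, regressions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcnet import connectomics, synthgen
from lcnet.connectomics import (
    can_dn,
    cell_length_fractions,
    cell_tree_fractions,
    convergence_scan,
    cortical_profile,
    density_connectivity_regression,
    density_to_km_per_cm3,
    doc_histogram,
    length_histogram,
    subvolume_map,
)
from lcnet.synthgen import SurfaceSpec, SyntheticSpec, generate_calcein_surfaces
from lcnet.types import LCNetwork


def star_network(centre, dirs, length, kind="junction"):
    net = LCNetwork()
    net.add_node(0, centre, kind)
    centre = np.asarray(centre, dtype=float)
    for i, d in enumerate(np.asarray(dirs, dtype=float)):
        tip = centre + length * d / np.linalg.norm(d)
        net.add_node(i + 1, tip, "endpoint")
        net.add_edge(0, i + 1, np.vstack([centre, tip]))
    return net


def edges_network(lengths, spacing=10.0):
    """Disjoint straight edges of prescribed lengths (along axis 0)."""
    net = LCNetwork()
    nid = 0
    for i, L in enumerate(lengths):
        a = np.array([1.0, (i + 0.5) * spacing, 1.0])
        b = a + np.array([L, 0.0, 0.0])
        net.add_node(nid, a, "endpoint")
        net.add_node(nid + 1, b, "endpoint")
        net.add_edge(nid, nid + 1, np.vstack([a, b]))
        nid += 2
    return net


@pytest.fixture(scope="module")
def homogeneous_network():
    spec = SyntheticSpec(target_density=0.15, seed=8, domain_size=(40, 40, 20))
    net, gt = synthgen.generate_network(spec)
    return spec, net, gt


class TestDensities:
    def test_can_dn_is_length_over_volume(self):
        net = edges_network([25.0])
        assert can_dn(net, 125.0) == pytest.approx(0.2)

    def test_empty_network_zero(self):
        assert can_dn(LCNetwork(), 100.0) == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            can_dn(edges_network([1.0]), 0.0)

    def test_scale_invariance(self):
        """Scaling all coordinates by s scales Can.Dn by 1/s^2."""
        net = edges_network([4.0, 7.0, 2.5])
        scaled = synthgen.shift_network(net, (0, 0, 0))
        s = 3.0
        for *_k, geom in scaled.edges():
            geom.polyline *= s
            geom.arc_length *= s
        v = 1000.0
        assert can_dn(scaled, v * s ** 3) == pytest.approx(
            can_dn(net, v) / s ** 2)

    @pytest.mark.parametrize("d,expected", [(0.202, 202.0), (0.0, 0.0),
                                            (1.0, 1000.0)])
    def test_km_per_cm3(self, d, expected):
        assert density_to_km_per_cm3(d) == pytest.approx(expected, abs=1e-9)

    def test_km_per_cm3_negative_rejected(self):
        with pytest.raises(ValueError):
            density_to_km_per_cm3(-0.1)


class TestSubvolumeMap:
    def test_single_edge_single_cell(self):
        # a straight 5 um edge spanning one cell, [5, 10) along z
        net = LCNetwork()
        a = np.array([7.5, 7.5, 5.0])
        b = np.array([7.5, 7.5, 10.0 - 1e-9])
        net.add_node(0, a, "endpoint")
        net.add_node(1, b, "endpoint")
        net.add_edge(0, 1, np.vstack([a, b]))
        grid = subvolume_map(net, domain_size=(15, 15, 15), edge_length=5.0)
        d = grid.can_dn.reshape(grid.shape)
        assert d[1, 1, 1] == pytest.approx(5.0 / 125.0, rel=1e-3)
        other = d.copy()
        other[1, 1, 1] = 0.0
        assert np.nansum(other) == pytest.approx(0.0, abs=1e-12)

    def test_cell_count_50_50_30(self):
        grid = subvolume_map(LCNetwork(), domain_size=(50, 50, 30),
                             edge_length=5.0)
        assert grid.shape == (10, 10, 6)
        assert grid.n_cells == 600

    def test_conservation(self, homogeneous_network):
        spec, net, gt = homogeneous_network
        grid = subvolume_map(net, domain_size=spec.domain_size, edge_length=5.0)
        assert grid.total_length() == pytest.approx(gt.total_length, rel=1e-3)

    def test_full_extent_single_cell_matches_global(self, homogeneous_network):
        spec, net, gt = homogeneous_network
        L = max(spec.domain_size)
        grid = subvolume_map(net, domain_size=spec.domain_size, edge_length=L)
        assert grid.n_cells == 1
        v = float(np.prod(spec.domain_size))
        assert grid.can_dn.ravel()[0] == pytest.approx(
            can_dn(net, v, domain_size=spec.domain_size), rel=1e-3)

    def test_oracle_brute_force_integration(self):
        """Fine-step map agrees with an independent per-edge integrator."""
        rng = np.random.default_rng(5)
        net = LCNetwork()
        for i in range(12):
            pts = np.cumsum(rng.uniform(-1.5, 1.5, size=(8, 3)), axis=0) + 10.0
            pts = np.clip(pts, 0.5, 19.5)
            net.add_node(2 * i, pts[0], "endpoint")
            net.add_node(2 * i + 1, pts[-1], "endpoint")
            net.add_edge(2 * i, 2 * i + 1, pts)
        grid = subvolume_map(net, domain_size=(20, 20, 20), edge_length=5.0,
                             step=0.002)
        # oracle: dense sampling with an explicit python accumulation
        acc = {}
        for *_k, geom in net.edges():
            poly = geom.polyline
            seg = np.diff(poly, axis=0)
            for a, s in zip(poly[:-1], seg):
                n = max(int(np.ceil(np.linalg.norm(s) / 0.005)), 1)
                for t in (np.arange(n) + 0.5) / n:
                    p = a + t * s
                    cell = tuple(np.minimum((p // 5.0).astype(int), 3))
                    acc[cell] = acc.get(cell, 0.0) + np.linalg.norm(s) / n
        lengths = grid.lengths.reshape(grid.shape)
        for cell, val in acc.items():
            assert lengths[cell] == pytest.approx(val, rel=1e-3, abs=5e-3)

    def test_convergence_scan_stable_4_to_6(self):
        """A stationary segment process gives a stable median Can.Dn for
        sub-volume edges of 4-6 um, and the same clipped total at every L."""
        rng = np.random.default_rng(12)
        domain = (40.0, 40.0, 20.0)
        net = LCNetwork()
        nid = 0
        for _ in range(900):  # centres in an enlarged box, clipped by binning
            centre = rng.uniform(-3, np.asarray(domain) + 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            a, b = centre - 1.5 * d, centre + 1.5 * d
            net.add_node(nid, a, "endpoint")
            net.add_node(nid + 1, b, "endpoint")
            net.add_edge(nid, nid + 1, np.vstack([a, b]))
            nid += 2
        scan = convergence_scan(net, domain_size=domain, edge_lengths=(4, 5, 6))
        med = scan["median"].to_numpy()
        assert np.max(med) / np.min(med) < 1.10
        totals = scan["total_length"].to_numpy()
        assert np.allclose(totals, totals[0], rtol=1e-9)


class TestLengthHistogram:
    def test_worked_example(self):
        net = edges_network([0.5, 1.5, 6.0])
        dist = length_histogram(net)
        pct = dist.histogram.percent
        assert pct[0] == pytest.approx(100 / 3)
        assert pct[1] == pytest.approx(100 / 3)
        assert pct[6] == pytest.approx(100 / 3)
        assert dist.long_fraction_count == pytest.approx(1 / 3)
        assert dist.long_fraction_length == pytest.approx(6.0 / 8.0)

    def test_percentages_sum_to_100(self, homogeneous_network):
        _spec, net, _gt = homogeneous_network
        dist = length_histogram(net)
        assert dist.histogram.percent.sum() == pytest.approx(100.0, abs=1e-6)

    def test_centre_of_mass_assignment_is_whole_edge(self):
        # edge straddles two cells; centre of mass in the first
        net = LCNetwork()
        a, b = np.array([1.0, 2.5, 2.5]), np.array([7.0, 2.5, 2.5])
        net.add_node(0, a, "endpoint")
        net.add_node(1, b, "endpoint")
        net.add_edge(0, 1, np.vstack([a, b]))  # com at x=4 -> cell 0
        grid = subvolume_map(net, domain_size=(10, 5, 5), edge_length=5.0)
        frac = cell_length_fractions(net, grid)
        assert frac["n_edges"].sum() == 1
        assert frac["n_edges"].to_numpy().reshape(grid.shape)[0, 0, 0] == 1
        d0 = length_histogram(net, scope=("cell", grid, (0, 0, 0)))
        assert d0.histogram.n == 1
        assert d0.histogram.counts[6] == 1  # full 6 um length counted there
        d1 = length_histogram(net, scope=("cell", grid, (1, 0, 0)))
        assert d1.histogram.empty

    @settings(deadline=None, max_examples=25)
    @given(lengths=st.lists(st.floats(0.1, 20.0), min_size=1, max_size=30))
    def test_histogram_properties(self, lengths):
        dist = length_histogram(edges_network(lengths, spacing=2.0))
        assert dist.histogram.percent.sum() == pytest.approx(100.0, abs=1e-6)
        assert 0.0 <= dist.long_fraction_count <= 1.0
        assert 0.0 <= dist.long_fraction_length <= 1.0
        assert dist.histogram.counts.sum() == len(lengths)


class TestDocHistogram:
    def test_y_junction(self):
        net = star_network((5, 5, 5), [(1, 0, 0), (-0.5, 1, 0), (-0.5, -1, 0)], 3.0)
        dist = doc_histogram(net)
        assert dist.histogram.percent[0] == pytest.approx(100.0)
        assert dist.tree_like_fraction == pytest.approx(1.0)

    def test_x_junction(self):
        net = star_network((5, 5, 5), [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0)], 3.0)
        dist = doc_histogram(net)
        assert dist.histogram.percent[-1] == pytest.approx(100.0)
        assert dist.tree_like_fraction == 0.0

    def test_chain_without_junctions_flagged_empty(self):
        net = edges_network([5.0])
        dist = doc_histogram(net)
        assert dist.histogram.empty
        assert np.isnan(dist.tree_like_fraction)


class TestProfileAndRegression:
    def _mask(self, domain, vs=0.5):
        calcein, mask = generate_calcein_surfaces(
            domain, (SurfaceSpec(domain[1] * 0.2), SurfaceSpec(domain[1] * 0.8)),
            voxel_size=(vs, vs, vs))
        return mask

    def test_homogeneous_profile_is_flat(self, homogeneous_network):
        spec, net, _gt = homogeneous_network
        mask = self._mask(spec.domain_size)
        grid = subvolume_map(net, mask=mask, edge_length=5.0)
        profile = cortical_profile(grid, mask)
        inner = slice(2, -2)  # boundary columns carry partial cells
        dev = np.abs(profile.mean[inner] - np.nanmean(profile.mean[inner]))
        assert np.all(dev <= 2.0 * np.maximum(profile.sd[inner], 1e-9))

    def test_profile_positions_span_unit_interval(self, homogeneous_network):
        spec, net, _gt = homogeneous_network
        mask = self._mask(spec.domain_size)
        grid = subvolume_map(net, mask=mask, edge_length=5.0)
        profile = cortical_profile(grid, mask)
        assert profile.positions[0] == 0.0
        assert profile.positions[-1] == 1.0
        assert 0.0 < profile.boundaries[0] < profile.boundaries[1] < 1.0

    def test_gradient_profile_slope_sign(self):
        spec = SyntheticSpec(target_density=0.15, seed=2,
                             density_gradient=(0.0, 0.03, 0.0))
        net, _gt = synthgen.generate_network(spec)
        mask = self._mask(spec.domain_size)
        grid = subvolume_map(net, mask=mask, edge_length=5.0)
        profile = cortical_profile(grid, mask)
        slope = np.polyfit(profile.positions, profile.mean, 1)[0]
        assert slope > 0  # endosteal (low x) to periosteal (high x) increase

    def test_collinear_regression_exact(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.05, 0.4, size=30)
        from lcnet.types import SubvolumeGrid
        import pandas as pd
        grid = SubvolumeGrid(origin=np.zeros(3), edge_length=5.0,
                             shape=(30, 1, 1), lengths=x * 125.0,
                             v_roi=np.full(30, 125.0),
                             region=np.ones(30, dtype=np.uint8))
        y = -0.5 * grid.can_dn.ravel() + 80.0
        long_fr = pd.DataFrame({"n_edges": np.ones(30, int),
                                "pct_long_count": y, "pct_long_length": y})
        tree_fr = pd.DataFrame({"n_junctions": np.ones(30, int), "pct_tree": y})
        fit_long, fit_tree = density_connectivity_regression(grid, long_fr, tree_fr)
        for fit in (fit_long, fit_tree):
            assert fit.slope == pytest.approx(-0.5, abs=1e-9)
            assert fit.intercept == pytest.approx(80.0, abs=1e-9)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
            assert fit.n == 30

    def test_too_few_cells_rejected(self):
        import pandas as pd
        from lcnet.types import SubvolumeGrid
        grid = SubvolumeGrid(origin=np.zeros(3), edge_length=5.0,
                             shape=(2, 1, 1), lengths=np.array([1.0, 2.0]),
                             v_roi=np.array([125.0, 125.0]),
                             region=np.ones(2, dtype=np.uint8))
        fr = pd.DataFrame({"n_edges": [1, 1], "pct_long_count": [1, 2],
                           "pct_long_length": [1, 2]})
        tr = pd.DataFrame({"n_junctions": [1, 1], "pct_tree": [1, 2]})
        with pytest.raises(ValueError, match="at least 3"):
            density_connectivity_regression(grid, fr, tr)

    def test_two_region_mechanism_negative_slope(self):
        """Dense short-canaliculi region + sparse long one: %long falls with
        density, the mechanism behind network densification."""
        sparse = SyntheticSpec(target_density=0.07, seed=3,
                               domain_size=(25, 40, 20),
                               segment_length_mean=10.0, segment_length_sd=4.0,
                               branch_rate=0.8)
        dense = SyntheticSpec(target_density=0.16, seed=4,
                              domain_size=(25, 40, 20),
                              segment_length_mean=3.0, segment_length_sd=1.5,
                              branch_rate=2.0)
        net_a, _ = synthgen.generate_network(sparse)
        net_b, _ = synthgen.generate_network(dense)
        merged = synthgen.merge_networks(
            net_a, synthgen.shift_network(net_b, (25.0, 0.0, 0.0)))
        grid = subvolume_map(merged, domain_size=(50, 40, 20), edge_length=5.0)
        long_fr = cell_length_fractions(merged, grid)
        tree_fr = cell_tree_fractions(merged, grid)
        fit_long, _fit_tree = density_connectivity_regression(
            grid, long_fr, tree_fr, weighting="length")
        assert fit_long.slope < 0
        assert 0.0 <= fit_long.r_squared <= 1.0
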