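import numpy as np
import pytest

from landconnect.circuit import (
    build_circuit,
    cell_current_density,
    effective_resistance,
    effective_resistance_matrix,
    neighborhood_analysis,
    net_currents,
    omnidirectional_map,
    solve_pair,
)
from landconnect.raster import Raster
from conftest import random_cost_raster
from oracles import dense_effective_resistance, dense_voltages


class TestBuildCircuit:
    def test_single_edge_resistance_is_mean_of_costs(self):
        c = build_circuit(Raster(np.array([[10.0, 10.0]]), cell_size=100.0))
        assert c.n_edges == 1
        assert 1.0 / c.conductance[0] == pytest.approx(10.0)
        c2 = build_circuit(Raster(np.array([[10.0, 1000.0]]), cell_size=100.0))
        assert 1.0 / c2.conductance[0] == pytest.approx(505.0)

    def test_3x3_four_connectivity_edge_count(self):
        c = build_circuit(Raster(np.full((3, 3), 10.0), cell_size=100.0))
        assert c.n_edges == 12

    def test_eight_connectivity_scales_diagonals(self):
        c = build_circuit(Raster(np.full((2, 2), 10.0), cell_size=100.0),
                          connectivity="eight")
        assert c.n_edges == 6
        resistances = np.sort(1.0 / c.conductance)
        np.testing.assert_allclose(resistances[-2:], 10.0 * np.sqrt(2.0))

    def test_nonpositive_cost_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            build_circuit(Raster(np.array([[10.0, -1.0]]), cell_size=100.0))

    def test_all_nodata_rejected(self):
        with pytest.raises(ValueError, match="NoData"):
            build_circuit(Raster(np.full((3, 3), np.nan), cell_size=100.0))

    def test_size_guard(self):
        with pytest.raises(ValueError, match="guard"):
            build_circuit(Raster(np.full((10, 10), 10.0), cell_size=100.0), max_cells=50)


class TestSolvePair:
    def test_series_chain_voltages_exact(self):
        c = build_circuit(Raster(np.full((1, 3), 10.0), cell_size=100.0))
        v = solve_pair(c, (0, 0), (0, 2))
        np.testing.assert_allclose(v, [20.0, 10.0, 0.0], atol=1e-12)

    def test_swapping_terminals_reflects_voltages(self):
        r = random_cost_raster(3)
        c = build_circuit(r)
        v1 = solve_pair(c, 0, c.n_nodes - 1)
        v2 = solve_pair(c, c.n_nodes - 1, 0)
        np.testing.assert_allclose(v1, v1.max() - v2, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_voltages_match_dense_grounded_oracle(self, seed):
        r = random_cost_raster(seed)
        c = build_circuit(r)
        s, g = 4, c.n_nodes - 2
        v = solve_pair(c, s, g)
        oracle = dense_voltages(c.laplacian.toarray(), s, g)
        np.testing.assert_allclose(v, oracle, rtol=1e-8, atol=1e-10)

    def test_cross_component_terminals_rejected(self):
        data = np.full((3, 3), 10.0)
        data[:, 1] = np.nan  # vertical NoData wall
        with pytest.warns(UserWarning, match="components"):
            c = build_circuit(Raster(data, cell_size=100.0))
        with pytest.raises(ValueError, match="components"):
            solve_pair(c, (0, 0), (0, 2))


class TestEffectiveResistance:
    def test_single_edge(self):
        c = build_circuit(Raster(np.array([[10.0, 10.0]]), cell_size=100.0))
        assert effective_resistance(c, 0, 1) == pytest.approx(10.0)

    def test_two_edges_in_series(self):
        c = build_circuit(Raster(np.full((1, 3), 10.0), cell_size=100.0))
        assert effective_resistance(c, 0, 2) == pytest.approx(20.0)

    def test_parallel_paths_on_ring(self):
        # 2x2 block: adjacent corners joined directly (10) and around (30)
        c = build_circuit(Raster(np.full((2, 2), 10.0), cell_size=100.0))
        assert effective_resistance(c, (0, 0), (0, 1)) == pytest.approx(7.5)

    @pytest.mark.parametrize("seed,holes", [(0, 0), (1, 0), (2, 2), (3, 3), (4, 0)])
    def test_matches_dense_pseudoinverse_oracle(self, seed, holes):
        r = random_cost_raster(seed, shape=(7, 7), nodata_holes=holes)
        c = build_circuit(r)
        L = c.laplacian.toarray()
        s, g = 2, c.n_nodes - 3
        assert effective_resistance(c, s, g) == pytest.approx(
            dense_effective_resistance(L, s, g), rel=1e-6
        )

    def test_symmetric_in_terminal_exchange(self):
        c = build_circuit(random_cost_raster(5))
        assert effective_resistance(c, 3, 20) == pytest.approx(
            effective_resistance(c, 20, 3)
        )

    def test_triangle_inequality(self):
        c = build_circuit(random_cost_raster(6))
        a, b, d = 0, 17, 33
        M = effective_resistance_matrix(c, [a, b, d])
        assert M[0, 2] <= M[0, 1] + M[1, 2] + 1e-10

    def test_matrix_agrees_with_pairwise_solves(self):
        c = build_circuit(random_cost_raster(7))
        nodes = [1, 9, 22, 35]
        M = effective_resistance_matrix(c, nodes)
        for i in range(4):
            for j in range(i + 1, 4):
                assert M[i, j] == pytest.approx(
                    effective_resistance(c, nodes[i], nodes[j]), rel=1e-9
                )

    def test_rayleigh_monotonicity(self):
        """Lowering any single cell cost never increases effective
        resistance between fixed terminals."""
        r = random_cost_raster(8)
        c = build_circuit(r)
        base = effective_resistance(c, 0, c.n_nodes - 1)
        rng = np.random.default_rng(0)
        for _ in range(5):
            r2 = r.copy()
            cell = rng.integers(0, 6, 2)
            r2.data[cell[0], cell[1]] *= rng.uniform(0.1, 0.9)
            c2 = build_circuit(r2)
            assert effective_resistance(c2, 0, c2.n_nodes - 1) <= base + 1e-9


class TestCurrentDensity:
    def test_chain_pass_through_and_terminals(self):
        c = build_circuit(Raster(np.full((1, 3), 10.0), cell_size=100.0))
        v = solve_pair(c, (0, 0), (0, 2))
        d = cell_current_density(c, v)
        np.testing.assert_allclose(d, [[0.5, 1.0, 0.5]], atol=1e-12)

    def test_kirchhoff_conservation_at_every_node(self):
        c = build_circuit(random_cost_raster(9))
        s, g = 2, c.n_nodes - 1
        v = solve_pair(c, s, g)
        net = net_currents(c, v)
        expected = np.zeros(c.n_nodes)
        expected[s], expected[g] = 1.0, -1.0
        np.testing.assert_allclose(net, expected, atol=1e-8)

    def test_cut_current_equals_injected(self):
        """Signed current across a column cut separating the terminals
        sums to the injected current."""
        r = random_cost_raster(10, shape=(5, 5))
        c = build_circuit(r)
        v = solve_pair(c, (2, 0), (2, 4))
        cut = 0.0
        for row in range(5):
            u = c.node_at((row, 1))
            w = c.node_at((row, 2))
            mask = ((c.edge_u == u) & (c.edge_v == w)) | ((c.edge_u == w) & (c.edge_v == u))
            (e,) = np.flatnonzero(mask)
            sign = 1.0 if c.edge_u[e] == u else -1.0
            cut += sign * c.conductance[e] * (v[c.edge_u[e]] - v[c.edge_v[e]])
        assert cut == pytest.approx(1.0, abs=1e-8)


class TestOmnidirectionalMap:
    def test_study_area_mean_is_zero(self):
        r = random_cost_raster(11, shape=(12, 12))
        m = omnidirectional_map(r, n_pairs=8, buffer_cells=3, seed=0)
        assert np.nanmean(m.current.data) == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_for_fixed_seed(self):
        r = random_cost_raster(12, shape=(10, 10))
        m1 = omnidirectional_map(r, n_pairs=6, buffer_cells=3, seed=5)
        m2 = omnidirectional_map(r, n_pairs=6, buffer_cells=3, seed=5)
        np.testing.assert_array_equal(m1.current.data, m2.current.data)
        assert m1.pair_cells == m2.pair_cells

    def test_pairs_respect_angular_separation(self):
        r = random_cost_raster(13, shape=(10, 10))
        m = omnidirectional_map(r, n_pairs=8, buffer_cells=4, seed=2)
        rows, cols = 10 + 8, 10 + 8
        cy, cx = (rows - 1) / 2, (cols - 1) / 2
        for (r0, c0), (r1, c1) in m.pair_cells:
            a0 = np.arctan2(r0 - cy, c0 - cx)
            a1 = np.arctan2(r1 - cy, c1 - cx)
            sep = abs(np.angle(np.exp(1j * (a0 - a1))))
            assert sep >= np.pi / 2 - 1e-12

    def test_perimeter_too_small_rejected(self):
        r = random_cost_raster(14, shape=(4, 4))
        with pytest.raises(ValueError, match="perimeter"):
            omnidirectional_map(r, n_pairs=500, buffer_cells=1, seed=0)

    def test_pinch_point_corridor_concentrates_current(self):
        """A single low-cost corridor between two resistant blocks rises
        above the 95th percentile of the map."""
        data = np.full((21, 21), 1000.0)
        data[10, :] = 10.0  # one-cell corridor through the middle
        m = omnidirectional_map(Raster(data, cell_size=100.0),
                                n_pairs=32, buffer_cells=5, seed=1)
        vals = m.current.data[np.isfinite(m.current.data)]
        assert m.current.data[10, 10] > np.percentile(vals, 95)


class TestNeighborhoodAnalysis:
    def test_five_next_nearest_pairs_on_uniform_circle(self):
        r = Raster(np.full((41, 41), 10.0), cell_size=100.0)
        site = r.cell_center(20, 20)
        res = neighborhood_analysis(r, site, radius_m=1800.0, inset_m=300.0, seed=0)
        assert len(res.pair_resistances) == 5
        assert len(res.focal_cells) == 5
        # rotational symmetry up to lattice discretization: focal nodes snap
        # to cell centers, which perturbs chord lengths by ~1 cell / radius
        pr = np.asarray(res.pair_resistances)
        assert pr.max() / pr.min() - 1.0 < 0.03
        assert res.mean_current_density > 0
        assert not res.clipped

    def test_focal_nodes_nudged_off_nodata(self):
        data = np.full((41, 41), 10.0)
        data[5:12, 18:24] = np.nan  # hole near the focal ring
        r = Raster(data, cell_size=100.0)
        res = neighborhood_analysis(r, r.cell_center(20, 20), 1800.0, 300.0, seed=3)
        for row, col in res.focal_cells:
            assert np.isfinite(data[row, col])

    def test_clipped_circle_warns(self):
        r = Raster(np.full((21, 21), 10.0), cell_size=100.0)
        with pytest.warns(UserWarning, match="clipped"):
            neighborhood_analysis(r, r.cell_center(3, 3), 900.0, 300.0, seed=0)

    def test_radius_must_exceed_inset(self):
        r = Raster(np.full((21, 21), 10.0), cell_size=100.0)
        with pytest.raises(ValueError, match="inset"):
            neighborhood_analysis(r, r.cell_center(10, 10), 200.0, 300.0)
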