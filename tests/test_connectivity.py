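import networkx as nx
import numpy as np
import pytest

from landgen import connectivity
from landgen.genetics import HaplotypeSet, PopulationSet
from landgen.raster import GridSpec, SuitabilityMap


def friction_of(costs: np.ndarray, cellsize: float = 1.0) -> connectivity.FrictionSurface:
    grid = GridSpec(0.0, 0.0, cellsize, *costs.shape)
    return connectivity.FrictionSurface(grid, np.asarray(costs, dtype=float))


def networkx_oracle(costs: np.ndarray, cellsize: float = 1.0) -> nx.Graph:
    """Explicitly built 8-connected graph with the endpoint-mean edge
    convention — the independent shortest-path oracle."""
    g = nx.Graph()
    nrows, ncols = costs.shape
    for r in range(nrows):
        for c in range(ncols):
            if not np.isfinite(costs[r, c]):
                continue
            for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nrows and 0 <= c2 < ncols and np.isfinite(costs[r2, c2]):
                    scale = np.sqrt(2) if dr and dc else 1.0
                    w = 0.5 * (costs[r, c] + costs[r2, c2]) * cellsize * scale
                    g.add_edge((r, c), (r2, c2), weight=w)
    return g


class TestFriction:
    def test_inversion_endpoints(self):
        grid = GridSpec(0, 0, 1, 4, 4)
        ones = SuitabilityMap(grid, np.ones((4, 4)))
        zeros = SuitabilityMap(grid, np.zeros((4, 4)))
        eps = 0.001
        np.testing.assert_allclose(
            connectivity.friction_from_suitability(ones, eps).costs, eps
        )
        np.testing.assert_allclose(
            connectivity.friction_from_suitability(zeros, eps).costs, 1 + eps
        )

    def test_strictly_decreasing_in_suitability(self):
        grid = GridSpec(0, 0, 1, 1, 5)
        s = SuitabilityMap(grid, np.linspace(0, 1, 5)[None, :])
        costs = connectivity.friction_from_suitability(s).costs[0]
        assert np.all(np.diff(costs) < 0)

    def test_nonpositive_epsilon_rejected(self):
        grid = GridSpec(0, 0, 1, 2, 2)
        s = SuitabilityMap(grid, np.ones((2, 2)))
        with pytest.raises(ValueError):
            connectivity.friction_from_suitability(s, epsilon=0.0)


class TestCostDistance:
    def test_source_cell_zero(self):
        f = friction_of(np.ones((5, 5)))
        d = connectivity.cost_distance(f, (2, 2))
        assert d[2, 2] == 0.0

    def test_uniform_cost_neighbour_step(self):
        c = 3.0
        f = friction_of(np.full((5, 5), c), cellsize=2.0)
        d = connectivity.cost_distance(f, (2, 2))
        assert d[2, 3] == pytest.approx(c * 2.0)
        assert d[3, 3] == pytest.approx(c * 2.0 * np.sqrt(2))

    def test_matches_networkx_oracle_on_random_rasters(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            costs = rng.uniform(0.1, 5.0, (10, 10))
            f = friction_of(costs)
            d = connectivity.cost_distance(f, (0, 0))
            oracle = nx.single_source_dijkstra_path_length(
                networkx_oracle(costs), (0, 0)
            )
            for (r, c), val in oracle.items():
                assert d[r, c] == pytest.approx(val, abs=1e-9)

    def test_masked_source_raises(self):
        costs = np.ones((4, 4))
        costs[1, 1] = np.nan
        with pytest.raises(ValueError):
            connectivity.cost_distance(friction_of(costs), (1, 1))


class TestLeastCostPath:
    def test_identical_endpoints(self):
        f = friction_of(np.ones((4, 4)))
        path, cost = connectivity.least_cost_path(f, (1, 1), (1, 1))
        assert path == [(1, 1)] and cost == 0.0

    def test_uniform_friction_straight_row(self):
        c, cell = 2.0, 1.0
        f = friction_of(np.full((5, 8), c), cellsize=cell)
        path, cost = connectivity.least_cost_path(f, (2, 1), (2, 6))
        assert path == [(2, j) for j in range(1, 7)]
        assert cost == pytest.approx(c * cell * 5)

    def test_path_follows_low_cost_corridor(self):
        costs = np.ones((6, 6))
        costs[1:5, 2:4] = 100.0  # high-cost block in the middle
        f = friction_of(costs)
        path, cost = connectivity.least_cost_path(f, (3, 0), (3, 5))
        assert not any((r, c) in {(r2, c2) for r2 in range(1, 5)
                                  for c2 in range(2, 4)} for r, c in path)
        oracle = nx.dijkstra_path_length(networkx_oracle(costs), (3, 0), (3, 5))
        assert cost == pytest.approx(oracle, abs=1e-9)

    def test_cost_symmetric(self):
        rng = np.random.default_rng(1)
        costs = rng.uniform(0.5, 2.0, (8, 8))
        f = friction_of(costs)
        _, ab = connectivity.least_cost_path(f, (0, 0), (7, 7))
        _, ba = connectivity.least_cost_path(f, (7, 7), (0, 0))
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_disconnected_raises_naming_cells(self):
        costs = np.ones((3, 5))
        costs[:, 2] = np.nan  # wall splits the grid
        with pytest.raises(ValueError, match="not connected"):
            connectivity.least_cost_path(friction_of(costs), (1, 0), (1, 4))


class TestSharedHaplotypeLinks:
    def _haps(self, assignment: dict[str, list[str]]) -> HaplotypeSet:
        inds, pops, seqs = [], [], []
        base = "ACGT" * 5
        hap_seq = {f"H{i}": base[:i] + "T" + base[i + 1:] for i in range(1, 9)}
        for pop, haps in assignment.items():
            for i, h in enumerate(haps):
                inds.append(f"{pop}_{i}")
                pops.append(pop)
                seqs.append(hap_seq[h])
        return HaplotypeSet(inds, pops, seqs)

    def test_all_sharing_one_haplotype_complete_graph(self):
        haps = self._haps({"A": ["H1"], "B": ["H1"], "C": ["H1"]})
        assert connectivity.shared_haplotype_links(haps) == {
            ("A", "B"), ("A", "C"), ("B", "C")
        }

    def test_private_haplotypes_no_links(self):
        haps = self._haps({"A": ["H1"], "B": ["H2"], "C": ["H3"]})
        assert connectivity.shared_haplotype_links(haps) == set()

    def test_chain_of_shared_sets(self):
        haps = self._haps({"A": ["H1"], "B": ["H1", "H2"], "C": ["H2"]})
        assert connectivity.shared_haplotype_links(haps) == {("A", "B"), ("B", "C")}


class TestBuildNetwork:
    def _setup(self, n_pops: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        costs = rng.uniform(0.2, 2.0, (10, 12))
        f = friction_of(costs, cellsize=0.5)
        cells = rng.choice(10 * 12, size=n_pops, replace=False)
        lons, lats = zip(*(f.grid.center_of(i // 12, i % 12) for i in cells))
        pops = PopulationSet([f"P{i}" for i in range(n_pops)],
                             np.array(lons), np.array(lats))
        return pops, f

    def test_two_pops_single_lcp_edge(self):
        pops, f = self._setup(2)
        net = connectivity.build_network(pops, f)
        assert len(net.edges) == 1
        a = f.grid.cell_of(pops.lons[0], pops.lats[0])
        b = f.grid.cell_of(pops.lons[1], pops.lats[1])
        _, expected = connectivity.least_cost_path(f, a, b)
        assert net.edges[0].cost == pytest.approx(expected, abs=1e-9)

    def test_all_pairs_edge_count(self):
        pops, f = self._setup(6)
        net = connectivity.build_network(pops, f)
        assert len(net.edges) == 6 * 5 // 2

    def test_edge_costs_invariant_to_node_order(self):
        pops, f = self._setup(5, seed=3)
        rev = PopulationSet(pops.ids[::-1], pops.lons[::-1], pops.lats[::-1])
        net1 = connectivity.build_network(pops, f)
        net2 = connectivity.build_network(rev, f)
        c1 = {frozenset((e.pop_a, e.pop_b)): e.cost for e in net1.edges}
        c2 = {frozenset((e.pop_a, e.pop_b)): e.cost for e in net2.edges}
        assert set(c1) == set(c2)
        for k in c1:
            assert c1[k] == pytest.approx(c2[k], abs=1e-9)

    def test_shared_mode_subset_of_all_pairs(self, genetic_data, climate):
        current, _ = climate
        pops, _, haps, _ = genetic_data
        s = SuitabilityMap(current.grid,
                           1 / (1 + np.exp(-current.layers[current.names[0]])))
        f = connectivity.friction_from_suitability(s)
        links = connectivity.shared_haplotype_links(haps)
        net_all = connectivity.build_network(pops, f, links, "all-pairs")
        net_shared = connectivity.build_network(pops, f, links, "shared-haplotype")
        all_pairs = {frozenset((e.pop_a, e.pop_b)) for e in net_all.edges}
        shared_pairs = {frozenset((e.pop_a, e.pop_b)) for e in net_shared.edges}
        assert shared_pairs <= all_pairs
        assert len(shared_pairs) == len(links)


class TestResistanceMatrix:
    def test_uniform_friction_proportional_to_grid_distance(self):
        f = friction_of(np.full((9, 9), 2.0), cellsize=1.0)
        pops = PopulationSet(
            ["a", "b", "c"],
            np.array([0.5, 4.5, 8.5]),
            np.array([8.5, 8.5, 4.5]),
        )
        R = connectivity.resistance_matrix(pops, f)
        # 8-connected geometric distance: max(|dr|,|dc|)-min * sqrt2 form
        def chamfer(a, b):
            dr, dc = abs(a[0] - b[0]), abs(a[1] - b[1])
            return (max(dr, dc) - min(dr, dc)) + min(dr, dc) * np.sqrt(2)

        cells = [(0, 0), (0, 4), (4, 8)]
        for i in range(3):
            for j in range(3):
                assert R[i, j] == pytest.approx(2.0 * chamfer(cells[i], cells[j]),
                                                abs=1e-9)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(5)
        costs = rng.uniform(0.1, 3.0, (10, 10))
        f = friction_of(costs)
        cells = [(0, 0), (9, 9), (0, 9), (5, 4)]
        lons, lats = zip(*(f.grid.center_of(r, c) for r, c in cells))
        pops = PopulationSet(list("abcd"), np.array(lons), np.array(lats))
        R = connectivity.resistance_matrix(pops, f)
        n = len(R)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert R[i, j] <= R[i, k] + R[k, j] + 1e-9

    def test_scaling_linearity(self):
        rng = np.random.default_rng(6)
        costs = rng.uniform(0.5, 1.5, (8, 8))
        pops = PopulationSet(["a", "b"], np.array([0.5, 7.5]), np.array([0.5, 7.5]))
        R1 = connectivity.resistance_matrix(pops, friction_of(costs))
        R3 = connectivity.resistance_matrix(pops, friction_of(3 * costs))
        np.testing.assert_allclose(R3, 3 * R1, atol=1e-9)

    def test_monotone_in_cell_cost(self):
        rng = np.random.default_rng(7)
        costs = rng.uniform(0.5, 1.5, (8, 8))
        pops = PopulationSet(["a", "b"], np.array([0.5, 7.5]), np.array([0.5, 7.5]))
        R1 = connectivity.resistance_matrix(pops, friction_of(costs))
        bumped = costs.copy()
        bumped[4, 4] += 5.0
        R2 = connectivity.resistance_matrix(pops, friction_of(bumped))
        assert np.all(R2 >= R1 - 1e-12)
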