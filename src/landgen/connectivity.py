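"""Friction surfaces, cost distances, least-cost paths and networks.

Suitability is inverted into a dispersal-cost (friction) surface; cost
distances are single-source shortest paths on the 8-connected raster
graph with the gdistance/ArcGIS edge convention: edge weight = mean of
the two endpoint cell costs x centre-to-centre distance (diagonals
scaled by sqrt(2)). Shortest paths run on ``scipy.sparse.csgraph``.

Two population networks are built: all pairs ("population
connectivity") and pairs sharing at least one haplotype ("genetic
connectivity"), each edge carrying its least-cost path and cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .genetics import HaplotypeSet, PopulationSet
from .raster import GridSpec, SuitabilityMap

__all__ = [
    "FrictionSurface",
    "ConnectivityNetwork",
    "friction_from_suitability",
    "cost_distance",
    "least_cost_path",
    "shared_haplotype_links",
    "build_network",
    "resistance_matrix",
]


@dataclass
class FrictionSurface:
    """Per-cell dispersal cost; NaN marks impassable (nodata) cells."""

    grid: GridSpec
    costs: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.costs.shape != self.grid.shape:
            raise ValueError("cost grid shape mismatch")
        finite = self.costs[np.isfinite(self.costs)]
        if finite.size and finite.min() <= 0:
            raise ValueError("friction costs must be strictly positive")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.costs)


@dataclass
class NetworkEdge:
    pop_a: str
    pop_b: str
    cost: float
    path: list[tuple[int, int]]  # (row, col) cells, a -> b
    shared: bool


@dataclass
class ConnectivityNetwork:
    """Population nodes joined by least-cost-path edges."""

    pops: PopulationSet
    edges: list[NetworkEdge]
    mode: str  # "all-pairs" | "shared-haplotype"

    def edge_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"pop_a": e.pop_a, "pop_b": e.pop_b, "cost": e.cost,
                 "shared": e.shared}
                for e in self.edges
            ]
        )


def friction_from_suitability(suit: SuitabilityMap, epsilon: float = 0.001
                              ) -> FrictionSurface:
    """Invert continuous suitability into friction: cost = (1 - s) + eps.

    High suitability means low dispersal cost; the epsilon floor keeps
    perfectly suitable terrain from being free to cross.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    costs = np.where(suit.mask, (1.0 - suit.values) + epsilon, np.nan)
    return FrictionSurface(suit.grid, costs, source_label=suit.scenario)


def _raster_graph(friction: FrictionSurface):
    """Sparse 8-connected graph over unmasked cells.

    Returns (csr_matrix, node_index grid, (rows, cols) of nodes).
    Edge weight = 0.5*(cost_a + cost_b) * cellsize * (sqrt(2) if diagonal).
    """
    mask = friction.mask
    nrows, ncols = mask.shape
    node = -np.ones(mask.shape, dtype=int)
    rr, cc = np.nonzero(mask)
    node[rr, cc] = np.arange(len(rr))
    cell = friction.grid.cellsize
    data, i_idx, j_idx = [], [], []
    offsets = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]
    c = friction.costs
    for dr, dc, scale in offsets:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        ok = mask[r0, c0] & mask[r1, c1]
        w = 0.5 * (c[r0, c0] + c[r1, c1]) * cell * scale
        a = node[r0, c0][ok]
        b = node[r1, c1][ok]
        data.append(w[ok])
        i_idx.append(a)
        j_idx.append(b)
    data = np.concatenate(data) if data else np.array([])
    i_idx = np.concatenate(i_idx) if i_idx else np.array([], dtype=int)
    j_idx = np.concatenate(j_idx) if j_idx else np.array([], dtype=int)
    n = len(rr)
    graph = coo_matrix((data, (i_idx, j_idx)), shape=(n, n)).tocsr()
    return graph, node, (rr, cc)


def cost_distance(friction: FrictionSurface, source: tuple[int, int]) -> np.ndarray:
    """Accumulated least-cost surface from one source cell (NaN off-mask)."""
    r, s = source
    if not friction.mask[r, s]:
        raise ValueError(f"source cell {source} is masked")
    graph, node, (rr, cc) = _raster_graph(friction)
    dist = dijkstra(graph, directed=False, indices=node[r, s])
    out = np.full(friction.grid.shape, np.nan)
    out[rr, cc] = dist
    return out


def least_cost_path(friction: FrictionSurface, a: tuple[int, int],
                    b: tuple[int, int]) -> tuple[list[tuple[int, int]], float]:
    """Minimal accumulated-cost path between two cells.

    Returns the cell sequence a -> b and the total cost; raises if the
    cells are masked or disconnected. Cost is symmetric in (a, b).
    """
    for cell_rc in (a, b):
        if not friction.mask[cell_rc]:
            raise ValueError(f"cell {cell_rc} is masked")
    if a == b:
        return [a], 0.0
    graph, node, (rr, cc) = _raster_graph(friction)
    dist, pred = dijkstra(
        graph, directed=False, indices=node[a], return_predecessors=True
    )
    target = node[b]
    if not np.isfinite(dist[target]):
        raise ValueError(f"cells {a} and {b} are not connected")
    path_nodes = [target]
    while path_nodes[-1] != node[a]:
        path_nodes.append(pred[path_nodes[-1]])
    path_nodes.reverse()
    path = [(int(rr[i]), int(cc[i])) for i in path_nodes]
    return path, float(dist[target])


def shared_haplotype_links(haps: HaplotypeSet) -> set[tuple[str, str]]:
    """Unordered population pairs whose haplotype sets intersect."""
    by_pop = haps.population_haplotypes()
    pops = sorted(by_pop)
    links: set[tuple[str, str]] = set()
    for i, p in enumerate(pops):
        for q in pops[i + 1:]:
            if by_pop[p] & by_pop[q]:
                links.add((p, q))
    return links


def _snap_populations(pops: PopulationSet, friction: FrictionSurface
                      ) -> list[tuple[int, int]]:
    """Snap each population to the nearest unmasked cell centre."""
    grid = friction.grid
    rr, cc = np.nonzero(friction.mask)
    cells = []
    for pid, lon, lat in zip(pops.ids, pops.lons, pops.lats):
        r, c = grid.cell_of(lon, lat)
        if friction.mask[r, c]:
            cells.append((r, c))
            continue
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        j = int(np.argmin(d2))
        warnings.warn(
            f"population {pid} snapped {np.sqrt(d2[j]):.1f} cells to nearest "
            "unmasked cell"
        )
        cells.append((int(rr[j]), int(cc[j])))
    return cells


def build_network(pops: PopulationSet, friction: FrictionSurface,
                  links: set[tuple[str, str]] | None = None,
                  mode: str = "all-pairs") -> ConnectivityNetwork:
    """Least-cost-path network over populations.

    ``mode="all-pairs"`` joins every pair; ``mode="shared-haplotype"``
    joins only the pairs in ``links`` (from
    :func:`shared_haplotype_links`). Unreachable pairs keep an edge with
    infinite cost and empty path.
    """
    if mode not in ("all-pairs", "shared-haplotype"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "shared-haplotype" and links is None:
        raise ValueError("shared-haplotype mode requires links")
    cells = _snap_populations(pops, friction)
    wanted: list[tuple[int, int]] = []
    n = len(pops)
    for i in range(n):
        for j in range(i + 1, n):
            pair = tuple(sorted((pops.ids[i], pops.ids[j])))
            if mode == "all-pairs" or pair in links:
                wanted.append((i, j))
    graph, node, (rr, cc) = _raster_graph(friction)
    shared_set = links or set()
    edges: list[NetworkEdge] = []
    by_source: dict[int, list[int]] = {}
    for i, j in wanted:
        by_source.setdefault(i, []).append(j)
    for i, targets in by_source.items():
        src = node[cells[i]]
        dist, pred = dijkstra(
            graph, directed=False, indices=src, return_predecessors=True
        )
        for j in targets:
            tgt = node[cells[j]]
            pair = tuple(sorted((pops.ids[i], pops.ids[j])))
            if not np.isfinite(dist[tgt]):
                edges.append(
                    NetworkEdge(pops.ids[i], pops.ids[j], np.inf, [],
                                pair in shared_set)
                )
                continue
            path_nodes = [tgt]
            while path_nodes[-1] != src:
                path_nodes.append(pred[path_nodes[-1]])
            path_nodes.reverse()
            path = [(int(rr[k]), int(cc[k])) for k in path_nodes]
            edges.append(
                NetworkEdge(pops.ids[i], pops.ids[j], float(dist[tgt]), path,
                            pair in shared_set)
            )
    return ConnectivityNetwork(pops, edges, mode)


def resistance_matrix(pops: PopulationSet, friction: FrictionSurface) -> np.ndarray:
    """Symmetric matrix of pairwise accumulated cost distances."""
    cells = _snap_populations(pops, friction)
    graph, node, _ = _raster_graph(friction)
    idx = np.array([node[c] for c in cells])
    dist = dijkstra(graph, directed=False, indices=idx)
    R = dist[:, idx]
    R = 0.5 * (R + R.T)  # symmetrize away float round-off
    np.fill_diagonal(R, 0.0)
    return R
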