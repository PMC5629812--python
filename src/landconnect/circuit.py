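"""Raster circuit theory: lattice Laplacians, effective resistance, and
omnidirectional current-density mapping.

A resistance raster is recast as an electrical network: each non-NoData
cell is a node, adjacent cells are joined by a resistor whose resistance is
the arithmetic mean of the two cell costs (diagonal neighbors, when
enabled, are scaled by sqrt(2) for the longer span).  Current injected
between a source and a ground then spreads over all paths in proportion to
their conductance, so per-cell current density is proportional to the
probability that a random walker moves through the cell, and the
voltage-to-current ratio between two terminals is their effective
resistance in ohms — a pairwise isolation measure.

Omnidirectional maps average current density over many randomized
source/ground pairs placed on a buffer *outside* the study-area perimeter,
which removes the current build-up near interior terminals known as node
placement bias, and the map is standardized to mean zero over the study
area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .raster import Raster, classify_landcover  # noqa: F401  (re-exported)

__all__ = [
    "LatticeCircuit",
    "CurrentDensityMap",
    "NeighborhoodResult",
    "build_circuit",
    "solve_pair",
    "effective_resistance",
    "effective_resistance_matrix",
    "cell_current_density",
    "omnidirectional_map",
    "neighborhood_analysis",
    "classify_landcover",
]

#: hard ceiling on solvable raster size; tiling larger mosaics is out of scope
DEFAULT_MAX_CELLS = 4_000_000


@dataclass
class LatticeCircuit:
    """Sparse electrical-network view of a resistance raster."""

    raster: Raster
    node_of: np.ndarray            # (rows, cols) int, -1 where NoData
    cells: np.ndarray              # (n_nodes, 2) row/col per node
    edge_u: np.ndarray             # edge endpoint node ids
    edge_v: np.ndarray
    conductance: np.ndarray        # per-edge, siemens (1/ohm)
    laplacian: sp.csr_matrix
    component: np.ndarray          # per-node component label
    _factors: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.cells.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_u.size

    def node_at(self, cell: tuple[int, int]) -> int:
        node = int(self.node_of[cell[0], cell[1]])
        if node < 0:
            raise ValueError(f"cell {cell} is NoData; no circuit node")
        return node

    def _component_solver(self, comp: int):
        """LU factorization of the component Laplacian with its first node
        grounded (row/column deleted); cached per component."""
        if comp not in self._factors:
            idx = np.flatnonzero(self.component == comp)
            if idx.size < 2:
                raise ValueError("component has fewer than 2 nodes; nothing to solve")
            sub = self.laplacian[np.ix_(idx, idx)]
            reduced = sub[1:, :][:, 1:].tocsc()
            lu = splu(reduced)
            local = np.full(self.n_nodes, -1, dtype=int)
            local[idx] = np.arange(idx.size)
            self._factors[comp] = (idx, local, lu, sub.tocsr())
        return self._factors[comp]

    def solve_injection(self, source: int, ground: int, current: float = 1.0) -> np.ndarray:
        """Node voltages with ``current`` amperes injected at ``source`` and
        extracted at ``ground`` (fixed at 0 V).  Nodes outside the terminals'
        component are NaN."""
        if source == ground:
            raise ValueError("source and ground must differ")
        comp = int(self.component[source])
        if int(self.component[ground]) != comp:
            raise ValueError(
                "source and ground lie in different connected components; "
                "no current can flow between them"
            )
        idx, local, lu, sub = self._component_solver(comp)
        m = idx.size - 1
        b = np.zeros(m)
        ls, lg = local[source], local[ground]
        if ls > 0:
            b[ls - 1] += current
        if lg > 0:
            b[lg - 1] -= current
        x = lu.solve(b)
        v_local = np.concatenate(([0.0], x))
        v_local -= v_local[lg]
        # relative residual against the full component Laplacian
        rhs = np.zeros(idx.size)
        rhs[ls] = current
        rhs[lg] = -current
        res = sub @ v_local - rhs
        rel = np.linalg.norm(res) / max(np.linalg.norm(rhs), 1e-300)
        if rel > 1e-8:
            raise RuntimeError(f"linear solve residual {rel:.2e} exceeds 1e-8")
        v = np.full(self.n_nodes, np.nan)
        v[idx] = v_local
        return v


def build_circuit(
    raster: Raster,
    connectivity: str = "four",
    max_cells: int = DEFAULT_MAX_CELLS,
) -> LatticeCircuit:
    """Assemble the lattice circuit for a resistance raster.

    Edge resistance is the arithmetic mean of the two incident cell costs;
    diagonal edges (``connectivity="eight"``) are scaled by sqrt(2).
    """
    if connectivity not in {"four", "eight"}:
        raise ValueError("connectivity must be 'four' or 'eight'")
    data = raster.data
    if data.size > max_cells:
        raise ValueError(
            f"raster has {data.size} cells, above the {max_cells} guard; "
            "tiled mosaics are not supported"
        )
    finite = np.isfinite(data)
    if finite.sum() < 2:
        raise ValueError("raster needs at least 2 non-NoData cells")
    if np.any(data[finite] <= 0):
        raise ValueError("resistance costs must be strictly positive")

    node_of = np.full(data.shape, -1, dtype=int)
    cells = np.argwhere(finite)
    node_of[finite] = np.arange(cells.shape[0])

    offsets = [(0, 1), (1, 0)]
    if connectivity == "eight":
        offsets += [(1, 1), (1, -1)]
    eu, ev, cond = [], [], []
    rows, cols = data.shape
    for dr, dc in offsets:
        r0 = slice(0, rows - dr)
        r1 = slice(dr, rows)
        if dc >= 0:
            c0, c1 = slice(0, cols - dc), slice(dc, cols)
        else:
            c0, c1 = slice(-dc, cols), slice(0, cols + dc)
        ok = finite[r0, c0] & finite[r1, c1]
        a = node_of[r0, c0][ok]
        b = node_of[r1, c1][ok]
        resistance = 0.5 * (data[r0, c0][ok] + data[r1, c1][ok])
        if dr and dc:
            resistance = resistance * np.sqrt(2.0)
        eu.append(a)
        ev.append(b)
        cond.append(1.0 / resistance)
    edge_u = np.concatenate(eu)
    edge_v = np.concatenate(ev)
    conductance = np.concatenate(cond)

    n = cells.shape[0]
    adj = sp.coo_matrix(
        (np.concatenate([conductance, conductance]),
         (np.concatenate([edge_u, edge_v]), np.concatenate([edge_v, edge_u]))),
        shape=(n, n),
    ).tocsr()
    lap = sp.diags(np.asarray(adj.sum(axis=1)).ravel()) - adj
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        warnings.warn(
            f"raster splits into {n_comp} connected components "
            f"(sizes {sorted(sizes, reverse=True)[:5]}...); solves are "
            "restricted to the component containing the terminals"
        )
    return LatticeCircuit(
        raster=raster,
        node_of=node_of,
        cells=cells,
        edge_u=edge_u,
        edge_v=edge_v,
        conductance=conductance,
        laplacian=lap.tocsr(),
        component=labels,
    )


def _as_node(circuit: LatticeCircuit, terminal) -> int:
    if isinstance(terminal, (int, np.integer)):
        return int(terminal)
    return circuit.node_at(tuple(terminal))


def solve_pair(circuit: LatticeCircuit, source, ground, current: float = 1.0) -> np.ndarray:
    """Node voltages for a unit (or given) current between two terminals.

    Terminals may be node ids or (row, col) cells. The ground is held at
    0 V; voltages are NaN outside the terminals' component.
    """
    s = _as_node(circuit, source)
    g = _as_node(circuit, ground)
    return circuit.solve_injection(s, g, current)


def effective_resistance(circuit: LatticeCircuit, source, ground, current: float = 1.0) -> float:
    """Two-terminal effective resistance in ohms: (v_s - v_g) / I."""
    s = _as_node(circuit, source)
    g = _as_node(circuit, ground)
    v = circuit.solve_injection(s, g, current)
    return float((v[s] - v[g]) / current)


def effective_resistance_matrix(circuit: LatticeCircuit, terminals: Sequence) -> np.ndarray:
    """Pairwise effective resistance among a set of terminals.

    One linear solve per terminal (all against the component's grounded
    reference), then R(a, b) = (e_a - e_b)' L_r^{-1} (e_a - e_b).
    """
    nodes = [_as_node(circuit, t) for t in terminals]
    comps = {int(circuit.component[n]) for n in nodes}
    if len(comps) > 1:
        raise ValueError("terminals span multiple connected components")
    comp = comps.pop()
    idx, local, lu, _ = circuit._component_solver(comp)
    m = idx.size - 1
    ys = []
    for n in nodes:
        ln = local[n]
        b = np.zeros(m)
        if ln > 0:
            b[ln - 1] = 1.0
        y = np.concatenate(([0.0], lu.solve(b))) if ln > 0 else np.zeros(m + 1)
        ys.append(y)
    k = len(nodes)
    out = np.zeros((k, k))
    for i in range(k):
        li = local[nodes[i]]
        for j in range(i + 1, k):
            lj = local[nodes[j]]
            r = ys[i][li] + ys[j][lj] - ys[i][lj] - ys[j][li]
            out[i, j] = out[j, i] = r
    return out


def cell_current_density(circuit: LatticeCircuit, voltages: np.ndarray) -> np.ndarray:
    """Per-cell current density: half the sum of absolute currents on a
    cell's incident resistors (terminal cells included).

    Returns a grid shaped like the raster, NaN at NoData cells.
    """
    if voltages.shape != (circuit.n_nodes,):
        raise ValueError("voltages must be a per-node vector from solve_pair")
    dv = voltages[circuit.edge_u] - voltages[circuit.edge_v]
    dv = np.where(np.isnan(dv), 0.0, dv)
    edge_i = np.abs(circuit.conductance * dv)
    per_node = np.zeros(circuit.n_nodes)
    np.add.at(per_node, circuit.edge_u, edge_i)
    np.add.at(per_node, circuit.edge_v, edge_i)
    per_node *= 0.5
    grid = np.full(circuit.raster.shape, np.nan)
    grid[circuit.cells[:, 0], circuit.cells[:, 1]] = per_node
    return grid


def net_currents(circuit: LatticeCircuit, voltages: np.ndarray) -> np.ndarray:
    """Signed net current at every node (Kirchhoff balance diagnostic)."""
    v = np.where(np.isnan(voltages), 0.0, voltages)
    return np.asarray(circuit.laplacian @ v)


@dataclass
class CurrentDensityMap:
    """Omnidirectional current-density surface over the study area.

    ``current`` holds densities standardized to mean zero over non-NoData
    study-area cells; ``raw_mean`` is the pre-standardization mean so the
    raw surface can be recovered.
    """

    current: Raster
    n_pairs: int
    buffer_cells: int
    buffer_cost: float
    raw_mean: float
    pair_cells: list  # [((r, c), (r, c)), ...] in padded-grid coordinates


def _perimeter_cells(rows: int, cols: int) -> np.ndarray:
    """Outermost ring of a rows x cols grid, ordered around the boundary."""
    top = [(0, c) for c in range(cols)]
    right = [(r, cols - 1) for r in range(1, rows)]
    bottom = [(rows - 1, c) for c in range(cols - 2, -1, -1)]
    left = [(r, 0) for r in range(rows - 2, 0, -1)]
    return np.array(top + right + bottom + left)


def omnidirectional_map(
    raster: Raster,
    n_pairs: int = 64,
    buffer_cells: int = 8,
    buffer_cost: float | None = None,
    seed: int = 0,
    connectivity: str = "four",
) -> CurrentDensityMap:
    """Average current density over random perimeter source/ground pairs.

    The raster is padded by ``buffer_cells`` of uniform ``buffer_cost``
    (default: mean study-area cost, a neutral medium), pairs are drawn
    without replacement from the outer perimeter of the pad with members
    at least 90 degrees apart around the boundary, per-pair densities are
    averaged, the pad is clipped, and the study-area surface is
    standardized to mean zero.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if buffer_cells < 1:
        raise ValueError("buffer_cells must be >= 1")
    data = raster.data
    finite = np.isfinite(data)
    if buffer_cost is None:
        buffer_cost = float(np.mean(data[finite]))
    padded = np.pad(data, buffer_cells, constant_values=buffer_cost)
    # NoData holes inside the study area stay NoData; the pad is conductive
    pad_raster = replace(
        raster,
        data=padded,
        xll=raster.xll - buffer_cells * raster.cell_size,
        yll=raster.yll - buffer_cells * raster.cell_size,
    )
    circuit = build_circuit(pad_raster, connectivity=connectivity)

    rows, cols = padded.shape
    ring = _perimeter_cells(rows, cols)
    if ring.shape[0] < 2 * n_pairs:
        raise ValueError(
            f"perimeter has {ring.shape[0]} cells; cannot place {n_pairs} "
            "disjoint pairs"
        )
    cy, cx = (rows - 1) / 2, (cols - 1) / 2
    angles = np.arctan2(ring[:, 0] - cy, ring[:, 1] - cx)

    rng = np.random.default_rng(seed)
    available = np.ones(ring.shape[0], dtype=bool)
    pairs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for _ in range(n_pairs):
        cand = np.flatnonzero(available)
        s = int(rng.choice(cand))
        available[s] = False
        sep = np.abs(np.angle(np.exp(1j * (angles - angles[s]))))
        ok = np.flatnonzero(available & (sep >= np.pi / 2))
        if ok.size == 0:
            raise ValueError(
                "no perimeter cell at >= 90 degrees separation remains; "
                "reduce n_pairs or enlarge the raster"
            )
        g = int(rng.choice(ok))
        available[g] = False
        pairs.append((tuple(ring[s]), tuple(ring[g])))

    acc = np.zeros(padded.shape)
    for s_cell, g_cell in pairs:
        v = solve_pair(circuit, s_cell, g_cell)
        dens = cell_current_density(circuit, v)
        acc += np.where(np.isnan(dens), 0.0, dens)
    acc /= n_pairs

    b = buffer_cells
    study = acc[b:-b, b:-b].copy()
    study[~finite] = np.nan
    raw_mean = float(np.nanmean(study))
    study -= raw_mean
    out = replace(raster, data=study)
    return CurrentDensityMap(
        current=out,
        n_pairs=n_pairs,
        buffer_cells=buffer_cells,
        buffer_cost=float(buffer_cost),
        raw_mean=raw_mean,
        pair_cells=pairs,
    )


@dataclass
class NeighborhoodResult:
    """Current-vs-resistance diagnostic for one circular neighborhood."""

    site: tuple[float, float]
    radius_m: float
    mean_effective_resistance: float
    mean_current_density: float
    focal_cells: list
    pair_resistances: list
    clipped: bool


def neighborhood_analysis(
    raster: Raster,
    site: tuple[float, float],
    radius_m: float,
    inset_m: float = 300.0,
    seed: int = 0,
    connectivity: str = "four",
    current_map: CurrentDensityMap | None = None,
) -> NeighborhoodResult:
    """Mean effective resistance vs mean current density in a circle.

    Five focal nodes are placed 72 degrees apart on the circle of radius
    ``radius_m - inset_m`` around ``site`` (starting angle drawn from
    ``seed``; the inset keeps terminals off the clipped boundary), and the
    effective resistance of the five next-nearest pairs (i, i+2 mod 5) is
    averaged.  Mean current density is taken over the circular mask from
    the same five solves, unless ``current_map`` supplies a precomputed
    omnidirectional surface to sample instead.
    """
    if radius_m <= inset_m:
        raise ValueError("radius_m must exceed inset_m")
    X, Y = raster.cell_centers()
    sx, sy = site
    dist2 = (X - sx) ** 2 + (Y - sy) ** 2
    mask = dist2 <= radius_m**2
    xmin, ymin, xmax, ymax = raster.extent
    clipped = (
        sx - radius_m < xmin or sx + radius_m > xmax
        or sy - radius_m < ymin or sy + radius_m > ymax
    )
    if clipped:
        warnings.warn("neighborhood circle extends beyond the raster; clipped")
    circle = np.where(mask, raster.data, np.nan)
    if np.isfinite(circle).sum() < 10:
        raise ValueError("circular neighborhood covers too few valid cells")
    sub = replace(raster, data=circle)
    circuit = build_circuit(sub, connectivity=connectivity)
    # snap focal points into the largest component so all pairs are solvable
    comp_sizes = np.bincount(circuit.component)
    main = int(np.argmax(comp_sizes))
    valid_cells = circuit.cells[circuit.component == main]
    vx = raster.xll + (valid_cells[:, 1] + 0.5) * raster.cell_size
    vy = raster.yll + (raster.n_rows - valid_cells[:, 0] - 0.5) * raster.cell_size

    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0.0, 2 * np.pi)
    focal_nodes: list[int] = []
    focal_cells: list[tuple[int, int]] = []
    for k in range(5):
        th = theta0 + 2 * np.pi * k / 5
        fx = sx + (radius_m - inset_m) * np.cos(th)
        fy = sy + (radius_m - inset_m) * np.sin(th)
        j = int(np.argmin((vx - fx) ** 2 + (vy - fy) ** 2))
        cell = tuple(valid_cells[j])
        focal_cells.append(cell)
        focal_nodes.append(circuit.node_at(cell))

    pair_r: list[float] = []
    acc = np.zeros(raster.shape)
    for i in range(5):
        a, b = focal_nodes[i], focal_nodes[(i + 2) % 5]
        if a == b:  # degenerate snap on a tiny mask
            continue
        v = circuit.solve_injection(a, b)
        pair_r.append(float(v[a] - v[b]))
        dens = cell_current_density(circuit, v)
        acc += np.where(np.isnan(dens), 0.0, dens)
    if not pair_r:
        raise ValueError("all focal-node pairs were degenerate")
    acc /= len(pair_r)

    if current_map is not None:
        cur = current_map.current.data
        mean_current = float(np.nanmean(np.where(mask, cur, np.nan)))
    else:
        mean_current = float(np.mean(acc[mask & np.isfinite(circle)]))
    return NeighborhoodResult(
        site=(float(sx), float(sy)),
        radius_m=float(radius_m),
        mean_effective_resistance=float(np.mean(pair_r)),
        mean_current_density=mean_current,
        focal_cells=focal_cells,
        pair_resistances=pair_r,
        clipped=bool(clipped),
    )
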