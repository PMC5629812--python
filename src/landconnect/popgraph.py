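"""Population graphs: saturated genetic networks, conditional-independence
edge pruning, conditional genetic distance (cGD), and node connectivity.

Sampled sites are nodes; the saturated network joins every pair with an
edge weighted by the among-population genetic distance.  Edges that do not
carry direct genetic covariance — whose partial correlation given all
other sites is negligible — are pruned with the edge-exclusion deviance
of a Gaussian graphical model: EED_ij = -N ln(1 - r_ij.rest^2), compared
to a chi-square(1) critical value.  Shortest-path length along the pruned
network is the conditional genetic distance, and the per-node mean of
reciprocal incident edge weights ("average inverse edge weight") is the
node-based genetic-connectivity response, z-scored within species so that
species can be compared on one scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genetics import PopulationMatrixSet

__all__ = [
    "CgdMatrix",
    "saturated_graph",
    "prune_edges",
    "conditional_genetic_distance",
    "node_connectivity",
    "write_graphml",
    "read_graphml",
]

log = logging.getLogger(__name__)


def saturated_graph(
    mats: PopulationMatrixSet,
    meta: pd.DataFrame | None = None,
) -> nx.Graph:
    """Complete graph on sites with genetic distance D_ij as edge weight.

    ``meta`` may carry per-site columns (x, y, species, ...) indexed or
    keyed by ``site_id``; zero distances between distinct sites are
    clamped to 1e-9 x max(D) with a warning (identical populations).
    """
    sites = mats.site_order
    G = nx.Graph(alpha=None)
    meta_by_site: dict[str, dict] = {}
    if meta is not None:
        m = meta.set_index("site_id") if "site_id" in meta.columns else meta
        meta_by_site = m.to_dict("index")
    for i, s in enumerate(sites):
        attrs = dict(meta_by_site.get(s, {}))
        attrs["n"] = int(mats.n_per_site[s])
        G.add_node(s, **attrs)
    eps = 1e-9 * float(mats.D.max()) if mats.D.max() > 0 else 1e-9
    clamped = []
    for i, j in combinations(range(len(sites)), 2):
        w = float(mats.D[i, j])
        if w <= 0:
            clamped.append((sites[i], sites[j]))
            w = eps
        G.add_edge(sites[i], sites[j], weight=w)
    if clamped:
        warnings.warn(
            f"zero genetic distance clamped to {eps:.3g} for pairs {clamped}"
        )
    return G


def _partial_correlations(C: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    """Pairwise partial correlations given all remaining sites.

    C is converted to a correlation matrix and inverted to a precision
    matrix through an eigen-truncated (Moore-Penrose) inverse: the
    grand-centered among-site covariance always carries a null direction
    (its rows sum to zero), so eigenvalues below ``rcond`` x the largest
    are treated as exact zeros rather than ridged into huge precisions.
    """
    C = np.asarray(C, dtype=float)
    d = np.sqrt(np.clip(C.diagonal(), 1e-300, None))
    R = C / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    w, V = np.linalg.eigh(0.5 * (R + R.T))
    w_max = float(w.max())
    if w_max <= 0:
        raise ValueError("correlation matrix has no positive eigenvalues")
    rank = int((w > rcond * w_max).sum())
    if rank < R.shape[0]:
        log.info("correlation matrix rank %d < %d; pseudoinverse precision",
                 rank, R.shape[0])
    winv = np.where(w > rcond * w_max, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    P = (V * winv) @ V.T
    pd_ = np.sqrt(np.clip(P.diagonal(), 1e-300, None))
    r = -P / np.outer(pd_, pd_)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1 + 1e-15, 1 - 1e-15)


def prune_edges(
    graph: nx.Graph,
    C: np.ndarray,
    n_total: int,
    alpha: float = 0.05,
) -> nx.Graph:
    """Drop edges whose removal does not degrade the graphical-model fit.

    For each pair, the edge-exclusion deviance EED = -N ln(1 - r^2) with r
    the partial correlation given all other sites and N the post-filter
    total number of individuals; the edge is retained iff EED exceeds the
    chi-square(1) critical value at ``alpha`` (3.841 at 0.05).  The
    returned graph carries a ``pruning`` record covering every pair.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    sites = list(graph.nodes)
    k = len(sites)
    if C.shape != (k, k):
        raise ValueError("covariance matrix does not match graph nodes")
    r = _partial_correlations(C)
    crit = stats.chi2.ppf(1 - alpha, df=1) if alpha < 1 else 0.0
    pruned = nx.Graph(alpha=alpha)
    pruned.add_nodes_from(graph.nodes(data=True))
    record = []
    for i, j in combinations(range(k), 2):
        eed = -n_total * np.log1p(-r[i, j] ** 2)
        keep = bool(eed > crit)
        record.append((sites[i], sites[j], float(graph[sites[i]][sites[j]]["weight"]),
                       float(eed), keep))
        if keep:
            pruned.add_edge(
                sites[i], sites[j],
                weight=graph[sites[i]][sites[j]]["weight"],
                eed=float(eed),
            )
    pruned.graph["pruning"] = pd.DataFrame(
        record, columns=["site_a", "site_b", "weight", "eed", "kept"]
    )
    log.info(
        "pruned %d of %d edges at alpha=%g (N=%d)",
        k * (k - 1) // 2 - pruned.number_of_edges(),
        k * (k - 1) // 2, alpha, n_total,
    )
    return pruned


@dataclass
class CgdMatrix:
    """All-pairs shortest-path (conditional genetic) distances."""

    site_order: list[str]
    values: np.ndarray     # inf where unreachable
    reachable: np.ndarray  # boolean mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_order, columns=self.site_order)


def conditional_genetic_distance(graph: nx.Graph) -> CgdMatrix:
    """Shortest-path lengths along the pruned network (cGD).

    Unreachable pairs are flagged (inf), never fabricated; a disconnected
    graph triggers a warning listing its components.
    """
    sites = list(graph.nodes)
    k = len(sites)
    pos = {s: i for i, s in enumerate(sites)}
    vals = np.full((k, k), np.inf)
    np.fill_diagonal(vals, 0.0)
    for src, lengths in nx.all_pairs_dijkstra_path_length(graph, weight="weight"):
        for dst, d in lengths.items():
            vals[pos[src], pos[dst]] = d
    comps = list(nx.connected_components(graph))
    if len(comps) > 1:
        warnings.warn(
            f"pruned graph has {len(comps)} components: "
            + "; ".join(",".join(sorted(c)) for c in comps)
        )
    return CgdMatrix(site_order=sites, values=vals, reachable=np.isfinite(vals))


def node_connectivity(
    graph: nx.Graph,
    species: dict[str, str] | pd.Series | None = None,
    all_pairs_cgd: bool = False,
) -> pd.DataFrame:
    """Node-based genetic connectivity table.

    Per node: degree, mean incident edge weight, mean inverse incident
    edge weight, and the within-species z-score of the latter (the
    standardized response used in the regression stage).  With
    ``all_pairs_cgd=True`` the means are taken over 1/cGD to all reachable
    nodes instead of incident edges.  Isolated nodes get NaN connectivity
    and are excluded from the z-scores; a species with fewer than two
    scored nodes is an error (its z-score is undefined).
    """
    sites = list(graph.nodes)
    if species is None:
        species_of = {s: graph.nodes[s].get("species", "all") for s in sites}
    elif isinstance(species, pd.Series):
        species_of = species.to_dict()
    else:
        species_of = dict(species)

    rows = []
    if all_pairs_cgd:
        cgd = conditional_genetic_distance(graph)
        for i, s in enumerate(sites):
            d = cgd.values[i]
            ok = np.isfinite(d) & (np.arange(len(sites)) != i)
            mw = float(np.mean(d[ok])) if ok.any() else np.nan
            miw = float(np.mean(1.0 / d[ok])) if ok.any() else np.nan
            rows.append((s, species_of[s], int(graph.degree[s]), mw, miw))
    else:
        for s in sites:
            w = np.array([graph[s][t]["weight"] for t in graph.neighbors(s)])
            if w.size == 0:
                log.warning("node %s is isolated; connectivity undefined", s)
                rows.append((s, species_of[s], 0, np.nan, np.nan))
            else:
                rows.append((s, species_of[s], int(w.size),
                             float(np.mean(w)), float(np.mean(1.0 / w))))
    df = pd.DataFrame(
        rows, columns=["site_id", "species", "degree", "mean_edge_weight",
                       "mean_inverse_edge_weight"],
    )
    z = np.full(len(df), np.nan)
    for sp, sub in df.groupby("species"):
        vals = sub["mean_inverse_edge_weight"].to_numpy()
        scored = np.isfinite(vals)
        if scored.sum() < 2:
            raise ValueError(
                f"species {sp!r} has {int(scored.sum())} scored node(s); "
                "z-score undefined"
            )
        mu, sd = vals[scored].mean(), vals[scored].std(ddof=1)
        if sd == 0:
            zz = np.where(scored, 0.0, np.nan)
        else:
            zz = np.where(scored, (vals - mu) / sd, np.nan)
        z[sub.index] = zz
    df["connectivity_z"] = z
    for s, row in zip(df["site_id"], df.itertuples()):
        for attr in ("x", "y", "n"):
            if attr in graph.nodes[s]:
                df.loc[row.Index, attr] = graph.nodes[s][attr]
    return df


def write_graphml(graph: nx.Graph, path) -> None:
    """GraphML export (pruning record and non-scalar attrs are dropped)."""
    G = nx.Graph()
    G.add_nodes_from(
        (n, {k: v for k, v in d.items() if isinstance(v, (int, float, str, bool))})
        for n, d in graph.nodes(data=True)
    )
    G.add_edges_from(
        (u, v, {k: w for k, w in d.items() if isinstance(w, (int, float, str, bool))})
        for u, v, d in graph.edges(data=True)
    )
    nx.write_graphml(G, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
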