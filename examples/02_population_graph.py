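"""Build a population graph from genotypes: saturated network, edge
pruning by conditional independence, conditional genetic distance (cGD),
and the node connectivity response.

Run 01_simulate_landscape_and_genotypes.py first (reads its CSVs).
"""

import numpy as np
import pandas as pd

from landconnect import (
    conditional_genetic_distance,
    encode_multivariate,
    filter_individuals,
    node_connectivity,
    population_covariance,
    prune_edges,
    read_genotypes,
    saturated_graph,
)

table = filter_individuals(read_genotypes("genotypes.csv", sites_path="sites.csv"))
mats = population_covariance(encode_multivariate(table), np.asarray(table.site_ids))

meta = pd.DataFrame(
    [{"site_id": s, "x": xy[0], "y": xy[1], "species": "sim"}
     for s, xy in table.sites.items()]
)
graph = saturated_graph(mats, meta)
pruned = prune_edges(graph, mats.C, n_total=table.n_individuals, alpha=0.05)
print(f"saturated edges: {graph.number_of_edges()}, kept after pruning: "
      f"{pruned.number_of_edges()} (edge-exclusion deviance vs chi2, alpha=0.05)")

cgd = conditional_genetic_distance(pruned)
print("cGD matrix (shortest paths along the pruned network):")
print(cgd.to_frame().round(2))

nodes = node_connectivity(pruned)
print(nodes[["site_id", "degree", "mean_inverse_edge_weight", "connectivity_z"]]
      .round(3).to_string(index=False))
print("-> mean_inverse_edge_weight is the node's genetic-connectivity proxy;")
print("   connectivity_z puts it on a common within-species scale.")
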