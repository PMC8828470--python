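"""Neighborhood enrichment and related cluster-level graph statistics.

Two spatially segregated clusters should be enriched for within-cluster
adjacency (positive diagonal z) and depleted for between-cluster adjacency
(negative off-diagonal z).
"""

import numpy as np

import spomics as spm

# two spatial blocks -> block labels are spatially coherent
ds = spm.simulate_points(
    spm.SimulationSpec(n_points=300, pattern="poisson", label_model="blocks", n_labels=2, seed=3)
)
graph = spm.knn_graph(ds, 6)

res = spm.nhood_enrichment(ds, graph, "cluster", n_perms=1000, seed=0)
print("clusters:", res.clusters)
print("z-score matrix (rows/cols = clusters):")
print(np.round(res.zscore, 1))
print("-> positive diagonal: clusters sit next to themselves; negative "
      "off-diagonal: the two blocks rarely touch.")

im = spm.interaction_matrix(ds, graph, "cluster", normalized=True)
print("\nrow-normalized interaction matrix (share of each cluster's edges):")
print(im.round(2))

cent = spm.centrality_scores(ds, graph, "cluster").join(
    spm.group_betweenness(ds, graph, "cluster")
)
print("\ngroup centralities:")
print(cent[["degree_centrality", "closeness_centrality", "average_clustering",
            "group_betweenness"]].round(3))
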