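"""Build spatial neighbor graphs in all four modalities.

A Visium-style hexagonal lattice gets a grid graph with ring weights; a
dissociated (cell-resolution) pattern gets kNN, radius and Delaunay graphs.
"""

import numpy as np

import spomics as spm

# hexagonal lattice, like an array-based spatial transcriptomics slide
lattice = spm.simulate_points(
    spm.SimulationSpec(n_points=100, pattern="lattice", lattice_kind="hex", pitch=1.0, seed=0)
)
grid = spm.grid_graph(lattice, n_neigh=6, n_rings=2)
center = int(np.argmin(np.linalg.norm(lattice.coords - lattice.coords.mean(axis=0), axis=1)))
row = grid.connectivity.getrow(center)
print(f"grid graph: interior spot has {int((row.data == 1).sum())} first-ring and "
      f"{int((row.data == 2).sum())} second-ring neighbors (weights = ring ordinals)")

# dissociated coordinates, like an imaging-based dataset
cells = spm.simulate_points(spm.SimulationSpec(n_points=200, pattern="poisson", seed=1))
for name, g in [
    ("kNN (k=6)", spm.knn_graph(cells, 6)),
    ("radius 10", spm.radius_graph(cells, 10.0)),
    ("Delaunay", spm.delaunay_graph(cells)),
]:
    print(f"{name}: {g.n_edges} edges, mean degree "
          f"{2 * g.n_edges / g.n_obs:.1f}")

# spectral transform for graph-convolutional downstream use
spec = spm.transform_graph(spm.knn_graph(cells, 6), "spectral")
print(f"spectral transform: weights in [{spec.connectivity.data.min():.3f}, "
      f"{spec.connectivity.data.max():.3f}] (D^-1/2 A D^-1/2)")
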