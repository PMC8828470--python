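"""Detect spatially variable genes with Moran's I, Geary's C and sepal.

Two genes carry a planted spatial block pattern; the rest are noise.  All
three statistics should single the planted genes out.
"""

import spomics as spm

ds = spm.simulate_points(
    spm.SimulationSpec(
        n_points=100, pattern="lattice", lattice_kind="hex", pitch=1.0,
        expression_model="planted-spatial", n_genes=6, n_spatial_genes=2,
        block_effect=3.0, seed=7,
    )
)
grid = spm.grid_graph(ds, n_neigh=6, n_rings=1)

moran = spm.spatial_autocorr(ds, grid, "moran", n_perms=1000, seed=0).table
geary = spm.spatial_autocorr(ds, grid, "geary", n_perms=0, seed=0).table
sep = spm.sepal(ds, grid, dt=0.01, max_iters=20000).table

print("gene  moran_I  p_adj   geary_C  sepal_score")
for g in ds.var_ids:
    print(f"{g:>4}  {moran.loc[g, 'statistic']:7.3f}  {moran.loc[g, 'pvalue_adj']:.3f}"
          f"  {geary.loc[g, 'statistic']:7.3f}  {sep.loc[g, 'sepal_score']:8.2f}")
print("-> planted genes g0/g1: I near 1 (clustered), C near 0, and the "
      "largest sepal scores (their diffusion to uniformity takes longest); "
      "noise genes sit at I~0, C~1 with small sepal scores.")
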