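# spomics

Spatial statistics for spatial-omics data: neighbor graphs, cluster-level
graph statistics, point-pattern functions, spatially variable gene detection,
ligand–receptor permutation testing and tissue-image feature extraction — in
one small, self-contained Python library with a matching command-line tool.

## Who this is for

Spatial transcriptomics and proteomics assays (Visium-style spot arrays,
seqFISH/MERFISH-style single-cell imaging, imaging mass cytometry) produce an
obs × gene expression matrix plus a 2-D coordinate per observation, usually
with cluster or cell-type labels and often with a registered microscopy
image.  The recurring analysis questions are the same across technologies:
*which cell types sit next to each other more often than chance?  which genes
vary in space rather than just across cells?  which ligand–receptor pairs
connect which cluster pairs?  what does the tissue image say at each spot?*
This package answers those questions on a minimal data model
(`SpatialDataset` = matrix + coordinates + labels; `SpatialGraph` = sparse
symmetric connectivity + distances) without requiring any particular
single-cell framework.

## What it computes

**Spatial neighbor graphs** — hexagonal/square lattice graphs with ring
ordinals as weights, k-nearest-neighbor (union-symmetrized), fixed-radius and
Delaunay graphs; spectral (`D^{-1/2} A D^{-1/2}`) and cosine adjacency
transforms.

**Neighborhood enrichment** — for cluster pair (i, j), the observed number of
graph edges joining the two clusters, x_ij, is compared against label
permutations holding the graph fixed:

    Z_ij = (x_ij − μ_ij) / σ_ij

with μ, σ the permutation mean and standard deviation.  Also the ordered-pair
interaction matrix and group centralities (degree, closeness, average
clustering, group betweenness).

**Point-pattern statistics** — Ripley's L (variance-stabilized K with
`K(t) = A/(n(n−1)) Σ_{i≠j} 1[d_ij < t]`), the nearest-neighbor function G,
the empty-space function F, and the co-occurrence ratio
`p(cluster | shell) / p(cluster)` over distance shells around a conditioning
cluster.

**Spatially variable genes** — Moran's I and Geary's C

    I = (n/W) · Σ_ij w_ij z_i z_j / Σ_i z_i²
    C = (n−1) · Σ_ij w_ij (x_i − x_j)² / (2W Σ_i z_i²)

with permutation or analytic p-values and Benjamini–Hochberg correction; and
the sepal diffusion score: simulate `u ← u + D Δu dt` on the lattice and
report the time until the entropy of u stops changing — spatially structured
genes take longer to relax to uniformity.

**Ligand–receptor analysis** — a CellphoneDB-style permutation test: for each
annotated (ligand, receptor) pair and ordered cluster pair (sender,
receiver), the mean of the two cluster means is compared against label
shuffles; multi-subunit complexes are reduced per cell by the minimum (or
mean) of their subunits.

**Image features** — grayscale/Gaussian preprocessing (with overlap-tiled
execution for large images), marker-based watershed segmentation, and
per-spot summary, histogram, GLCM texture (contrast, dissimilarity,
homogeneity, angular second moment, correlation) and segmentation features,
returned as an obs × features matrix.

A `synthetic` module generates every input shape the statistics consume
(Poisson/Thomas/lattice point patterns, random or spatially blocked labels,
expression with planted spatial or ligand–receptor structure, blob images
with known ground truth), so the whole package is testable and demoable
offline.

## Worked example

```python
import spomics as spm

ds = spm.simulate_points(spm.SimulationSpec(
    n_points=100, pattern="lattice", lattice_kind="hex", pitch=1.0,
    expression_model="planted-spatial", n_genes=6, n_spatial_genes=2,
    block_effect=3.0, seed=7))
grid = spm.grid_graph(ds, n_neigh=6, n_rings=1)
moran = spm.spatial_autocorr(ds, grid, "moran", n_perms=1000, seed=0).table
sep   = spm.sepal(ds, grid, dt=0.01, max_iters=20000).table
```

Running `python examples/04_spatially_variable_genes.py` (which does exactly
this) prints:

```
gene  moran_I  p_adj   geary_C  sepal_score
  g0    0.635  0.003    0.348     50.17
  g1    0.666  0.003    0.318     46.04
  g2   -0.019  0.830    0.978      9.08
  g3   -0.046  0.830    1.020      8.61
  g4   -0.041  0.830    1.029      9.13
  g5   -0.087  0.901    1.071      8.11
```

The two planted genes (g0, g1) stand out on all three statistics: Moran's I
well above 0 with significant adjusted p-values, Geary's C well below its
null value of 1, and sepal scores ~5× those of the noise genes (their
expression takes much longer to diffuse to a uniform state).  The noise
genes sit at I ≈ 0, C ≈ 1, as expected when expression is independent of
position.

The other scripts in `examples/` cover graph construction, neighborhood
enrichment, Ripley/co-occurrence, ligand–receptor testing and the image
workflow, each printing a few annotated numbers.

## Command line

Every analysis is also a subcommand of the `spomics` CLI, reading and
writing CSV/MTX/TIFF:

```sh
spomics simulate --spec spec.json --out sim
spomics graph --coords sim.coords.csv --type grid --n-neigh 6 --n-rings 1 --out g
spomics nhood --expr sim.expr.csv --coords sim.coords.csv --labels sim.labels.csv \
    --graph g --coord-type grid --label-key cluster --n-perms 1000 --seed 1 --out z.csv
```

Outputs carry a `#`-comment provenance header (tool version, parameters,
seed); data rows are byte-reproducible for a fixed seed.

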