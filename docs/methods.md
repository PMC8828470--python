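# Methods

This note records the statistical models implemented in `spomics`, the
conventions and defaults chosen where several reasonable options exist, what
the synthetic generators do and do not emulate, and known limitations.

## Data model and conventions

Observations (cells or spots) live in a `SpatialDataset`: an obs × gene
matrix, one (x, y) coordinate per observation in a single consistent length
unit, and categorical label vectors.  The observation order is the order of
the coordinates file; all other inputs are re-indexed to it by `obs_id`, so
misaligned files fail loudly rather than silently permuting rows.  When
relating coordinates to images, (x, y) maps to (column, row) of the pixel
array, origin top-left, 0-based.

Graphs are stored as a pair of sparse symmetric matrices — connectivity and
Euclidean distances — with structural zeros meaning "no edge".  Distances of
exactly zero cannot be represented (they would be indistinguishable from
absent edges), so duplicate coordinates in a kNN graph get machine-epsilon
distances and a warning.

## Spatial graphs

* **Grid graphs** (`grid_graph`): the lattice pitch is inferred as the modal
  nearest-neighbor distance; ring-1 neighbors are all points at that pitch
  within a 10 % tolerance, and higher ring ordinals are hop distances on the
  ring-1 graph (breadth-first expansion).  BFS rather than distance
  thresholds makes ring 2+ assignment robust to mild lattice distortion.
  Hexagonal lattices have 6 first-ring neighbors, square lattices 4.
  Inputs where more than 5 % of points lack a pitch-distance neighbor are
  rejected with a pointer to the generic constructors.
* **kNN** (`knn_graph`): the directed k-nearest relation is symmetrized by
  union, guaranteeing minimum degree k; distance ties break toward the lower
  observation index (stable argsort), making results order-deterministic.
* **Radius** (`radius_graph`): edge iff 0 < d ≤ r.  Monotone in r by
  construction.
* **Delaunay** (`delaunay_graph`): triangulation edges (scipy/Qhull).
* **Transforms**: spectral `D^{-1/2} A D^{-1/2}` (isolated nodes keep zero
  rows); cosine similarity of adjacency rows restricted to the original
  sparsity pattern, diagonal dropped.

## Neighborhood enrichment

The pair statistic x_ij counts undirected edges with one endpoint in cluster
i and one in j; within-cluster edges count once.  The null holds the graph
fixed and permutes labels uniformly (default 1000 permutations, caller-
supplied seed, bit-reproducible), giving Z_ij = (x_ij − μ_ij)/σ_ij.  When
σ_ij = 0 (e.g. a single label level) the z-score is defined as 0 and the
pair is listed in `zero_sigma_pairs` rather than returning NaN, keeping
downstream heatmaps finite without losing the information.

The companion `interaction_matrix` deliberately uses the *ordered-pair*
convention (each undirected edge contributes to both (i,j) and (j,i), and
twice to (i,i)), so its total is always 2|E|.  The two conventions are
documented side by side in the module docstring because they differ by a
factor of 2 off-diagonal.

Calibration: on Erdős–Rényi graphs with labels independent of the graph,
the empirical z-scores are close to standard normal (checked: |mean| < 0.1,
sd within [0.8, 1.2]; ≈5 % of |Z| > 1.96).

## Group centralities

Computed on the unweighted connectivity pattern (hop distances), per
cluster S: degree |N(S)−S|/(|V|−|S|); closeness |V−S|/Σ d(S,v) with d(S,v)
the multi-source BFS distance, unreachable nodes excluded from numerator
and denominator; average clustering = mean local clustering coefficient over
members; group betweenness Σ_{u<v∉S} g_uv(S)/g_uv.  The betweenness
implementation counts shortest paths through S as g_uv − g'_uv, where g'_uv
counts same-length shortest paths in the graph with S deleted — an exact
identity, cross-checked in the tests against explicit path enumeration.
A cluster covering the whole graph has no non-members; degree and closeness
are reported as 0 with a `degenerate` flag.

## Ripley statistics

L uses the unbiased estimator K(t) = A/(n(n−1)) Σ_{i≠j} 1[d_ij < t] with A
the axis-aligned bounding-box area of *all* coordinates and no edge
correction; under complete spatial randomness L(t) ≈ t over the scales
where border effects are small (tested against a simulation envelope at
t ≤ ¼ of the window side).  G is the empirical CDF of within-cluster
nearest-neighbor distances; F the empirical CDF of distances from seeded
uniform reference points (default: as many as cluster points) to the
cluster.  The default support is 50 equal steps from 0 to half the
bounding-box diagonal, shared across clusters for comparability.

Because the window is the axis-aligned bounding box, L is exactly invariant
under translations and quarter-turn rotations and scales linearly with the
coordinates, but is not invariant under arbitrary rotations (the box, and
with it A, changes).  An edge-corrected, window-free estimator is out of
scope.

## Co-occurrence ratio

For a conditioning cluster, distance shells (d_low, d_high] are taken around
every member point and pooled (a point near two centers counts twice —
neighborhood membership, not a partition).  The ratio is the label frequency
among pooled shell points divided by the global label frequency; 1 means no
association at that range.  Default edges: 50 equal steps from the smallest
positive pairwise distance to half the maximum pairwise distance.  Empty
shells yield NaN.  A cumulative variant (growing balls instead of annuli) is
available behind a flag; annuli are the default because they localize the
signal in distance.

## Spatial autocorrelation

Moran's I and Geary's C with weights defaulting to the binary connectivity
pattern row-standardized, which puts I on the conventional [−1, 1] scale
(raw stored weights available via `row_standardize=False`).  Tests are
one-sided toward spatial clustering (large I, small C) by default, matching
the screening use case; two-sided available.

P-values: permutation (p = (1 + #as-or-more-extreme)/(1 + n_perms); the +1
avoids p = 0) or analytic via a Gaussian approximation with E[I] = −1/(n−1),
E[C] = 1.  Two analytic variance assumptions are provided: *randomization*
(moments over relabelings of the observed values, involving the sample
kurtosis — the analytic counterpart of the permutation test, and the
default) and *normality* (i.i.d. Gaussian observations).  The randomization
variance matches the empirical permutation variance to within Monte-Carlo
error; p-value agreement with the permutation test is limited by the
skewness of the exact null, about 0.01 on average (up to ~0.03 for
individual genes at n = 200).  Genes with zero variance are reported as NaN
with a flag rather than raising.  Benjamini–Hochberg correction is applied
across the evaluated (non-NaN) genes.

## Sepal score

Requires a first-ring grid graph.  Expression is normalized to total mass 1
and diffused by explicit Euler steps u ← u + D·Δu·dt, where Δu at a node is
the neighbor average minus the center value — scaled 2/3 on hexagonal grids,
unscaled on square grids — with missing neighbors at the boundary replaced
by the center value (zero flux).  This update conserves total mass exactly
(the Laplacian of a symmetric adjacency has zero column sums), verified to
1e−9 over 1000 steps.  Entropy H = −Σ û log û is tracked every iteration
and the score is t·dt at the first step with |ΔH| < ε.

Defaults dt = 0.001, D = 1, ε = 1e−5, max 30 000 iterations.  The absolute
score depends on these and on the lattice stencil scaling; the *ranking* of
genes, which is what the score is used for, is robust within stability
limits (dt below the explicit-Euler stability bound) and invariant to
positive rescaling of a gene (tested).  Genes that do not converge within
the iteration cap are flagged and carry the capped time; in ranking uses
this is conservative (the most structured genes saturate at the top).
Uniform genes converge at the first check (score ≈ dt); all-zero genes
score 0 with a flag.

## Ligand–receptor test

For interaction (L, R) and ordered cluster pair (s, r), the statistic is
(mean L over s-cells + mean R over r-cells)/2, with multi-subunit complexes
reduced per cell to the minimum (limiting subunit, the default) or the mean
of their subunits.  The null permutes cluster labels; p = (1 + #{m_perm ≥
m_obs})/(1 + n_perms), one-sided toward high joint expression.  Pairs where
either complex is expressed (> 0) in fewer than 10 % of its cluster's cells
(configurable) keep their mean but get p = NaN — significance without
expression is an artifact worth suppressing.  BH correction runs over the
tested (non-NaN) hypotheses.  The expression matrix is used exactly as
given — no internal normalization — so log-normalized input is recommended;
the permutation null makes the test invariant to the overall scale.
Interactions naming genes absent from the dataset are dropped with a
warning.  Type-I error under a label-independent simulation is ≈5 % at the
nominal 0.05 level, and identical seeds give bit-identical outputs.

## Image workflow

`ImageStore` holds named (height, width, channels) layers sharing one pixel
frame.  Grayscale conversion uses luminance weights (0.2125, 0.7154,
0.0721); Gaussian smoothing is channel-wise.  Tiled execution processes
overlapping square tiles and keeps each tile's interior; for smoothing, an
overlap of at least 4σ (the default, ⌈4σ⌉) makes tiled output equal the
whole-image result to better than 1e−6 — the whole-image run is the oracle
in the tests.

Watershed segmentation: foreground by threshold (Otsu or explicit, optional
inversion for dark-on-bright nuclei), markers = local maxima of the
Euclidean distance transform at least `min_peak_distance` apart, flooding on
the negative distance transform within the foreground.  Labels are
consecutive integers from 1; empty foreground yields all zeros with a
warning.

Per-spot features are computed from square crops of side
round(diameter × spot_scale × scale) centered at each spot (out-of-bounds
crops zero-padded and flagged; a circular mask is deliberately not applied
by default — crops are squares unless the caller masks them).  Feature sets:

* **summary**: mean, sd, quantiles (default 0.9/0.5/0.1) per channel;
* **histogram**: per-bin pixel counts (default 10 bins) per channel;
* **texture**: gray-level co-occurrence matrix at offset distance 1 and
  angles {0°, 45°, 90°, 135°}, 256 gray levels, symmetrized and normalized
  to a probability distribution *before* property computation (contrast,
  dissimilarity, homogeneity, angular second moment, correlation — the
  properties are only well-scaled on probabilities), averaged over angles.
  Float layers require an explicit quantization range; a zero-variance crop
  has correlation defined as 1 (limit convention).
* **segmentation**: objects are assigned to the spot whose crop window
  contains their centroid (unambiguous single assignment); reported are the
  object count, mean/sd of whole-object pixel areas and the pixel-weighted
  mean object intensity per channel.

Feature extraction is independent per observation, so results do not depend
on any parallel scheduling; rows follow the observation order and columns
are sorted by name for determinism.

## Synthetic data

The generators are pure functions of their spec, seed included.  Point
patterns: uniform (CSR), Thomas process (Poisson parents, Gaussian
offspring — the standard clustered alternative), and hex/square lattices.
Labels: uniform random with given proportions, or vertical strips (spatial
blocks).  Expression: truncated-Gaussian noise, optionally with genes
elevated in the left half-plane (planted spatially variable genes) or with
ligand/receptor genes elevated in designated clusters.  Blob images place
non-overlapping disks by rejection sampling and return the true centers.

What these emulate is the *geometry* of array- and imaging-based spatial
data: coordinates, labels with or without spatial structure, expression
with or without planted signal.  What they do not emulate: count noise
(expression is Gaussian, not negative binomial), segmentation artifacts,
spatial gradients in capture efficiency, realistic tissue morphology, or
multi-sample batch structure.  Passing tests therefore demonstrate
correctness of the statistics and their calibration under clean nulls and
alternatives — not robustness to every failure mode of real assays.

## Problem sizes used in the test suite

The suite and the acceptance script use deliberately small instances chosen
to make the tested properties sharp: 100-node graphs with 1000 permutations
and 50 replicates for enrichment calibration; 500-point patterns with a
200-simulation envelope for Ripley's L; n = 200 with 10⁴ permutations for
the analytic-vs-permutation comparison; a 49-node lattice with 100 seeds
for sepal ranking; 40 interactions × 1000 permutations for the
ligand–receptor type-I rate; 128×128 images across 20 seeds for watershed
recovery.  These sizes give Monte-Carlo error comfortably below the asserted
tolerances.

## Known limitations

* No edge-corrected Ripley variants or cross-K functions.
* Shortest-path centralities ignore stored edge weights (hop distances).
* Sepal's absolute scores are stencil- and dt-dependent; only rankings are
  meaningful across parameter choices.
* Images are 2-D only; no lazy/on-disk backing; no pretrained deep-learning
  segmenters (a custom callable hook exists in `process`, but no models
  ship).
* Ligand–receptor interactions come from a user-supplied CSV; no database
  retrieval.
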