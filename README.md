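# coexspot

Nested coexpression hotspots and spatial cell–cell interaction (CCI)
hotspots for spatial transcriptomics.

## The problem

Tissue is organized at many spatial scales at once: an organ region can
contain sub-regions, which contain niches, which contain single repeated
micro-structures. Segmentation methods assign every cell/spot to exactly
one region at one chosen scale, so nested or overlapping structure is
flattened. `coexspot` instead looks for **coexpression hotspots**: groups
of genes whose high-expression domains coincide spatially. Because each
gene's domain is found independently, hotspots of different gene groups
may nest, overlap, or tile the tissue freely — the scale is not chosen in
advance, and the hierarchy falls out of the containment relations.

It is aimed at anyone analyzing spot-array (Visium/Slide-seq-like) or
single-cell-resolution (MERFISH/Stereo-seq-like) spatial expression data,
in 2D or layered 3D.

## The method

1. **Single-gene hotspots.** Each gene is binarized with Otsu's threshold
   (minimizing within-class variance). The high cells are clustered with
   DBSCAN: a cell is a core point when the fraction of cells within radius
   ε of it that are high exceeds a relative `density`; clusters below
   `hotspot_min_size` are dropped. Optionally each hotspot is *closed* by
   an α-shape boundary (α chosen automatically by bisection) and every cell
   inside the boundary is absorbed.
2. **The hotspot similarity network.** For hotspots `H_i`, `H_j` the edge
   weight is the Jaccard similarity
   `S_ij = |H_i ∩ H_j| / (|H_i| + |H_j| − |H_i ∩ H_j|)`, computed from
   sparse overlap counts `O_ij = |H_i ∩ H_j|` tallied per cell inside
   spatial chunks; edges are kept where `S_ij` exceeds a threshold.
3. **Coexpression hotspots (CHs).** Leiden communities of the network with
   at least `min_genes` constituents collapse to the set of cells contained
   in > 30% of the community's hotspots. CH0 is the largest.
4. **Hierarchy and markers.** A CH whose members are ≥ 75% inside a larger
   CH becomes its child (parent = smallest such container). Hierarchical
   marker genes are enriched at p < 0.001 (two-sided Mann–Whitney U,
   Benjamini–Hochberg FDR) against every parent, sibling and child.
5. **Scores.** Per-cell spatial-coherence and unique-expression scores,
   similarity maps (within or across samples), and a greedy decomposition
   of any gene's expression into CHs via the match score
   `MS_j = |H ∩ CH_j| − |H̄ ∩ CH_j|`.
6. **CCI hotspots.** Per ligand–receptor pair, ligand is spread by a
   truncated-Gaussian diffusion kernel (secreted signaling; cutoff 100 μm,
   σ = cutoff/2) or Delaunay-contact adjacency (cell–cell contact; edges
   ≤ 20 μm), rows normalized to 1. Activity = `L′R / (K_h + L′R)` (Hill,
   `K_h` = 0.5). Cells above the (1−α) quantile of a pooled permutation
   null are active and are clustered like gene hotspots; in layered 3D
   data, per-layer hotspots are linked by a multilayer Leiden graph with
   linear-sum-assignment matching between adjacent layers.
7. **Synthetic benchmark.** A recursive-halving 5-layer hierarchy (layer k
   covers a fraction 2^(1−k) of a 64×64 grid) with zero-inflated Poisson
   counts over 2048 genes, plus assignment-based Jaccard scoring against
   ground truth, subsampling stability, and one-at-a-time parameter sweeps.

## Worked example

```python
from coexspot import (
    CoexpressionModel, SyntheticHierarchyConfig, generate_hierarchy,
    HotspotDetectionConfig, CoexpressionConfig, match_score,
)

dataset, truth = generate_hierarchy(SyntheticHierarchyConfig(seed=1))
model = CoexpressionModel(
    dataset,
    detection=HotspotDetectionConfig(
        epsilon=2.0, local_density=0.2, hotspot_min_size=40, closure=True
    ),
    coexpression=CoexpressionConfig(jaccard_threshold=0.6, seed=1),
)
results = model.fit(seed=1)
print(results.summary())
per_region, mean = match_score(results.coexpression_hotspots, truth)
print([round(j, 2) for j in per_region], round(mean, 3))
```

prints

```
   ch_id  n_cells  n_genes  n_gene_hotspots  layer  parent
0      0     4090      103              103      1     NaN
1      1     2062      103              103      2     0.0
2      2     1034      102              102      3     1.0
3      3      528      101              101      4     2.0
4      4      260      106              106      5     3.0
[1.0, 0.99, 0.99, 0.97, 0.98] 0.987
```

Five coexpression hotspots, one per planted layer, each roughly halving in
cell count and nested inside the previous one (`parent` column — a
depth-5 chain); the bracketed numbers are the Jaccard similarities between
each recovered hotspot and its matched ground-truth region.

The same pipeline is scriptable from the shell:

```sh
coexspot synth --out synth_run --seed 1
coexspot hotspots synth_run/dataset --format triplet-matrix+tables --out ch_run
coexspot score-synthetic --seed 1
```

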