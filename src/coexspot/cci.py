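"""Spatial ligand-receptor (cell-cell interaction) hotspots, in 2D and 3D.

For each ligand-receptor pair a *transport matrix* A spreads ligand from
sender cells to nearby receivers: a truncated-Gaussian diffusion kernel for
secreted signaling (cutoff 100 um, sigma = cutoff/2) or Delaunay-contact
adjacency for cell-cell contact (edges <= 20 um).  Rows are normalized to
sum to 1 as a first-order cell-size correction.  Per-cell activity combines
the transported ligand L' with receptor expression R through a Hill
function

    activity = L'R / (K_h + L'R)          (K_h default 0.5)

Cells are called *active* above a null cutoff: expression rows are permuted
across cells (same permutation for all genes, within layers for 3D data),
activity recomputed, and the cutoff set at the (1-alpha) quantile of the
pooled permuted scores.  Because the Hill function is monotone, the active
set does not depend on K_h.  Active cells are then clustered into CCI
hotspots exactly like single-gene hotspots, and for layered 3D data the
per-layer hotspots are linked through a multilayer Leiden graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial.distance import cdist

from .dataset import SpatialExpressionDataset
from .hotspots import HotspotDetectionConfig, SingleGeneHotspot, dbscan_hotspots

SECRETED = "Secreted Signaling"
CONTACT = "Cell-Cell Contact"


@dataclass(frozen=True)
class LigandReceptorPair:
    ligand: str
    receptor: str
    pathway: str = ""
    annotation: str = SECRETED

    @property
    def label(self) -> str:
        return f"{self.ligand}-{self.receptor}"


@dataclass
class TransportMatrix:
    """Row-stochastic cell x cell ligand transport."""

    A: sp.csr_matrix
    model: str  # "diffusion" | "contact"
    cutoff: float


@dataclass
class ActivityField:
    """Per-cell activity, permutation cutoff and binary activation."""

    interaction: LigandReceptorPair
    activity: np.ndarray
    cutoff_value: float = np.nan
    active: Optional[np.ndarray] = None
    K_h: float = 0.5
    n_perm: int = 0
    alpha: float = 0.05


def load_lr_database(
    path,
    ligand_col: str = "ligand",
    receptor_col: str = "receptor",
    pathway_col: str = "pathway",
    annotation_col: str = "annotation",
    genes: Optional[Sequence[str]] = None,
) -> list[LigandReceptorPair]:
    """Read a ligand-receptor table (CellChat-style schema) from CSV.

    Keeps only secreted-signaling and cell-cell-contact annotations; if a
    gene universe is given, pairs with missing genes are dropped with a
    report.
    """
    df = pd.read_csv(path)
    required = [ligand_col, receptor_col, pathway_col, annotation_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ligand-receptor table missing columns {missing}")
    if df.empty:
        warnings.warn("empty ligand-receptor database")
        return []
    keep = df[annotation_col].str.strip().str.lower().isin(
        {SECRETED.lower(), CONTACT.lower()}
    )
    df = df[keep]
    pairs = [
        LigandReceptorPair(
            ligand=str(r[ligand_col]),
            receptor=str(r[receptor_col]),
            pathway=str(r[pathway_col]),
            annotation=str(r[annotation_col]).strip().title(),
        )
        for _, r in df.iterrows()
    ]
    if genes is not None:
        gene_set = set(genes)
        analyzable = [p for p in pairs if p.ligand in gene_set and p.receptor in gene_set]
        dropped = len(pairs) - len(analyzable)
        if dropped:
            warnings.warn(f"{dropped} pair(s) dropped: ligand or receptor absent from dataset")
        pairs = analyzable
    return pairs


# ---------------------------------------------------------------------------
# transport models
# ---------------------------------------------------------------------------


def _row_normalize(A: sp.csr_matrix) -> sp.csr_matrix:
    rs = np.asarray(A.sum(axis=1)).ravel()
    inv = np.divide(1.0, rs, out=np.zeros_like(rs), where=rs > 0)
    return sp.diags(inv) @ A


def diffusion_transport(coords: np.ndarray, cutoff: float = 100.0) -> TransportMatrix:
    """Truncated-Gaussian diffusion transport (2D or 3D coordinates).

    Raw weight exp(-d^2 / (2 sigma^2)) with sigma = cutoff/2 for all pairs
    within the cutoff, the sender itself included (d = 0); rows normalized
    to sum to 1, so an isolated cell keeps all its ligand.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    pairs = tree.sparse_distance_matrix(tree, max_distance=cutoff, output_type="coo_matrix")
    sigma = cutoff / 2.0
    data = np.exp(-(pairs.data**2) / (2 * sigma**2))
    n = len(coords)
    A = sp.coo_matrix((data, (pairs.row, pairs.col)), shape=(n, n)).tocsr()
    # sparse_distance_matrix stores explicit zeros for d=0 only implicitly;
    # guarantee the self term
    A = A.tolil()
    A.setdiag(1.0)
    A = A.tocsr()
    return TransportMatrix(A=_row_normalize(A), model="diffusion", cutoff=cutoff)


def contact_transport(coords: np.ndarray, max_edge: float = 20.0) -> TransportMatrix:
    """Delaunay-contact transport: equal weights to triangulation neighbors.

    Edges longer than ``max_edge`` are removed; each cell additionally
    retains itself.  Degenerate geometry (fewer than 3 points or collinear)
    raises.
    """
    coords = np.asarray(coords, dtype=float)[:, :2]
    if len(coords) < 3:
        raise ValueError("contact transport needs at least 3 cells")
    try:
        tri = Delaunay(coords)
    except Exception as e:
        raise ValueError(f"degenerate geometry for Delaunay triangulation: {e}") from e
    n = len(coords)
    rows, cols = [], []
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = int(simplex[a]), int(simplex[b])
                if np.linalg.norm(coords[i] - coords[j]) <= max_edge:
                    rows += [i, j]
                    cols += [j, i]
    rows += list(range(n))
    cols += list(range(n))
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    A.data[:] = 1.0  # duplicate edges collapse to equal weight
    return TransportMatrix(A=_row_normalize(A), model="contact", cutoff=max_edge)


# ---------------------------------------------------------------------------
# activity and permutation significance
# ---------------------------------------------------------------------------


def _lognorm_max1(values: np.ndarray, already_log: bool) -> np.ndarray:
    v = values if already_log else np.log1p(values)
    m = v.max()
    return v / m if m > 0 else v


def _activity_from_vectors(
    L: np.ndarray, R: np.ndarray, A: sp.csr_matrix, K_h: float
) -> np.ndarray:
    # row-stochastic smoothing: cell i's exposure is the kernel-weighted
    # average of ligand within reach (uniform ligand stays uniform)
    transported = A @ L
    lr = transported * R
    return lr / (K_h + lr)


def cci_activity(
    d: SpatialExpressionDataset,
    pair: LigandReceptorPair,
    transport: TransportMatrix,
    K_h: float = 0.5,
) -> ActivityField:
    """Hill-function activity of one interaction at every cell.

    Ligand and receptor vectors are log-normalized (skipped when the
    dataset is already on the log scale) and scaled to a maximum of 1; the
    ligand is then spread through the transport matrix before entering the
    Hill function, so activity lies in [0, 1).
    """
    L = _lognorm_max1(d.gene_values(pair.ligand), d.log_transformed)
    R = _lognorm_max1(d.gene_values(pair.receptor), d.log_transformed)
    if L.max() == 0 or R.max() == 0:
        warnings.warn(f"{pair.label}: all-zero ligand or receptor; activity is zero")
        return ActivityField(interaction=pair, activity=np.zeros(d.n_cells), K_h=K_h)
    return ActivityField(
        interaction=pair,
        activity=_activity_from_vectors(L, R, transport.A, K_h),
        K_h=K_h,
    )


def permutation_cutoff(
    d: SpatialExpressionDataset,
    pair: LigandReceptorPair,
    transport: TransportMatrix,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    K_h: float = 0.5,
    layer_index: Optional[np.ndarray] = None,
) -> ActivityField:
    """Permutation-null significance cutoff and binary activation.

    Each permutation shuffles cells' expression across positions (one
    permutation applied to every gene; restricted within layers when a
    layer index is given), recomputes transported activity, and pools the
    scores over all cells and permutations.  The cutoff is the (1-alpha)
    quantile of the pool; cells strictly above it are active.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    field = cci_activity(d, pair, transport, K_h)
    L = _lognorm_max1(d.gene_values(pair.ligand), d.log_transformed)
    R = _lognorm_max1(d.gene_values(pair.receptor), d.log_transformed)
    n = d.n_cells
    pool = np.empty((n_perm, n))
    for p in range(n_perm):
        perm = np.arange(n)
        if layer_index is None:
            perm = rng.permutation(n)
        else:
            for lab in np.unique(layer_index):
                idx = np.nonzero(layer_index == lab)[0]
                perm[idx] = idx[rng.permutation(idx.size)]
        pool[p] = _activity_from_vectors(L[perm], R[perm], transport.A, K_h)
    if alpha >= 1.0:
        # degenerate significance level: nothing is called active
        cutoff = float(pool.max())
        field.active = np.zeros(n, dtype=bool)
    else:
        cutoff = float(np.quantile(pool.ravel(), 1.0 - alpha))
        field.active = field.activity > cutoff
    field.cutoff_value = cutoff
    field.n_perm = n_perm
    field.alpha = alpha
    return field


def cci_hotspots(
    d: SpatialExpressionDataset,
    field: ActivityField,
    det_cfg: HotspotDetectionConfig,
) -> list[SingleGeneHotspot]:
    """Cluster active cells into CCI hotspots (per layer for layered data).

    Reuses the density-clustering machinery of single-gene hotspots with
    the interaction label standing in for the gene.
    """
    if field.active is None:
        raise ValueError("run permutation_cutoff before extracting hotspots")
    out: list[SingleGeneHotspot] = []
    if d.layer_index is not None and np.unique(d.layer_index).size > 1:
        layers = list(np.unique(d.layer_index))
    else:
        layers = [None]
    for layer in layers:
        if layer is None:
            idx = np.nonzero(field.active)[0]
            universe = d.coords
        else:
            idx = np.nonzero(field.active & (d.layer_index == layer))[0]
            universe = d.coords[d.layer_index == layer]
        out.extend(
            dbscan_hotspots(
                d.coords[idx],
                idx,
                det_cfg,
                gene=field.interaction.label,
                source_layer=layer,
                all_points=universe,
            )
        )
    return out


# ---------------------------------------------------------------------------
# 3D linking of per-layer hotspots
# ---------------------------------------------------------------------------


def _match_adjacent(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Linear-sum-assignment matching on squared Euclidean (x, y) cost.

    With unequal sizes, min(n_a, n_b) pairs are matched and the rest left
    unmatched.
    """
    cost = cdist(coords_a, coords_b, metric="sqeuclidean")
    ra, cb = linear_sum_assignment(cost)
    return ra, cb


def link_3d_hotspots(
    d: SpatialExpressionDataset,
    per_layer_hotspots: list[SingleGeneHotspot],
    k: int = 20,
    intra_decay: float = 0.04,
    inter_base: float = 0.001,
    gamma: float = 0.02,
    seed: int = 0,
    min_size: int = 1,
) -> list[dict]:
    """Link per-layer CCI hotspots into 3D hotspots via multilayer Leiden.

    Every cell belonging to a per-layer hotspot becomes a node.  Intra-layer
    edges connect each node to its k nearest neighbors in the same layer
    with weight exp(-intra_decay * d_ij).  Cells of adjacent layers are
    matched by linear sum assignment (squared-Euclidean cost); the matched
    edge (i, j) is weighted inter_base * a^2 where a counts i's k-nearest
    neighbors whose matched partner is a k-nearest neighbor of j (rewarding
    spatially consistent matchings).  The two edge sets are optimized
    jointly by Leiden: RB modularity (resolution ``gamma``) on the
    intra-layer graph plus a CPM partition at resolution 0 on the
    inter-layer graph.  Returns one dict per 3D hotspot with the member
    cells and the layers spanned.
    """
    import igraph as ig
    import leidenalg

    if d.layer_index is None:
        raise ValueError("3D linking needs a layer index")
    nodes = sorted({c for h in per_layer_hotspots for c in h.members})
    if not nodes:
        return []
    node_of = {c: i for i, c in enumerate(nodes)}
    n = len(nodes)
    node_layer = d.layer_index[nodes]
    xy = d.coords[nodes]
    layers = sorted(np.unique(node_layer))

    intra_edges, intra_w = [], []
    knn: dict[int, set[int]] = {}
    for lab in layers:
        idx = np.nonzero(node_layer == lab)[0]
        if idx.size < 2:
            for i in idx:
                knn[int(i)] = set()
            continue
        tree = cKDTree(xy[idx])
        kk = min(k + 1, idx.size)
        _, nbrs = tree.query(xy[idx], k=kk)
        for row, i in enumerate(idx):
            neigh = {int(idx[j]) for j in np.atleast_1d(nbrs[row]) if idx[j] != i}
            knn[int(i)] = neigh
            for j in neigh:
                if i < j:
                    w = float(np.exp(-intra_decay * np.linalg.norm(xy[i] - xy[j])))
                    intra_edges.append((int(i), int(j)))
                    intra_w.append(w)

    matched: dict[int, int] = {}
    inter_edges, inter_w = [], []
    for la, lb in zip(layers[:-1], layers[1:]):
        ia = np.nonzero(node_layer == la)[0]
        ib = np.nonzero(node_layer == lb)[0]
        if ia.size == 0 or ib.size == 0:
            continue
        ra, cb = _match_adjacent(xy[ia], xy[ib])
        pair_map = {int(ia[a]): int(ib[b]) for a, b in zip(ra, cb)}
        matched.update(pair_map)
        for i, j in pair_map.items():
            a = sum(1 for q in knn[i] if matched.get(q) in knn[j])
            inter_edges.append((i, j))
            inter_w.append(inter_base * a * a)

    g_intra = ig.Graph(n=n, edges=intra_edges)
    g_inter = ig.Graph(n=n, edges=inter_edges)
    part_intra = leidenalg.RBConfigurationVertexPartition(
        g_intra, weights=intra_w or None, resolution_parameter=gamma
    )
    part_inter = leidenalg.CPMVertexPartition(
        g_inter, weights=inter_w or None, resolution_parameter=0.0, node_sizes=[0] * n
    )
    opt = leidenalg.Optimiser()
    opt.set_rng_seed(seed)
    opt.optimise_partition_multiplex([part_intra, part_inter])
    membership = np.array(part_intra.membership)
    out = []
    for com in np.unique(membership):
        cells = [nodes[i] for i in np.nonzero(membership == com)[0]]
        if len(cells) < min_size:
            continue
        out.append(
            {
                "cells": sorted(cells),
                "layers": sorted({int(d.layer_index[c]) for c in cells}),
            }
        )
    out.sort(key=lambda h: (-len(h["cells"]), h["cells"][0]))
    return out


# ---------------------------------------------------------------------------
# 3D regions
# ---------------------------------------------------------------------------


def regions_3d(
    d: SpatialExpressionDataset,
    alpha_mix: float = 0.2,
    n_pcs: int = 8,
    k: int = 20,
    space_scale: float = 0.04,
    expr_scale: float = 2.0,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Multilayer Leiden regions from spatial + expression similarity.

    Intra-layer adjacency over each cell's k nearest neighbors mixes a
    spatial kernel exp(-d_ij / space_scale) with an expression kernel
    exp(-|z_i - z_j| / expr_scale) on the ``n_pcs``-dimensional PCA
    embedding z:  A = alpha_mix * A_space + (1 - alpha_mix) * A_expr.
    Inter-layer edges come from adjacent-layer linear sum assignment under
    squared-Euclidean cost.  Returns one region label per cell.
    """
    import igraph as ig
    import leidenalg
    from sklearn.decomposition import PCA

    if d.layer_index is None:
        raise ValueError("3D regions need a layer index")
    n_pcs_eff = min(n_pcs, d.n_genes, d.n_cells)
    if n_pcs_eff < n_pcs:
        warnings.warn(f"n_pcs reduced to {n_pcs_eff} (fewer genes than requested components)")
    emb = PCA(n_components=n_pcs_eff, random_state=seed).fit_transform(d.expression)
    layers = sorted(np.unique(d.layer_index))
    n = d.n_cells
    intra_edges, intra_w = [], []
    for lab in layers:
        idx = np.nonzero(d.layer_index == lab)[0]
        if idx.size < 2:
            continue
        tree = cKDTree(d.coords[idx])
        kk = min(k + 1, idx.size)
        _, nbrs = tree.query(d.coords[idx], k=kk)
        for row, i in enumerate(idx):
            for jj in np.atleast_1d(nbrs[row]):
                j = idx[jj]
                if j == i or i > j:
                    continue
                a_space = np.exp(-np.linalg.norm(d.coords[i] - d.coords[j]) / space_scale)
                a_expr = np.exp(-np.linalg.norm(emb[i] - emb[j]) / expr_scale)
                intra_edges.append((int(i), int(j)))
                intra_w.append(alpha_mix * a_space + (1 - alpha_mix) * a_expr)
    inter_edges = []
    for la, lb in zip(layers[:-1], layers[1:]):
        ia = np.nonzero(d.layer_index == la)[0]
        ib = np.nonzero(d.layer_index == lb)[0]
        ra, cb = _match_adjacent(d.coords[ia], d.coords[ib])
        inter_edges.extend((int(ia[a]), int(ib[b])) for a, b in zip(ra, cb))
    g_intra = ig.Graph(n=n, edges=intra_edges)
    g_inter = ig.Graph(n=n, edges=inter_edges)
    part_intra = leidenalg.RBConfigurationVertexPartition(
        g_intra, weights=intra_w or None, resolution_parameter=resolution
    )
    part_inter = leidenalg.CPMVertexPartition(
        g_inter, resolution_parameter=0.0, node_sizes=[0] * n
    )
    opt = leidenalg.Optimiser()
    opt.set_rng_seed(seed)
    opt.optimise_partition_multiplex([part_intra, part_inter])
    return np.array(part_intra.membership)


def intra_space_weight(dist: float, scale: float = 0.04) -> float:
    """Spatial kernel of the 3D-region graph: exp(-d / scale)."""
    return float(np.exp(-dist / scale))


def expr_weight(delta: float, scale: float = 2.0) -> float:
    """Expression kernel of the 3D-region graph: exp(-|dz| / scale)."""
    return float(np.exp(-abs(delta) / scale))


def mix_weight(a_space: float, a_expr: float, alpha_mix: float = 0.2) -> float:
    """Intra-layer mixture alpha*A_space + (1-alpha)*A_expr."""
    return alpha_mix * a_space + (1 - alpha_mix) * a_expr
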