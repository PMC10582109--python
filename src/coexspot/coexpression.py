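"""Coexpression hotspots: the hotspot similarity network and its communities.

Single-gene hotspots that occupy near-identical regions are linked in a
similarity network: the edge weight between hotspots ``H_i`` and ``H_j`` is
their Jaccard similarity

    S_ij = |H_i ∩ H_j| / (|H_i| + |H_j| - |H_i ∩ H_j|)

retained only where it exceeds a threshold.  Only the sparse overlap counts
``O_ij = |H_i ∩ H_j|`` are needed, tallied per cell (every pair of hotspots
containing a given cell receives one overlap) inside spatial chunks so the
work parallelizes over a grid without changing the result.  Communities of
the weighted network (Leiden) are collapsed into coexpression hotspots: the
cells contained in more than a cutoff fraction (default 30%) of a
community's constituent single-gene hotspots.  Coexpression hotspots are
numbered in decreasing order of cell count (CH0 largest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .dataset import SpatialExpressionDataset
from .hotspots import HotspotDetectionConfig, SingleGeneHotspot, compute_all_gene_hotspots


@dataclass
class CoexpressionConfig:
    """Network and community parameters.

    ``jaccard_threshold`` defaults: 0.6 with hotspot closure, 0.3 for
    single-cell (sparse) hotspots.  ``membership_cutoff`` is the fraction of
    constituent hotspots a cell must exceed to join the coexpression
    hotspot.
    """

    jaccard_threshold: float = 0.6
    resolution: float = 1.0
    min_genes: int = 3
    membership_cutoff: float = 0.3
    chunk_grid: tuple[int, int] = (10, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.jaccard_threshold < 1):
            raise ValueError("jaccard_threshold must be in (0, 1)")
        if not (0 < self.membership_cutoff < 1):
            raise ValueError("membership_cutoff must be in (0, 1)")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")


@dataclass
class HotspotSimilarityNetwork:
    """Sparse symmetric Jaccard-similarity graph over single-gene hotspots."""

    n_nodes: int
    edges: dict[tuple[int, int], float] = field(default_factory=dict)

    def add_edge(self, i: int, j: int, w: float) -> None:
        if i == j:
            raise ValueError("self edges are not stored")
        a, b = (i, j) if i < j else (j, i)
        self.edges[(a, b)] = w

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class CoexpressionHotspot:
    """A community of single-gene hotspots collapsed to one region.

    ``id`` is ordinal with CH0 the largest by cell count.  ``gene_hotspots``
    keeps every constituent single-gene hotspot (a gene may contribute more
    than one); ``genes`` deduplicates their gene names.
    """

    id: int
    members: frozenset[int]
    gene_hotspots: tuple[int, ...]
    genes: frozenset[str]
    membership_cutoff: float

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# overlap counting
# ---------------------------------------------------------------------------


def _membership_matrix(hotspots: list[SingleGeneHotspot], n_cells: int) -> sp.csr_matrix:
    rows, cols = [], []
    for j, h in enumerate(hotspots):
        for c in h.members:
            rows.append(c)
            cols.append(j)
    data = np.ones(len(rows), dtype=np.int64)
    return sp.csr_matrix((data, (rows, cols)), shape=(n_cells, len(hotspots)))


def overlap_counts(
    hotspots: list[SingleGeneHotspot],
    n_cells: int,
    chunk_grid: tuple[int, int] = (10, 10),
    coords: np.ndarray | None = None,
) -> sp.csr_matrix:
    """Pairwise overlap counts ``O_ij = |H_i ∩ H_j|`` (diagonal zeroed).

    Cells are partitioned into a rectangular grid of spatial chunks; each
    chunk tallies one overlap per cell for every pair of hotspots containing
    that cell, and the per-chunk tallies are summed.  Because the chunks
    partition the cells, the result is independent of the grid.  Without
    coordinates the chunking falls back to index blocks (same result).
    """
    n_h = len(hotspots)
    M = _membership_matrix(hotspots, n_cells)
    gx, gy = chunk_grid
    if coords is not None and n_cells > 0:
        x, y = coords[:, 0], coords[:, 1]
        cx = np.minimum((gx * (x - x.min()) / max(np.ptp(x), 1e-300)).astype(int), gx - 1)
        cy = np.minimum((gy * (y - y.min()) / max(np.ptp(y), 1e-300)).astype(int), gy - 1)
        chunk_of = cx * gy + cy
    else:
        chunk_of = np.arange(n_cells) % max(gx * gy, 1)
    O = sp.csr_matrix((n_h, n_h), dtype=np.int64)
    for chunk in np.unique(chunk_of):
        sub = M[chunk_of == chunk]
        O = O + (sub.T @ sub)
    O = O.tolil()
    O.setdiag(0)
    return O.tocsr()


def jaccard_network(
    O: sp.spmatrix, sizes: np.ndarray, threshold: float
) -> HotspotSimilarityNetwork:
    """Threshold the Jaccard similarities derived from overlap counts."""
    sizes = np.asarray(sizes, dtype=float)
    net = HotspotSimilarityNetwork(n_nodes=len(sizes))
    Oc = sp.coo_matrix(O)
    for i, j, o in zip(Oc.row, Oc.col, Oc.data):
        if i >= j or o == 0:
            continue
        s = o / (sizes[i] + sizes[j] - o)
        if s > threshold:
            net.add_edge(int(i), int(j), float(s))
    return net


# ---------------------------------------------------------------------------
# community detection
# ---------------------------------------------------------------------------


def leiden_communities(
    net: HotspotSimilarityNetwork, resolution: float = 1.0, seed: int = 0
) -> list[int]:
    """Weighted Leiden partition (RB modularity) of the similarity network.

    Returns one community label per node; isolated nodes form singleton
    communities.  Deterministic for a fixed seed.
    """
    import igraph as ig
    import leidenalg

    if net.n_nodes == 0:
        return []
    g = ig.Graph(n=net.n_nodes)
    if net.edges:
        g.add_edges(list(net.edges.keys()))
        g.es["weight"] = list(net.edges.values())
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if net.edges else None,
        resolution_parameter=resolution,
        n_iterations=-1,  # iterate until no further modularity gain
        seed=seed,
    )
    return list(part.membership)


def form_coexpression_hotspots(
    partition: list[int],
    hotspots: list[SingleGeneHotspot],
    cfg: CoexpressionConfig,
) -> list[CoexpressionHotspot]:
    """Collapse qualifying communities into coexpression hotspots.

    A community qualifies with at least ``min_genes`` constituent hotspots;
    members are the cells contained in strictly more than
    ``membership_cutoff`` of the constituents.  Resulting hotspots are
    re-indexed by decreasing member count (ties by lowest constituent
    hotspot id).
    """
    groups: dict[int, list[int]] = {}
    for idx, com in enumerate(partition):
        groups.setdefault(com, []).append(idx)
    raw = []
    for com, idxs in groups.items():
        if len(idxs) < cfg.min_genes:
            continue
        counts: dict[int, int] = {}
        for hidx in idxs:
            for c in hotspots[hidx].members:
                counts[c] = counts.get(c, 0) + 1
        need = cfg.membership_cutoff * len(idxs)
        members = frozenset(c for c, k in counts.items() if k > need)
        if not members:
            continue
        raw.append((members, tuple(sorted(idxs))))
    raw.sort(key=lambda t: (-len(t[0]), t[1][0]))
    out = []
    for ch_id, (members, idxs) in enumerate(raw):
        out.append(
            CoexpressionHotspot(
                id=ch_id,
                members=members,
                gene_hotspots=idxs,
                genes=frozenset(hotspots[i].gene for i in idxs),
                membership_cutoff=cfg.membership_cutoff,
            )
        )
    return out


def run_coexpression(
    d: SpatialExpressionDataset,
    det_cfg: HotspotDetectionConfig,
    coex_cfg: CoexpressionConfig,
    hotspots: list[SingleGeneHotspot] | None = None,
) -> tuple[list[CoexpressionHotspot], list[SingleGeneHotspot], HotspotSimilarityNetwork]:
    """Full pipeline: gene hotspots -> network -> communities -> CHs.

    A cell may belong to one coexpression hotspot, several, or none.
    Precomputed ``hotspots`` may be passed to skip detection.
    """
    if hotspots is None:
        hotspots = compute_all_gene_hotspots(d, det_cfg)
    O = overlap_counts(hotspots, d.n_cells, coex_cfg.chunk_grid, coords=d.coords)
    sizes = np.array([len(h) for h in hotspots], dtype=float)
    net = jaccard_network(O, sizes, coex_cfg.jaccard_threshold)
    partition = leiden_communities(net, coex_cfg.resolution, coex_cfg.seed)
    chs = form_coexpression_hotspots(partition, hotspots, coex_cfg)
    return chs, hotspots, net
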