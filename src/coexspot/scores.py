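"""Per-cell score fields, similarity maps and hotspot decomposition.

The *spatial coherence score* counts, per cell, how many coexpression-
hotspot-constituent single-gene hotspots contain the cell (then max-
normalizes to [0, 1]); it is high where many genes share near-identical
expression regions.  The *unique expression score* restricts the count to
genes whose hotspots all sit inside a single coexpression hotspot, flagging
structures (e.g. a tertiary lymphoid structure) that occur only once in the
tissue.  *Similarity maps* ask, per cell of a (possibly different) target
sample, what fraction of a coexpression hotspot's genes are locally hot
there.  *Decomposition* greedily explains one gene's hotspots as a sum of
coexpression hotspots via the match score MS_j = |H ∩ CH_j| - |H̄ ∩ CH_j|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .coexpression import CoexpressionHotspot
from .dataset import SpatialExpressionDataset
from .hotspots import HotspotDetectionConfig, SingleGeneHotspot, compute_gene_hotspots


@dataclass
class CellScoreField:
    """A per-cell score in [0, 1] (max-normalized when any raw score > 0)."""

    score: np.ndarray
    kind: str
    raw: np.ndarray | None = None


def _normalize(raw: np.ndarray, kind: str) -> CellScoreField:
    m = raw.max() if raw.size else 0.0
    score = raw / m if m > 0 else np.zeros_like(raw, dtype=float)
    return CellScoreField(score=score, kind=kind, raw=raw.astype(float))


def _constituent_counts(
    chs: list[CoexpressionHotspot],
    all_hotspots: list[SingleGeneHotspot],
    n_cells: int,
    unique_only: bool,
) -> np.ndarray:
    in_ch: dict[int, set[int]] = {}
    for c in chs:
        for h in c.gene_hotspots:
            in_ch.setdefault(h, set()).add(c.id)
    if unique_only:
        # exclude genes with hotspots spread over more than one coexpression
        # hotspot
        gene_chs: dict[str, set[int]] = {}
        for h, cids in in_ch.items():
            gene_chs.setdefault(all_hotspots[h].gene, set()).update(cids)
        eligible = {h for h in in_ch if len(gene_chs[all_hotspots[h].gene]) == 1}
    else:
        eligible = set(in_ch)
    raw = np.zeros(n_cells)
    for h in eligible:
        for cell in all_hotspots[h].members:
            raw[cell] += 1
    return raw


def coherence_score(
    chs: list[CoexpressionHotspot],
    all_hotspots: list[SingleGeneHotspot],
    n_cells: int,
) -> CellScoreField:
    """Count of CH-constituent single-gene hotspots containing each cell."""
    if not chs:
        warnings.warn("no coexpression hotspots; coherence score is all zero")
    return _normalize(_constituent_counts(chs, all_hotspots, n_cells, False), "coherence")


def uniqueness_score(
    chs: list[CoexpressionHotspot],
    all_hotspots: list[SingleGeneHotspot],
    n_cells: int,
) -> CellScoreField:
    """Coherence restricted to genes hot in exactly one coexpression hotspot."""
    if not chs:
        warnings.warn("no coexpression hotspots; uniqueness score is all zero")
    return _normalize(_constituent_counts(chs, all_hotspots, n_cells, True), "uniqueness")


def similarity_map(
    ch: CoexpressionHotspot,
    target: SpatialExpressionDataset,
    det_cfg: HotspotDetectionConfig,
    target_hotspots: list[SingleGeneHotspot] | None = None,
) -> CellScoreField:
    """Fraction of a hotspot's genes locally hot at each target cell.

    Gene hotspots are (re)computed on the target sample, so the map works
    across samples; genes absent from the target are dropped with a
    warning.  The mean of the map over all target cells summarizes
    inter-sample similarity.
    """
    genes = sorted(ch.genes)
    present = [g for g in genes if g in target.gene_names]
    if not present:
        raise ValueError(f"none of CH{ch.id}'s genes are present in the target sample")
    if len(present) < len(genes):
        warnings.warn(f"{len(genes) - len(present)} CH gene(s) missing from target, dropped")
    if target_hotspots is not None:
        by_gene: dict[str, list[SingleGeneHotspot]] = {}
        for h in target_hotspots:
            by_gene.setdefault(h.gene, []).append(h)
    raw = np.zeros(target.n_cells)
    for g in present:
        hs = (
            by_gene.get(g, [])
            if target_hotspots is not None
            else compute_gene_hotspots(target, g, det_cfg)
        )
        covered = set()
        for h in hs:
            covered.update(h.members)
        for cell in covered:
            raw[cell] += 1
    frac = raw / len(present)
    return CellScoreField(score=frac, kind="similarity_map", raw=raw)


@dataclass
class Decomposition:
    """Greedy explanation of one gene's hotspots by coexpression hotspots."""

    gene: str
    selected: list[int] = field(default_factory=list)
    match_scores: list[int] = field(default_factory=list)
    residual: int = 0

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "selected": self.selected,
            "match_scores": self.match_scores,
            "residual": self.residual,
        }


def decompose_gene(
    gene: str,
    gene_hotspots: list[SingleGeneHotspot],
    chs: list[CoexpressionHotspot],
    n_cells: int,
) -> Decomposition:
    """Greedy match-score decomposition of a gene's hotspot union.

    With H the union of the gene's hotspots and H̄ its complement within
    the full cell universe, repeatedly select the coexpression hotspot
    maximizing MS_j = |H ∩ CH_j| - |H̄ ∩ CH_j| (ties by lowest id), remove
    its cells from H, and stop once no unselected hotspot scores positive.
    """
    H: set[int] = set()
    for h in gene_hotspots:
        if h.gene == gene:
            H.update(h.members)
    dec = Decomposition(gene=gene)
    remaining = {c.id: c for c in chs}
    while remaining:
        best_id, best_ms = None, 0
        for cid in sorted(remaining):
            c = remaining[cid]
            inter = len(H & c.members)
            ms = inter - (len(c.members) - inter)
            if ms > best_ms:
                best_id, best_ms = cid, ms
        if best_id is None:
            break
        dec.selected.append(best_id)
        dec.match_scores.append(best_ms)
        H -= remaining.pop(best_id).members
    dec.residual = len(H)
    return dec


def ch_similarity_matrix(
    chs: list[CoexpressionHotspot],
    d: SpatialExpressionDataset,
    det_cfg: HotspotDetectionConfig,
    all_hotspots: list[SingleGeneHotspot] | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Pairwise coexpression-hotspot similarity with dendrogram ordering.

    similarity(a, b) = mean over a's genes of the similarity-map value
    averaged over b's cells, symmetrized by averaging with the transpose.
    Returns the matrix (indexed by position in ``chs``) and the
    average-linkage dendrogram leaf order on 1 - similarity.
    """
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import squareform

    if len(chs) < 2:
        raise ValueError("need at least 2 coexpression hotspots")
    maps = [similarity_map(c, d, det_cfg, target_hotspots=all_hotspots).score for c in chs]
    n = len(chs)
    raw = np.zeros((n, n))
    for i, mi in enumerate(maps):
        for j, c in enumerate(chs):
            idx = np.array(sorted(c.members))
            raw[i, j] = mi[idx].mean()
    S = 0.5 * (raw + raw.T)
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    order = list(leaves_list(average(squareform(D, checks=False))))
    return S, order
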