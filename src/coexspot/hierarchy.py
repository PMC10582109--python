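"""Containment hierarchy over coexpression hotspots and marker genes.

A coexpression hotspot whose members are at least 75% contained within a
larger coexpression hotspot is a child of that hotspot; its parent is the
*smallest* such container.  Roots sit at layer 1 and each child one layer
deeper.  Hierarchical marker genes of a hotspot are the genes positively
enriched (higher mean) and significant (two-sided Mann-Whitney U,
p < 0.001) against *every* parent, sibling and child hotspot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

from .coexpression import CoexpressionHotspot
from .dataset import SpatialExpressionDataset


@dataclass
class HierarchyTree:
    """Parent map and layer depths over coexpression hotspot ids."""

    parent: dict[int, Optional[int]]
    layer: dict[int, int]
    containment_threshold: float = 0.75

    def children(self, ch_id: int) -> list[int]:
        return sorted(c for c, p in self.parent.items() if p == ch_id)

    def siblings(self, ch_id: int) -> list[int]:
        p = self.parent[ch_id]
        return sorted(c for c, q in self.parent.items() if q == p and c != ch_id)

    def roots(self) -> list[int]:
        return sorted(c for c, p in self.parent.items() if p is None)

    def depth(self) -> int:
        return max(self.layer.values(), default=0)

    def is_chain(self) -> bool:
        """True when the tree is a single root-to-leaf chain."""
        return len(self.parent) == self.depth() and len(self.roots()) == 1

    def to_dict(self) -> dict:
        return {
            "containment_threshold": self.containment_threshold,
            "parent": {str(k): v for k, v in self.parent.items()},
            "layer": {str(k): v for k, v in self.layer.items()},
        }


@dataclass
class MarkerResult:
    """One gene's marker evidence for one coexpression hotspot."""

    ch_id: int
    gene: str
    comparisons: list[str] = field(default_factory=list)
    u_statistics: list[float] = field(default_factory=list)
    raw_p: float = 1.0  # worst (largest) p over comparisons
    fdr_q: float = 1.0
    direction: int = 0  # +1 = enriched in the focal hotspot in all comparisons
    is_marker: bool = False


def build_tree(chs: list[CoexpressionHotspot], threshold: float = 0.75) -> HierarchyTree:
    """Assign each hotspot the smallest container holding >= threshold of it.

    Equal-size mutual containment is broken deterministically: the hotspot
    with the larger id becomes the child (with a warning).  Layers follow
    root distance (roots = 1).
    """
    if not chs:
        return HierarchyTree(parent={}, layer={}, containment_threshold=threshold)
    parent: dict[int, Optional[int]] = {}
    for c in chs:
        candidates = []
        for p in chs:
            if p.id == c.id:
                continue
            frac = len(c.members & p.members) / len(c.members)
            if frac < threshold:
                continue
            if len(p.members) > len(c.members):
                candidates.append(p)
            elif len(p.members) == len(c.members):
                # mutual containment possible between equal-size hotspots
                back = len(c.members & p.members) / len(p.members)
                if back >= threshold and c.id > p.id:
                    warnings.warn(
                        f"equal-size mutual containment between CH{p.id} and CH{c.id}; "
                        f"CH{c.id} made the child"
                    )
                    candidates.append(p)
        if candidates:
            best = min(candidates, key=lambda p: (len(p.members), p.id))
            parent[c.id] = best.id
        else:
            parent[c.id] = None
    layer: dict[int, int] = {}

    def depth_of(cid: int) -> int:
        if cid in layer:
            return layer[cid]
        p = parent[cid]
        layer[cid] = 1 if p is None else depth_of(p) + 1
        return layer[cid]

    for c in chs:
        depth_of(c.id)
    return HierarchyTree(parent=parent, layer=layer, containment_threshold=threshold)


# ---------------------------------------------------------------------------
# Mann-Whitney U with BH correction
# ---------------------------------------------------------------------------

_EXACT_MAX = 8  # exact enumeration when both groups are at most this size


def _exact_mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Enumerates all C(n+m, n) ways the pooled observations could have been
    split into the two groups and counts splits with a U statistic at least
    as extreme (two-sided, via distance from the mean U) as observed.
    Midranks handle ties, so the enumeration remains valid for tied data.
    """
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = float(ranks[:n].sum()) - n * (n + 1) / 2.0
    mu = n * m / 2.0
    dev_obs = abs(u_obs - mu)
    total = comb(n + m, n)
    hits = 0
    idx_all = range(n + m)
    for subset in combinations(idx_all, n):
        u = float(ranks[list(subset)].sum()) - n * (n + 1) / 2.0
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return u_obs, hits / total


def mannwhitney_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small groups, else asymptotic.

    Small groups (both sizes <= 8) use an exact enumeration valid with
    ties; larger groups use the normal approximation with tie correction.
    Returns (U of the first group, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one observation")
    if len(x) <= _EXACT_MAX and len(y) <= _EXACT_MAX:
        return _exact_mannwhitney(x, y)
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def mannwhitney_bh(
    group_a: np.ndarray, group_b: np.ndarray, gene_names: list[str]
) -> "pd.DataFrame":
    """Per-gene two-sided Mann-Whitney tests with BH correction.

    ``group_a`` and ``group_b`` are (cells x genes) expression blocks.
    Returns a DataFrame with columns gene, U, p, q, sorted as given.
    """
    import pandas as pd

    us, ps = [], []
    for g in range(group_a.shape[1]):
        u, p = mannwhitney_test(group_a[:, g], group_b[:, g])
        us.append(u)
        ps.append(p)
    qs = bh_qvalues(np.array(ps))
    return pd.DataFrame({"gene": gene_names, "U": us, "p": ps, "q": qs})


# ---------------------------------------------------------------------------
# hierarchical markers and pairwise DE
# ---------------------------------------------------------------------------


def hierarchical_markers(
    d: SpatialExpressionDataset,
    chs: list[CoexpressionHotspot],
    tree: HierarchyTree,
    p_cut: float = 0.001,
    genes: Optional[list[str]] = None,
) -> list[MarkerResult]:
    """Marker genes of each hotspot against all its tree relatives.

    For parent and sibling relatives the comparison group is the relative's
    cells minus the focal hotspot's cells; for a child (which nests inside
    the focal hotspot) the focal cells minus the child are compared against
    the child's cells.  A gene is a marker iff it is enriched (higher mean
    on the focal side) with p < ``p_cut`` in *every* comparison.  Hotspots
    with no relatives fall back to a comparison against all non-member
    cells (flagged "background").
    """
    gene_list = genes if genes is not None else d.gene_names
    gidx = np.array([d.gene_index(g) for g in gene_list])
    by_id = {c.id: c for c in chs}
    results: list[MarkerResult] = []
    for c in chs:
        # (label, focal-side cells, comparison cells)
        rel: list[tuple[str, frozenset[int], frozenset[int]]] = []
        p = tree.parent.get(c.id)
        if p is not None:
            rel.append((f"parent:CH{p}", c.members, by_id[p].members - c.members))
        for s in tree.siblings(c.id):
            rel.append((f"sibling:CH{s}", c.members, by_id[s].members - c.members))
        for k in tree.children(c.id):
            # the child nests inside the focal hotspot: compare the focal
            # cells outside the child against the child itself
            rel.append((f"child:CH{k}", c.members - by_id[k].members, by_id[k].members))
        if not rel:
            rel.append(("background", c.members, frozenset(range(d.n_cells)) - c.members))
        per_gene = [MarkerResult(ch_id=c.id, gene=g, direction=1, is_marker=True) for g in gene_list]
        for name, focal_side, other in rel:
            focal_idx = np.array(sorted(focal_side))
            comp = np.array(sorted(other))
            if comp.size == 0 or focal_idx.size == 0:
                warnings.warn(f"CH{c.id} vs {name}: comparison group empty, skipped")
                continue
            A = d.expression[np.ix_(focal_idx, gidx)]
            B = d.expression[np.ix_(comp, gidx)]
            table = mannwhitney_bh(A, B, gene_list)
            enriched = A.mean(axis=0) > B.mean(axis=0)
            for r, (u, pv, q, en) in zip(
                per_gene, zip(table["U"], table["p"], table["q"], enriched)
            ):
                r.comparisons.append(name)
                r.u_statistics.append(float(u))
                r.raw_p = max(r.raw_p if r.comparisons[:-1] else 0.0, float(pv))
                r.fdr_q = max(r.fdr_q if r.comparisons[:-1] else 0.0, float(q))
                if not en:
                    r.direction = 0
                if not (en and pv < p_cut):
                    r.is_marker = False
        for r in per_gene:
            if not r.comparisons:
                r.is_marker = False
        results.extend(per_gene)
    return results


def pairwise_de(
    d: SpatialExpressionDataset,
    ch_a: CoexpressionHotspot,
    ch_b: CoexpressionHotspot,
    genes: Optional[list[str]] = None,
) -> "pd.DataFrame":
    """Differential expression between two hotspots, overlap excluded.

    Cells in both hotspots are removed from both sides; the log-fold-change
    is the difference of group means on the (log-scale) expression, positive
    toward ``ch_a``.  Rows are sorted by ascending p then descending |lfc|.
    """
    only_a = np.array(sorted(ch_a.members - ch_b.members))
    only_b = np.array(sorted(ch_b.members - ch_a.members))
    if only_a.size == 0 or only_b.size == 0:
        raise ValueError(
            f"overlap exclusion empties CH{ch_a.id if only_a.size == 0 else ch_b.id}: "
            f"CH{ch_a.id} vs CH{ch_b.id} are not separable"
        )
    gene_list = genes if genes is not None else d.gene_names
    gidx = np.array([d.gene_index(g) for g in gene_list])
    A = d.expression[np.ix_(only_a, gidx)]
    B = d.expression[np.ix_(only_b, gidx)]
    table = mannwhitney_bh(A, B, gene_list)
    table["lfc"] = A.mean(axis=0) - B.mean(axis=0)
    return table.sort_values(["p", "lfc"], ascending=[True, False], key=None).reset_index(
        drop=True
    )
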