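"""Single-gene spatial hotspots.

A single-gene hotspot is a spatially dense, connected set of cells in which
one gene is highly expressed.  Detection proceeds per gene:

1. binarize expression with Otsu's threshold (minimizing within-class
   variance over candidate thresholds between distinct observed values);
2. cluster the high-expression cells with DBSCAN, with ``min_samples``
   derived from a relative local-density parameter;
3. optionally *close* each hotspot by drawing an alpha-shape boundary around
   its members and absorbing every dataset cell inside the boundary;
4. discard clusters below a minimum size.

The per-gene computation doubles as a spatially-variable-gene filter: a gene
with no sufficiently localized high-expression region yields no hotspots and
drops out of all downstream analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, cKDTree

from .dataset import SpatialExpressionDataset


class ConstantGeneError(ValueError):
    """Otsu thresholding is undefined for a constant vector."""


@dataclass(frozen=True)
class SingleGeneHotspot:
    """One gene's spatially dense high-expression cell set.

    ``members`` are integer cell indices into the parent dataset.
    """

    gene: str
    members: frozenset[int]
    closed: bool = False
    source_layer: Optional[int] = None

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class HotspotDetectionConfig:
    """Detection parameters.

    Parameters
    ----------
    epsilon
        DBSCAN connectivity radius in coordinate units (um).
    local_density
        Fraction in (0, 1]: ``min_samples`` is this fraction of the mean
        number of epsilon-neighbors over the high-expression points
        (recommended 0.5 for multi-cell resolution, 0.2 for single-cell).
    hotspot_min_size
        Minimum cluster size to keep.
    closure
        Apply alpha-shape closure to each hotspot (recommended for
        multi-cell resolution spot arrays; expensive at single-cell scale).
    """

    epsilon: float
    local_density: float = 0.5
    hotspot_min_size: int = 10
    closure: bool = False

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0 < self.local_density <= 1):
            raise ValueError("local_density must be in (0, 1]")
        if self.hotspot_min_size < 1:
            raise ValueError("hotspot_min_size must be >= 1")


# ---------------------------------------------------------------------------
# Otsu binarization
# ---------------------------------------------------------------------------


def otsu_threshold(values: np.ndarray) -> tuple[float, np.ndarray]:
    """Otsu's threshold for a 1-D vector.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted values; the chosen threshold minimizes the total within-class
    variance (sum of class-size-weighted variances).  Returns the threshold
    and the boolean high mask (strictly greater than the threshold).
    """
    v = np.asarray(values, dtype=float).ravel()
    order = np.sort(v)
    distinct = np.unique(order)
    if distinct.size < 2:
        raise ConstantGeneError("need at least 2 distinct values for Otsu thresholding")
    n = order.size
    # prefix sums over the sorted vector give O(1) class moments per split
    csum = np.cumsum(order)
    csum2 = np.cumsum(order**2)
    # split after index k (0-based): low = order[:k+1], high = order[k+1:]
    # restrict to boundaries between distinct values
    boundary = np.nonzero(np.diff(order) > 0)[0]
    n_lo = boundary + 1
    n_hi = n - n_lo
    s_lo = csum[boundary]
    s2_lo = csum2[boundary]
    s_hi = csum[-1] - s_lo
    s2_hi = csum2[-1] - s2_lo
    var_lo = s2_lo - s_lo**2 / n_lo
    var_hi = s2_hi - s_hi**2 / n_hi
    within = var_lo + var_hi  # class-size-weighted variance sum (SSE form)
    k = int(np.argmin(within))
    b = boundary[k]
    thr = 0.5 * (order[b] + order[b + 1])
    return thr, v > thr


# ---------------------------------------------------------------------------
# DBSCAN clustering of high-expression cells
# ---------------------------------------------------------------------------


def derive_min_samples(
    points: np.ndarray,
    epsilon: float,
    local_density: float,
    all_points: np.ndarray | None = None,
) -> int:
    """Absolute ``min_samples`` implementing the relative density rule.

    A cell is a core point when the fraction of cells within distance
    epsilon of it that are high-expression *exceeds* ``local_density``.
    The neighborhood size (dataset cells within epsilon, self excluded,
    averaged over the high-expression points, against ``all_points`` when
    given, else against the high points themselves) converts the fraction
    into ``min_samples`` = floor(local_density x mean count) + 1, floored
    at 2.
    """
    if len(points) == 0:
        return 2
    universe = all_points if all_points is not None else points
    tree = cKDTree(universe)
    counts = tree.query_ball_point(points, r=epsilon, return_length=True)
    if all_points is None:
        counts = counts - 1  # the point itself is in the universe
    else:
        counts = np.maximum(counts - 1, 0)
    return max(2, int(np.floor(local_density * float(np.mean(counts)))) + 1)


def _dbscan_labels(
    neighbors: list, min_samples: int
) -> np.ndarray:
    """Plain DBSCAN over precomputed epsilon-neighbor lists.

    A point is a core point when it has at least ``min_samples`` *other*
    points within epsilon.  Core points within epsilon of each other join
    one cluster; non-core (border) points attach to the first core cluster
    reaching them in scan order; the rest is noise (-1).
    """
    n = len(neighbors)
    core = np.array([len(nb) - 1 >= min_samples for nb in neighbors])
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] >= 0:
            continue
        labels[i] = cluster
        stack = [i]
        while stack:
            p = stack.pop()
            for q in neighbors[p]:
                if labels[q] >= 0:
                    continue
                if core[q]:
                    labels[q] = cluster
                    stack.append(q)
                else:
                    labels[q] = cluster  # border point, fixed scan order
        cluster += 1
    return labels


def dbscan_hotspots(
    points: np.ndarray,
    point_ids: np.ndarray,
    cfg: HotspotDetectionConfig,
    gene: str = "",
    source_layer: Optional[int] = None,
    all_points: np.ndarray | None = None,
    min_samples: int | None = None,
) -> list[SingleGeneHotspot]:
    """Density-cluster high-expression cell positions into hotspots.

    ``points`` are the (x, y) positions of the high-expression cells and
    ``point_ids`` the matching dataset cell indices.  ``min_samples`` is
    derived from the relative ``local_density`` against ``all_points`` (the
    full cell population; the high points themselves when absent) unless
    given explicitly; noise points and clusters below ``hotspot_min_size``
    are dropped.  Hotspots are returned in decreasing size order (ties by
    smallest member index).
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return []
    point_ids = np.asarray(point_ids)
    if min_samples is None:
        min_samples = derive_min_samples(points, cfg.epsilon, cfg.local_density, all_points)
    tree = cKDTree(points)
    neighbors = tree.query_ball_point(points, r=cfg.epsilon)
    labels = _dbscan_labels(neighbors, min_samples)
    out = []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        members = point_ids[labels == lab]
        if members.size < cfg.hotspot_min_size:
            continue
        out.append(
            SingleGeneHotspot(
                gene=gene, members=frozenset(int(m) for m in members), source_layer=source_layer
            )
        )
    out.sort(key=lambda h: (-len(h.members), min(h.members)))
    return out


# ---------------------------------------------------------------------------
# alpha-shape closure
# ---------------------------------------------------------------------------


def _triangle_circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area2 = np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[area2 == 0] = np.inf
    return r


def _alpha_complex_valid(keep: np.ndarray, tri: Delaunay, n_points: int) -> bool:
    """A kept-triangle set is a valid single shape if it covers every member
    point and forms one edge-connected region."""
    kept = np.nonzero(keep)[0]
    if kept.size == 0:
        return False
    if np.unique(tri.simplices[kept]).size != n_points:
        return False
    if kept.size == 1:
        return True
    # connect triangles sharing an edge (= mutual Delaunay neighbors)
    keep_lookup = np.full(len(tri.simplices) + 1, -1, dtype=int)
    keep_lookup[kept] = np.arange(kept.size)
    nbr = keep_lookup[tri.neighbors[kept].ravel()]  # -1 entries map to sentinel
    rows = np.repeat(np.arange(kept.size), 3)
    ok = nbr >= 0
    adj = coo_matrix(
        (np.ones(int(ok.sum())), (rows[ok], nbr[ok])), shape=(kept.size, kept.size)
    )
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp == 1


def close_hotspot(
    h: SingleGeneHotspot,
    d: SpatialExpressionDataset,
    max_bisect: int = 12,
) -> SingleGeneHotspot:
    """Close a hotspot with an alpha-shape boundary.

    An alpha-shape generalizes the convex hull: alpha = 0 is the hull and
    increasing alpha tightens the boundary (a triangle of the member
    triangulation survives while its circumradius <= 1/alpha) until the
    shape breaks apart or orphans a point.  A bisection search selects the
    largest alpha that still yields a single connected shape covering all
    members; every dataset cell inside that shape is absorbed into the
    hotspot.  Degenerate geometry (fewer than 3 members, collinear points)
    returns the hotspot unchanged with a warning.
    """
    members = np.array(sorted(h.members))
    if members.size < 3:
        warnings.warn(f"hotspot of gene {h.gene!r} too small to close; returned unchanged")
        return h
    pts = d.coords[members]
    try:
        tri = Delaunay(pts)
    except Exception:
        warnings.warn(f"degenerate geometry for gene {h.gene!r}; hotspot returned unchanged")
        return h
    if len(tri.simplices) == 0:
        warnings.warn(f"degenerate geometry for gene {h.gene!r}; hotspot returned unchanged")
        return h
    radii = _triangle_circumradii(pts, tri.simplices)
    n_pts = len(pts)

    def keep_mask(alpha: float) -> np.ndarray:
        if alpha == 0:
            return np.ones(len(radii), dtype=bool)
        return radii <= 1.0 / alpha

    # bisection for the largest valid alpha: lo valid (hull), hi invalid
    lo = 0.0
    finite = radii[np.isfinite(radii)]
    if finite.size == 0:
        warnings.warn(f"degenerate geometry for gene {h.gene!r}; hotspot returned unchanged")
        return h
    hi = 2.0 / float(finite.min())  # removes even the roundest triangle
    if _alpha_complex_valid(keep_mask(hi), tri, n_pts):
        lo = hi
    else:
        for _ in range(max_bisect):
            mid = 0.5 * (lo + hi)
            if _alpha_complex_valid(keep_mask(mid), tri, n_pts):
                lo = mid
            else:
                hi = mid
    keep = _fill_holes(keep_mask(lo), tri)
    # membership query: locate every dataset cell in the triangulation and
    # accept it if its containing triangle lies within the boundary
    simplex = tri.find_simplex(d.coords)
    inside = (simplex >= 0) & keep[np.clip(simplex, 0, None)]
    new_members = frozenset(int(i) for i in np.nonzero(inside)[0]) | h.members
    return replace(h, members=new_members, closed=True)


def _fill_holes(keep: np.ndarray, tri: Delaunay) -> np.ndarray:
    """Absorb interior holes of the alpha complex.

    The closed hotspot is everything within the *boundary* of the kept
    triangles, so removed triangles that are not edge-connected to the
    outside of the convex hull are holes and get kept after all.
    """
    dropped = np.nonzero(~keep)[0]
    if dropped.size == 0:
        return keep
    n_drop = dropped.size
    lookup = np.full(len(tri.simplices) + 1, -1, dtype=int)
    lookup[dropped] = np.arange(n_drop)
    outside = n_drop  # virtual node for the hull exterior
    rows, cols = [], []
    for local_i, t in enumerate(dropped):
        for nb in tri.neighbors[t]:
            if nb == -1:
                rows.append(local_i)
                cols.append(outside)
            elif lookup[nb] >= 0:
                rows.append(local_i)
                cols.append(lookup[nb])
    adj = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_drop + 1, n_drop + 1)
    )
    _, comp = connected_components(adj, directed=False)
    hole = comp[:n_drop] != comp[outside]
    out = keep.copy()
    out[dropped[hole]] = True
    return out


# ---------------------------------------------------------------------------
# full per-gene sweep
# ---------------------------------------------------------------------------


def _layer_neighbor_counts(
    d: SpatialExpressionDataset, cfg: HotspotDetectionConfig, layer: Optional[int]
) -> tuple[np.ndarray, np.ndarray]:
    """(cell indices of the layer, per-cell count of other cells within
    epsilon) — the denominator of the relative density rule."""
    if layer is None:
        cell_idx = np.arange(d.n_cells)
    else:
        cell_idx = np.nonzero(d.layer_index == layer)[0]
    pts = d.coords[cell_idx]
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=cfg.epsilon, return_length=True) - 1
    return cell_idx, counts


def compute_gene_hotspots(
    d: SpatialExpressionDataset,
    gene: str,
    cfg: HotspotDetectionConfig,
    layer: Optional[int] = None,
    _layer_cache: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[SingleGeneHotspot]:
    """Hotspots of one gene (optionally restricted to one layer)."""
    cell_idx, nbr_counts = (
        _layer_cache if _layer_cache is not None else _layer_neighbor_counts(d, cfg, layer)
    )
    values = d.gene_values(gene)[cell_idx]
    try:
        _, mask = otsu_threshold(values)
    except ConstantGeneError:
        return []
    high = cell_idx[mask]
    if high.size < cfg.hotspot_min_size:
        return []
    min_samples = max(
        2, int(np.floor(cfg.local_density * float(nbr_counts[mask].mean()))) + 1
    )
    hs = dbscan_hotspots(
        d.coords[high], high, cfg, gene=gene, source_layer=layer, min_samples=min_samples
    )
    if cfg.closure:
        hs = [close_hotspot(h, d) for h in hs]
    return hs


def compute_all_gene_hotspots(
    d: SpatialExpressionDataset, cfg: HotspotDetectionConfig
) -> list[SingleGeneHotspot]:
    """Hotspots of every gene; for layered 3D data, computed per layer.

    Genes that are constant (Otsu undefined) or produce no cluster above the
    size threshold contribute nothing.
    """
    layers: list[Optional[int]]
    if d.layer_index is not None and np.unique(d.layer_index).size > 1:
        layers = list(np.unique(d.layer_index))
    else:
        layers = [None]
    out: list[SingleGeneHotspot] = []
    for layer in layers:
        cache = _layer_neighbor_counts(d, cfg, layer)
        for gene in d.gene_names:
            out.extend(compute_gene_hotspots(d, gene, cfg, layer=layer, _layer_cache=cache))
    return out


def hotspot_table(hotspots: list[SingleGeneHotspot], d: SpatialExpressionDataset):
    """Flat (hotspot_id, gene, cell_id) table for export."""
    import pandas as pd

    rows = []
    for hid, h in enumerate(hotspots):
        for m in sorted(h.members):
            rows.append((hid, h.gene, d.cell_ids[m]))
    return pd.DataFrame(rows, columns=["hotspot_id", "gene", "cell_id"])
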