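"""Synthetic nested-hierarchy generator and ground-truth scoring.

The generator plants a recursive-halving hierarchy on a regular grid of
cells: layer 1 covers the whole domain, layer 2 half of it, layer 3 half of
layer 2, and so on (the split axis alternating so the regions stay
compact).  A chosen number of *spatial genes* is divided evenly over the
layers; a spatial gene draws zero-inflated Poisson counts at rate
``lambda_in`` inside its region and ``lambda_out`` outside, while
non-spatial genes draw at ``lambda_out`` everywhere.  The dataset is then
normalized and log-transformed, mirroring standard preprocessing.

Scoring matches recovered coexpression hotspots one-to-one against the
ground-truth regions by linear sum assignment maximizing Jaccard
similarity; unmatched entries on either side contribute zeros to the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .coexpression import CoexpressionConfig, CoexpressionHotspot, run_coexpression
from .dataset import PreprocessingConfig, SpatialExpressionDataset, preprocess
from .hotspots import HotspotDetectionConfig


@dataclass
class SyntheticHierarchyConfig:
    """Study conditions of the synthetic benchmark.

    Defaults: a 5-layer hierarchy on a 64 x 64 grid (spacing 1 um) with
    2048 genes of which 512 carry spatial signal, zero-inflation pi = 0.5,
    Poisson rates 3 inside / 0.3 outside.
    """

    n_layers: int = 5
    n_genes: int = 2048
    n_spatial_genes: int = 512
    grid_side: int = 64
    zip_pi: float = 0.5
    lambda_in: float = 3.0
    lambda_out: float = 0.3
    seed: int = 0
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.n_spatial_genes > self.n_genes:
            raise ValueError("n_spatial_genes cannot exceed n_genes")
        if not (self.lambda_in > self.lambda_out >= 0):
            raise ValueError("need lambda_in > lambda_out >= 0")
        if not (0 <= self.zip_pi < 1):
            raise ValueError("zip_pi must be in [0, 1)")


@dataclass
class GroundTruth:
    """Nested cell-index sets; region k covers fraction 2**(1-k) of cells."""

    regions: list[frozenset[int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)


def default_detection_config(cfg: SyntheticHierarchyConfig) -> HotspotDetectionConfig:
    """Pipeline defaults for the grid benchmark (spot-array conventions):
    epsilon twice the grid spacing, density 0.2, closure on."""
    return HotspotDetectionConfig(
        epsilon=2.0, local_density=0.2, hotspot_min_size=40, closure=True
    )


def default_coexpression_config(seed: int = 0) -> CoexpressionConfig:
    return CoexpressionConfig(
        jaccard_threshold=0.6, resolution=1.0, min_genes=3, membership_cutoff=0.3, seed=seed
    )


def _nested_regions(grid_side: int, n_layers: int) -> list[np.ndarray]:
    """Boolean masks of the recursive halving, alternating split axis."""
    xs, ys = np.meshgrid(np.arange(grid_side), np.arange(grid_side), indexing="ij")
    x = xs.ravel()
    y = ys.ravel()
    masks = [np.ones(grid_side * grid_side, dtype=bool)]
    xlo, ylo = 0, 0
    x_extent, y_extent = grid_side, grid_side
    for k in range(1, n_layers):
        if k % 2 == 1:  # halve along x: keep the right half
            x_extent //= 2
            xlo = grid_side - x_extent
        else:  # halve along y: keep the top half
            y_extent //= 2
            ylo = grid_side - y_extent
        masks.append((x >= xlo) & (y >= ylo))
    return masks


def generate_hierarchy(
    cfg: SyntheticHierarchyConfig,
) -> tuple[SpatialExpressionDataset, GroundTruth]:
    """Generate the nested synthetic dataset and its ground truth.

    Counts are ZIP(pi, lambda): zero with probability pi, else Poisson.
    The returned dataset is normalized (median per-cell total) and
    log1p-transformed; raw counts remain available via the preprocessing
    record.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    side = cfg.grid_side
    n_cells = side * side
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    masks = _nested_regions(side, cfg.n_layers)

    # even division of spatial genes over layers (remainder to the shallow
    # layers first)
    base = cfg.n_spatial_genes // cfg.n_layers
    extra = cfg.n_spatial_genes % cfg.n_layers
    per_layer = [base + (1 if k < extra else 0) for k in range(cfg.n_layers)]

    X = np.empty((n_cells, cfg.n_genes))
    gene_names, gene_layer = [], []
    g = 0
    for k, count in enumerate(per_layer):
        lam = np.where(masks[k], cfg.lambda_in, cfg.lambda_out)
        for _ in range(count):
            counts = rng.poisson(lam)
            counts[rng.random(n_cells) < cfg.zip_pi] = 0
            X[:, g] = counts
            gene_names.append(f"spatial_L{k + 1}_{g}")
            gene_layer.append(k + 1)
            g += 1
    while g < cfg.n_genes:
        counts = rng.poisson(cfg.lambda_out, size=n_cells)
        counts[rng.random(n_cells) < cfg.zip_pi] = 0
        X[:, g] = counts
        gene_names.append(f"noise_{g}")
        gene_layer.append(0)
        g += 1

    d = SpatialExpressionDataset(
        expression=X,
        coords=coords,
        gene_names=gene_names,
        cell_ids=[f"cell{i}" for i in range(n_cells)],
    )
    d = preprocess(d, PreprocessingConfig(do_normalize=cfg.normalize, do_log=True))
    truth = GroundTruth(
        regions=[frozenset(int(i) for i in np.nonzero(m)[0]) for m in masks]
    )
    return d, truth


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _jaccard(a: frozenset[int], b: frozenset[int]) -> float:
    if not a and not b:
        return 0.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def match_score(
    found: list[CoexpressionHotspot], truth: GroundTruth
) -> tuple[list[float], float]:
    """One-to-one LSA matching of found hotspots to truth regions.

    Returns the per-truth-region Jaccard of the optimal assignment and the
    mean over all matched pairs plus zero-scored unmatched entries on
    either side.
    """
    n_f, n_t = len(found), len(truth.regions)
    if n_f == 0:
        return [0.0] * n_t, 0.0
    J = np.zeros((n_f, n_t))
    for i, f in enumerate(found):
        for j, t in enumerate(truth.regions):
            J[i, j] = _jaccard(f.members, t)
    ri, cj = linear_sum_assignment(-J)
    per_region = [0.0] * n_t
    for i, j in zip(ri, cj):
        per_region[j] = J[i, j]
    n_entries = max(n_f, n_t)  # matched pairs + unmatched on the larger side
    mean = float(sum(J[i, j] for i, j in zip(ri, cj)) / n_entries)
    return per_region, mean


def run_default_pipeline(
    d: SpatialExpressionDataset,
    det_cfg: HotspotDetectionConfig | None = None,
    coex_cfg: CoexpressionConfig | None = None,
    seed: int = 0,
):
    det = det_cfg or HotspotDetectionConfig(
        epsilon=2.0, local_density=0.2, hotspot_min_size=40, closure=True
    )
    coex = coex_cfg or default_coexpression_config(seed=seed)
    return run_coexpression(d, det, coex)


def subsample_stability(
    d: SpatialExpressionDataset,
    chs: list[CoexpressionHotspot],
    det_cfg: HotspotDetectionConfig,
    coex_cfg: CoexpressionConfig,
    fractions=(0.8,),
    n_reps: int = 10,
    seed: int = 0,
) -> dict[float, list[float]]:
    """Best-match Jaccard of each hotspot under random gene subsets.

    For each fraction, the coexpression pipeline is re-run ``n_reps`` times
    on independent random gene subsets; each original hotspot scores the
    Jaccard with its best-match subsampled hotspot, averaged over reps.
    """
    rng = np.random.default_rng(seed)
    out: dict[float, list[float]] = {}
    for frac in fractions:
        scores = np.zeros((n_reps, len(chs)))
        for rep in range(n_reps):
            n_keep = max(1, int(round(frac * d.n_genes)))
            keep = sorted(rng.choice(d.n_genes, size=n_keep, replace=False))
            sub = replace(
                d,
                expression=d.expression[:, keep],
                gene_names=[d.gene_names[i] for i in keep],
            )
            sub_chs, _, _ = run_coexpression(sub, det_cfg, coex_cfg)
            for i, c in enumerate(chs):
                best = max((_jaccard(c.members, s.members) for s in sub_chs), default=0.0)
                scores[rep, i] = best
        out[frac] = list(scores.mean(axis=0))
    return out


def parameter_sweep(
    cfg: SyntheticHierarchyConfig,
    sweep: dict[str, list[float]],
    n_reps: int = 10,
    seed: int = 0,
) -> "pd.DataFrame":
    """One-at-a-time parameter sweep of mean matched Jaccard.

    ``sweep`` maps parameter names (epsilon, density, jaccard_threshold,
    resolution) to value lists; each point is evaluated on ``n_reps``
    independently generated datasets.  Returns a tidy table with one row
    per (parameter, value, replicate).
    """
    import pandas as pd

    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(4096))
    for param, values in sweep.items():
        for value in values:
            for rep in range(n_reps):
                ds_seed = int(next(child_seeds))
                data, truth = generate_hierarchy(replace(cfg, seed=ds_seed))
                det = HotspotDetectionConfig(
                    epsilon=2.0, local_density=0.2, hotspot_min_size=40, closure=True
                )
                coex = default_coexpression_config(seed=ds_seed)
                if param == "epsilon":
                    det.epsilon = float(value)
                elif param == "density":
                    det.local_density = float(value)
                elif param == "jaccard_threshold":
                    coex.jaccard_threshold = float(value)
                elif param == "resolution":
                    coex.resolution = float(value)
                else:
                    raise ValueError(f"unknown sweep parameter {param!r}")
                chs, _, _ = run_coexpression(data, det, coex)
                _, mean = match_score(chs, truth)
                rows.append((param, value, rep, mean))
    return pd.DataFrame(rows, columns=["parameter", "value", "replicate", "mean_jaccard"])


def minimum_spatial_genes(
    cfg: SyntheticHierarchyConfig,
    counts=(8, 16, 32, 64, 128, 256, 512, 1024),
    n_reps: int = 10,
    criterion: float = 0.75,
    seed: int = 0,
    stop_at_first_pass: bool = True,
) -> tuple[int | None, "pd.DataFrame"]:
    """Smallest spatial-gene count whose mean matched Jaccard exceeds the
    good-match criterion, sweeping a doubling grid in ascending order."""
    import pandas as pd

    ss = np.random.SeedSequence(seed)
    child = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(len(counts) * n_reps))
    rows = []
    found = None
    for count in counts:
        means = []
        for rep in range(n_reps):
            ds_seed = int(next(child))
            data, truth = generate_hierarchy(
                replace(cfg, n_spatial_genes=int(count), seed=ds_seed)
            )
            chs, _, _ = run_default_pipeline(data, seed=ds_seed)
            _, mean = match_score(chs, truth)
            means.append(mean)
            rows.append((count, rep, mean))
        if np.mean(means) > criterion and found is None:
            found = int(count)
            if stop_at_first_pass:
                break
    table = pd.DataFrame(rows, columns=["n_spatial_genes", "replicate", "mean_jaccard"])
    return found, table
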