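"""Spatial expression dataset container, readers/writers, and preprocessing.

The central object is :class:`SpatialExpressionDataset`: a cells x genes
expression matrix together with 2D (optionally 3D/layered) spatial
coordinates in physical units and optional per-cell annotations.  All
downstream analysis (single-gene hotspots, coexpression hotspots, the
hierarchy, CCI) consumes this container.

Readers cover the three common plain interchange dialects: matrix-market
triplets plus label tables, dense delimited text, and the AnnData ``.h5ad``
container (coordinates under ``obsm['spatial']``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.spatial import cKDTree


class DatasetValidationError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class PreprocessingConfig:
    """Preprocessing switches.

    Parameters
    ----------
    do_normalize
        Per-cell total-count normalization to the median per-cell total.
    do_log
        log(1 + x) transform after normalization.
    smoothing_radius
        If set, spatial quantile smoothing radius in the same units as the
        coordinates (applied after the log transform).
    smoothing_quantiles
        The two quantiles averaged by the smoother; default (0.20, 0.80).
    """

    do_normalize: bool = True
    do_log: bool = True
    smoothing_radius: Optional[float] = None
    smoothing_quantiles: tuple[float, float] = (0.20, 0.80)

    def __post_init__(self) -> None:
        lo, hi = self.smoothing_quantiles
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("smoothing_quantiles must satisfy 0 <= lo <= hi <= 1")


@dataclass
class SpatialExpressionDataset:
    """Cells x genes expression with spatial coordinates.

    Attributes
    ----------
    expression
        (n_cells, n_genes) dense float array, non-negative.
    coords
        (n_cells, 2) array of (x, y) positions in physical units (um).
    gene_names, cell_ids
        Unique identifiers for columns and rows.
    z
        Optional per-cell z coordinate (um) for 3D data.
    layer_index
        Optional per-cell integer slice label; all cells of one layer must
        share one z value.
    annotations
        Optional per-cell categorical metadata (cell type, sample, ...).
    """

    expression: np.ndarray
    coords: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    z: Optional[np.ndarray] = None
    layer_index: Optional[np.ndarray] = None
    annotations: Optional[pd.DataFrame] = None
    units_hint: str = "um"
    log_transformed: bool = False
    _raw: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if sp.issparse(self.expression):  # pragma: no cover - defensive
            self.expression = self.expression.toarray()
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise DatasetValidationError("coords must be an (n_cells, 2) array")
        n, g = self.expression.shape
        if self.coords.shape[0] != n:
            raise DatasetValidationError(
                f"coordinate rows ({self.coords.shape[0]}) != expression rows ({n})"
            )
        if len(self.gene_names) != g:
            raise DatasetValidationError("gene_names length mismatch")
        if len(self.cell_ids) != n:
            raise DatasetValidationError("cell_ids length mismatch")
        if len(set(self.gene_names)) != g:
            raise DatasetValidationError("duplicate gene names")
        if len(set(self.cell_ids)) != n:
            raise DatasetValidationError("duplicate cell ids")
        if not np.all(np.isfinite(self.expression)):
            raise DatasetValidationError("expression contains non-finite values")
        if self.expression.min(initial=0.0) < 0:
            raise DatasetValidationError("expression contains negative values")
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
            if self.z.shape != (n,):
                raise DatasetValidationError("z must have one value per cell")
        if self.layer_index is not None:
            self.layer_index = np.asarray(self.layer_index, dtype=int)
            if self.layer_index.shape != (n,):
                raise DatasetValidationError("layer_index must have one value per cell")
            if self.z is not None:
                for lab in np.unique(self.layer_index):
                    if np.unique(self.z[self.layer_index == lab]).size != 1:
                        raise DatasetValidationError(
                            f"cells of layer {lab} do not share one z value"
                        )

    # -- basic introspection ------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.expression[:, self.gene_index(gene)]

    def zero_genes(self) -> list[str]:
        """Genes with zero total expression (retained but flagged)."""
        totals = self.expression.sum(axis=0)
        return [g for g, t in zip(self.gene_names, totals) if t == 0]

    def coords3d(self) -> np.ndarray:
        """(n, 3) coordinates; z filled with 0 when absent."""
        zcol = self.z if self.z is not None else np.zeros(self.n_cells)
        return np.column_stack([self.coords, zcol])

    # -- conversion ---------------------------------------------------------

    def to_anndata(self):
        import anndata

        obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        if self.layer_index is not None:
            obs["layer_index"] = self.layer_index
        if self.annotations is not None:
            for c in self.annotations.columns:
                obs[c] = np.asarray(self.annotations[c])
        adata = anndata.AnnData(
            X=self.expression.copy(),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        spatial = self.coords if self.z is None else self.coords3d()
        adata.obsm["spatial"] = spatial.copy()
        adata.uns["units_hint"] = self.units_hint
        adata.uns["log_transformed"] = self.log_transformed
        return adata

    @classmethod
    def from_anndata(cls, adata, spatial_key: str = "spatial") -> "SpatialExpressionDataset":
        X = adata.X
        if sp.issparse(X):
            X = X.toarray()
        spatial = np.asarray(adata.obsm[spatial_key], dtype=float)
        z = spatial[:, 2] if spatial.shape[1] >= 3 else None
        layer = None
        ann_cols = [c for c in adata.obs.columns if c != "layer_index"]
        if "layer_index" in adata.obs.columns:
            layer = np.asarray(adata.obs["layer_index"], dtype=int)
        annotations = adata.obs[ann_cols].copy() if ann_cols else None
        if annotations is not None:
            annotations.index = pd.RangeIndex(len(annotations))
        return cls(
            expression=np.asarray(X, dtype=float),
            coords=spatial[:, :2],
            gene_names=[str(g) for g in adata.var_names],
            cell_ids=[str(c) for c in adata.obs_names],
            z=z,
            layer_index=layer,
            annotations=annotations,
            units_hint=str(adata.uns.get("units_hint", "um")),
            log_transformed=bool(adata.uns.get("log_transformed", False)),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def load_dataset(
    path,
    format: str,
    coord_columns: Sequence[str] = ("x", "y", "z"),
    layer_column: str = "layer_index",
) -> SpatialExpressionDataset:
    """Load a dataset from one of the supported on-disk dialects.

    Parameters
    ----------
    path
        For ``"triplet-matrix+tables"``: directory containing ``matrix.mtx``
        (cells x genes triplets), ``genes.tsv``, ``cells.tsv`` and
        ``coords.csv``.  For ``"delimited-table"``: a CSV whose non-coordinate
        columns are genes, with a ``cell_id`` column.  For
        ``"hdf5-container"``: an ``.h5ad`` file.
    format
        One of ``triplet-matrix+tables``, ``delimited-table``,
        ``hdf5-container``.
    """
    path = Path(path)
    xc, yc, zc = (list(coord_columns) + ["z"])[:3]
    if format == "hdf5-container":
        import anndata

        return SpatialExpressionDataset.from_anndata(anndata.read_h5ad(path))
    if format == "triplet-matrix+tables":
        mat = scipy.io.mmread(path / "matrix.mtx")
        X = np.asarray(sp.coo_matrix(mat).todense(), dtype=float)
        genes = pd.read_csv(path / "genes.tsv", header=None, sep="\t")[0].astype(str).tolist()
        cells = pd.read_csv(path / "cells.tsv", header=None, sep="\t")[0].astype(str).tolist()
        cdf = pd.read_csv(path / "coords.csv")
        return _assemble(X, genes, cells, cdf, xc, yc, zc, layer_column)
    if format == "delimited-table":
        df = pd.read_csv(path)
        meta_cols = [c for c in (["cell_id", xc, yc, zc, layer_column]) if c in df.columns]
        genes = [c for c in df.columns if c not in meta_cols]
        cells = df["cell_id"].astype(str).tolist() if "cell_id" in df else [
            f"cell{i}" for i in range(len(df))
        ]
        X = df[genes].to_numpy(dtype=float)
        return _assemble(X, genes, cells, df, xc, yc, zc, layer_column)
    raise ValueError(f"unknown format {format!r}")


def _assemble(X, genes, cells, cdf, xc, yc, zc, layer_column):
    if xc not in cdf.columns or yc not in cdf.columns:
        raise DatasetValidationError(
            f"coordinate columns {xc!r},{yc!r} not found in {list(cdf.columns)}"
        )
    if len(cdf) != X.shape[0]:
        raise DatasetValidationError(
            f"coordinate rows ({len(cdf)}) != expression rows ({X.shape[0]})"
        )
    z = cdf[zc].to_numpy(dtype=float) if zc in cdf.columns else None
    layer = cdf[layer_column].to_numpy(dtype=int) if layer_column in cdf.columns else None
    ds = SpatialExpressionDataset(
        expression=X,
        coords=cdf[[xc, yc]].to_numpy(dtype=float),
        gene_names=genes,
        cell_ids=cells,
        z=z,
        layer_index=layer,
    )
    dead = ds.zero_genes()
    if dead:
        warnings.warn(f"{len(dead)} gene(s) with zero total expression retained")
    return ds


def write_dataset(d: SpatialExpressionDataset, path, format: str = "hdf5-container") -> None:
    """Write a dataset; inverse of :func:`load_dataset` for each dialect."""
    path = Path(path)
    if format == "hdf5-container":
        d.to_anndata().write_h5ad(path)
        return
    if format == "triplet-matrix+tables":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(d.expression))
        pd.Series(d.gene_names).to_csv(path / "genes.tsv", index=False, header=False)
        pd.Series(d.cell_ids).to_csv(path / "cells.tsv", index=False, header=False)
        cdf = pd.DataFrame({"x": d.coords[:, 0], "y": d.coords[:, 1]})
        if d.z is not None:
            cdf["z"] = d.z
        if d.layer_index is not None:
            cdf["layer_index"] = d.layer_index
        cdf.to_csv(path / "coords.csv", index=False)
        return
    if format == "delimited-table":
        df = pd.DataFrame(d.expression, columns=d.gene_names)
        df.insert(0, "cell_id", d.cell_ids)
        df.insert(1, "x", d.coords[:, 0])
        df.insert(2, "y", d.coords[:, 1])
        if d.z is not None:
            df.insert(3, "z", d.z)
        if d.layer_index is not None:
            df["layer_index"] = d.layer_index
        df.to_csv(path, index=False)
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess(d: SpatialExpressionDataset, cfg: PreprocessingConfig) -> SpatialExpressionDataset:
    """Normalize, log-transform and optionally smooth a dataset.

    Order is fixed: per-cell total-count normalization (target = median of
    per-cell totals) -> log(1 + x) -> spatial quantile smoothing.  Cells with
    zero total count are left as all-zero with a warning.
    """
    X = d.expression
    if cfg.do_normalize:
        totals = X.sum(axis=1)
        nonzero = totals > 0
        if not nonzero.all():
            warnings.warn(f"{int((~nonzero).sum())} cell(s) with zero total count left as zeros")
        target = float(np.median(totals[nonzero])) if nonzero.any() else 0.0
        scale = np.ones_like(totals)
        scale[nonzero] = target / totals[nonzero]
        X = X * scale[:, None]
    log_flag = d.log_transformed
    if cfg.do_log:
        X = np.log1p(X)
        log_flag = True
    out = replace(d, expression=X, log_transformed=log_flag, _raw=d._raw if d._raw is not None else d.expression)
    if cfg.smoothing_radius is not None:
        lo, hi = cfg.smoothing_quantiles
        out = quantile_smooth(out, cfg.smoothing_radius, lo, hi)
    return out


def quantile_smooth(
    d: SpatialExpressionDataset, radius: float, q_lo: float = 0.2, q_hi: float = 0.8
) -> SpatialExpressionDataset:
    """Replace each value by the mean of two neighborhood quantiles.

    For every cell and gene the value becomes
    ``(quantile(q_lo, V) + quantile(q_hi, V)) / 2`` where ``V`` are the values
    of that gene over all cells within Euclidean distance ``radius`` of the
    cell (the cell itself included).  Quantiles use the linear-interpolation
    definition.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(d.coords)
    neighbors = tree.query_ball_point(d.coords, r=radius)
    X = d.expression
    out = np.empty_like(X)
    for i, idx in enumerate(neighbors):
        sub = X[idx, :]
        qs = np.quantile(sub, [q_lo, q_hi], axis=0)
        out[i, :] = 0.5 * (qs[0] + qs[1])
    return replace(d, expression=out)


def auto_epsilon(d: SpatialExpressionDataset, scale_factor: float = 0.02) -> float:
    """Dataset-scaled DBSCAN radius: ``scale_factor`` x vertical extent.

    The heuristic sets the clustering radius to a fixed fraction (default
    0.02) of the sample's extent along the y axis.
    """
    y = d.coords[:, 1]
    extent = float(y.max() - y.min())
    if extent == 0:
        raise ValueError("degenerate dataset: zero vertical extent")
    return scale_factor * extent
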