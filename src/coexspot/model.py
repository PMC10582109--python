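"""Model/Results interface over the coexpression and CCI pipelines.

`CoexpressionModel` is constructed from a :class:`SpatialExpressionDataset`
plus configuration; ``fit()`` runs detection -> similarity network ->
Leiden communities -> coexpression hotspots and returns a
:class:`CoexpressionResults` carrying the hotspots, the containment
hierarchy, score fields, diagnostics and a ``summary()`` table.
`InteractionModel` does the same for ligand-receptor activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import cci as _cci
from . import hierarchy as _hierarchy
from . import scores as _scores
from .coexpression import (
    CoexpressionConfig,
    CoexpressionHotspot,
    HotspotSimilarityNetwork,
    run_coexpression,
)
from .dataset import PreprocessingConfig, SpatialExpressionDataset, preprocess
from .hotspots import HotspotDetectionConfig, SingleGeneHotspot


class CoexpressionModel:
    """Nested coexpression-hotspot model for one spatial sample.

    Parameters
    ----------
    dataset
        The (typically preprocessed) spatial expression dataset.
    detection, coexpression
        Stage configurations; see the respective dataclasses.
    preprocessing
        Optional preprocessing applied at construction (pass ``None`` when
        the dataset is already normalized/log-transformed).
    """

    def __init__(
        self,
        dataset: SpatialExpressionDataset,
        detection: HotspotDetectionConfig,
        coexpression: Optional[CoexpressionConfig] = None,
        preprocessing: Optional[PreprocessingConfig] = None,
    ) -> None:
        self.dataset = (
            preprocess(dataset, preprocessing) if preprocessing is not None else dataset
        )
        self.detection = detection
        self.coexpression = coexpression or CoexpressionConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        gene_columns: list[str],
        detection: HotspotDetectionConfig,
        x: str = "x",
        y: str = "y",
        **kwargs,
    ) -> "CoexpressionModel":
        ds = SpatialExpressionDataset(
            expression=df[gene_columns].to_numpy(dtype=float),
            coords=df[[x, y]].to_numpy(dtype=float),
            gene_names=list(gene_columns),
            cell_ids=[str(i) for i in df.index],
        )
        return cls(ds, detection, **kwargs)

    def fit(self, seed: Optional[int] = None) -> "CoexpressionResults":
        cfg = self.coexpression
        if seed is not None:
            from dataclasses import replace

            cfg = replace(cfg, seed=seed)
        chs, hotspots, net = run_coexpression(self.dataset, self.detection, cfg)
        return CoexpressionResults(
            model=self, hotspots=hotspots, network=net, coexpression_hotspots=chs
        )


@dataclass
class CoexpressionResults:
    """Fitted coexpression hotspots with hierarchy, scores and exports."""

    model: CoexpressionModel
    hotspots: list[SingleGeneHotspot]
    network: HotspotSimilarityNetwork
    coexpression_hotspots: list[CoexpressionHotspot]
    _tree: Optional[_hierarchy.HierarchyTree] = field(default=None, repr=False)

    @property
    def dataset(self) -> SpatialExpressionDataset:
        return self.model.dataset

    def hierarchy(self, threshold: float = 0.75) -> _hierarchy.HierarchyTree:
        if self._tree is None or self._tree.containment_threshold != threshold:
            self._tree = _hierarchy.build_tree(self.coexpression_hotspots, threshold)
        return self._tree

    def markers(self, p_cut: float = 0.001, genes=None) -> list[_hierarchy.MarkerResult]:
        return _hierarchy.hierarchical_markers(
            self.dataset, self.coexpression_hotspots, self.hierarchy(), p_cut, genes=genes
        )

    def pairwise_de(self, ch_a: int, ch_b: int, genes=None) -> pd.DataFrame:
        by_id = {c.id: c for c in self.coexpression_hotspots}
        return _hierarchy.pairwise_de(self.dataset, by_id[ch_a], by_id[ch_b], genes=genes)

    def coherence(self) -> _scores.CellScoreField:
        return _scores.coherence_score(
            self.coexpression_hotspots, self.hotspots, self.dataset.n_cells
        )

    def uniqueness(self) -> _scores.CellScoreField:
        return _scores.uniqueness_score(
            self.coexpression_hotspots, self.hotspots, self.dataset.n_cells
        )

    def similarity_map(
        self, ch_id: int, target: Optional[SpatialExpressionDataset] = None
    ) -> _scores.CellScoreField:
        by_id = {c.id: c for c in self.coexpression_hotspots}
        if target is None:
            return _scores.similarity_map(
                by_id[ch_id], self.dataset, self.model.detection, target_hotspots=self.hotspots
            )
        return _scores.similarity_map(by_id[ch_id], target, self.model.detection)

    def decompose(self, gene: str) -> _scores.Decomposition:
        return _scores.decompose_gene(
            gene, self.hotspots, self.coexpression_hotspots, self.dataset.n_cells
        )

    def summary(self) -> pd.DataFrame:
        """One row per coexpression hotspot: size, gene count, layer, parent."""
        tree = self.hierarchy()
        rows = []
        for c in self.coexpression_hotspots:
            rows.append(
                {
                    "ch_id": c.id,
                    "n_cells": len(c.members),
                    "n_genes": len(c.genes),
                    "n_gene_hotspots": len(c.gene_hotspots),
                    "layer": tree.layer[c.id],
                    "parent": tree.parent[c.id],
                }
            )
        return pd.DataFrame(rows)

    def membership_table(self) -> pd.DataFrame:
        rows = [
            (c.id, self.dataset.cell_ids[m])
            for c in self.coexpression_hotspots
            for m in sorted(c.members)
        ]
        return pd.DataFrame(rows, columns=["ch_id", "cell_id"])

    def network_table(self) -> pd.DataFrame:
        rows = [(i, j, w) for (i, j), w in sorted(self.network.edges.items())]
        return pd.DataFrame(rows, columns=["hotspot_i", "hotspot_j", "jaccard"])

    def plot_hotspots(self, ax=None, cmap: str = "tab20"):
        """Scatter the cells colored by deepest covering coexpression hotspot."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        coords = self.dataset.coords
        ax.scatter(coords[:, 0], coords[:, 1], s=4, c="lightgray", linewidths=0)
        tree = self.hierarchy()
        order = sorted(self.coexpression_hotspots, key=lambda c: tree.layer[c.id])
        cm = plt.get_cmap(cmap)
        for c in order:
            idx = np.array(sorted(c.members))
            ax.scatter(
                coords[idx, 0],
                coords[idx, 1],
                s=4,
                color=cm(c.id % 20),
                linewidths=0,
                label=f"CH{c.id}",
            )
        ax.set_aspect("equal")
        ax.legend(loc="upper right", fontsize="x-small", markerscale=2)
        return ax


class InteractionModel:
    """Spatial ligand-receptor activity model.

    ``fit()`` computes, per analyzable interaction, the transport matrix
    matching the pair's annotation, the Hill activity, the permutation
    cutoff, and the CCI hotspots.
    """

    def __init__(
        self,
        dataset: SpatialExpressionDataset,
        pairs: list[_cci.LigandReceptorPair],
        detection: HotspotDetectionConfig,
        diffusion_cutoff: float = 100.0,
        contact_max_edge: float = 20.0,
        K_h: float = 0.5,
        n_perm: int = 100,
        alpha: float = 0.05,
    ) -> None:
        self.dataset = dataset
        self.pairs = [
            p
            for p in pairs
            if p.ligand in dataset.gene_names and p.receptor in dataset.gene_names
        ]
        self.detection = detection
        self.diffusion_cutoff = diffusion_cutoff
        self.contact_max_edge = contact_max_edge
        self.K_h = K_h
        self.n_perm = n_perm
        self.alpha = alpha

    def fit(self, seed: int = 0) -> "InteractionResults":
        d = self.dataset
        use_3d = d.z is not None and d.layer_index is not None
        coords = d.coords3d() if use_3d else d.coords
        diff = _cci.diffusion_transport(coords, self.diffusion_cutoff)
        contact = None
        fields, hotspots = {}, {}
        ss = np.random.SeedSequence(seed)
        child = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(max(len(self.pairs), 1)))
        for pair in self.pairs:
            if pair.annotation == _cci.CONTACT:
                if contact is None:
                    contact = _cci.contact_transport(d.coords, self.contact_max_edge)
                transport = contact
            else:
                transport = diff
            field = _cci.permutation_cutoff(
                d,
                pair,
                transport,
                n_perm=self.n_perm,
                alpha=self.alpha,
                seed=int(next(child)),
                K_h=self.K_h,
                layer_index=d.layer_index if use_3d else None,
            )
            fields[pair.label] = field
            hotspots[pair.label] = _cci.cci_hotspots(d, field, self.detection)
        return InteractionResults(model=self, fields=fields, hotspots=hotspots, seed=seed)


@dataclass
class InteractionResults:
    model: InteractionModel
    fields: dict[str, _cci.ActivityField]
    hotspots: dict[str, list[SingleGeneHotspot]]
    seed: int = 0

    @property
    def dataset(self) -> SpatialExpressionDataset:
        return self.model.dataset

    def link_3d(self, label: str, **kwargs) -> list[dict]:
        return _cci.link_3d_hotspots(self.dataset, self.hotspots[label], **kwargs)

    def summary(self) -> pd.DataFrame:
        rows = []
        for label, field in self.fields.items():
            rows.append(
                {
                    "interaction": label,
                    "n_active": int(field.active.sum()) if field.active is not None else 0,
                    "cutoff": field.cutoff_value,
                    "n_hotspots": len(self.hotspots[label]),
                }
            )
        return pd.DataFrame(rows)

    def activity_table(self, label: str) -> pd.DataFrame:
        field = self.fields[label]
        d = self.dataset
        df = pd.DataFrame(
            {
                "cell_id": d.cell_ids,
                "activity": field.activity,
                "active": field.active if field.active is not None else False,
            }
        )
        hot = np.full(d.n_cells, -1)
        for hid, h in enumerate(self.hotspots[label]):
            for m in h.members:
                hot[m] = hid
        df["hotspot_id"] = hot
        if d.layer_index is not None:
            df["layer"] = d.layer_index
        return df

    def layer_prevalence(self) -> pd.DataFrame:
        """Fraction of each layer's cells active, per interaction."""
        d = self.dataset
        if d.layer_index is None:
            raise ValueError("layer prevalence needs layered data")
        rows = []
        for label, field in self.fields.items():
            for lab in np.unique(d.layer_index):
                sel = d.layer_index == lab
                rows.append(
                    {
                        "interaction": label,
                        "layer": int(lab),
                        "fraction_active": float(field.active[sel].mean())
                        if field.active is not None
                        else 0.0,
                    }
                )
        return pd.DataFrame(rows)
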