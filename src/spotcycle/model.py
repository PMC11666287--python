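"""The user-facing modelling objects.

:class:`SpatialDeconvolutionModel` is built from a spatial dataset and an
scRNA-seq reference; construction performs gene selection/harmonization,
normalization and spatial-graph building. :meth:`fit` runs the three-stage
training (VGAE pre-training, cycle-consistent adversarial refinement,
mapping-matrix optimization) and returns a :class:`DeconvolutionResults`
holding the per-spot annotation proportions, the mapping matrix, the loss
traces and a summary table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cgan, deconvolution as dec, io as scio, metrics
from .config import RunConfig
from .datasets import SingleCellDataset, SpatialDataset
from .graph import SpatialGraph, build_knn_graph
from .nn import NetworkParameters

__all__ = ["SpatialDeconvolutionModel", "DeconvolutionResults"]


class SpatialDeconvolutionModel:
    """Cell-type deconvolution of ST spots against an scRNA-seq reference.

    Parameters
    ----------
    st : SpatialDataset
        Spot × gene counts with 2-D coordinates.
    sc : SingleCellDataset
        Cell × gene counts with one annotation per cell.
    config : RunConfig, optional
        Training configuration; defaults follow the published settings.
    """

    def __init__(self, st: SpatialDataset, sc: SingleCellDataset,
                 config: RunConfig | None = None):
        self.config = config or RunConfig()
        genes_before = (st.n_genes, sc.n_genes)
        st = scio.select_hvgs(st, self.config.n_hvg)
        st, sc = scio.harmonize_genes(st, sc)
        self.st = st
        self.sc = sc
        self.annotation = scio.build_annotation_matrix(sc)
        self.graph: SpatialGraph = build_knn_graph(st.coordinates,
                                                   self.config.k_neighbors)
        if self.config.normalize:
            self.X = scio.normalize_expression(st.expression,
                                               target_sum=self.config.target_sum)
            self.X_sc = scio.normalize_expression(sc.expression,
                                                  target_sum=self.config.target_sum)
        else:
            self.X = np.asarray(st.expression, dtype=np.float64)
            self.X_sc = np.asarray(sc.expression, dtype=np.float64)
        if self.config.scale_genes:
            self.X = scio.standardize_genes(self.X)
            self.X_sc = scio.standardize_genes(self.X_sc)
        self.provenance = {
            "genes_before": {"st": genes_before[0], "sc": genes_before[1]},
            "genes_after_hvg": st.n_genes,
            "genes_harmonized": st.n_genes,
            "n_spots": st.n_spots,
            "n_cells": sc.n_cells,
            "n_annotations": int(self.annotation.n_annot),
        }

    @classmethod
    def from_files(cls, st_path, sc_path, annotation_key: str = "cell_type",
                   config: RunConfig | None = None, st_format: str | None = None,
                   sc_format: str | None = None) -> "SpatialDeconvolutionModel":
        st = scio.load_spatial(st_path, format=st_format)
        sc = scio.load_single_cell(sc_path, format=sc_format,
                                   annotation_key=annotation_key)
        return cls(st, sc, config=config)

    def fit(self, seed: int | None = None) -> "DeconvolutionResults":
        """Run all three training stages and return the results object."""
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        rng = np.random.default_rng(seed)
        params = NetworkParameters.init(self.st.n_genes, cfg.d_hidden,
                                        cfg.d_latent, rng, d_disc=cfg.d_disc)
        pre_trace = cgan.pretrain(self.X, self.graph, params, cfg, rng)

        # frozen reconstruction (evaluation mode, ε = 0) for the mapping stage
        state = cgan.encode(self.X, self.graph, params, eps=None)
        x_hat = cgan.decode_expression(state.z, self.graph, params)

        mapping, map_trace = dec.fit_mapping(self.X_sc, x_hat, self.graph,
                                             params, cfg, rng)
        P_raw = dec.project_annotations(mapping, self.annotation)
        P_filt = dec.filter_top_annotations(P_raw, cfg.top_fraction)
        trace = pd.concat([pre_trace, map_trace], ignore_index=True)
        return DeconvolutionResults(model=self, params=params, mapping=mapping,
                                    proportions_raw=P_raw.to_frame(self.st.spot_ids),
                                    proportions=P_filt.to_frame(self.st.spot_ids),
                                    trace=trace, seed=seed,
                                    latent=state.mu, x_hat=x_hat)


@dataclass
class DeconvolutionResults:
    """Estimates and diagnostics of one fitted deconvolution run."""

    model: SpatialDeconvolutionModel
    params: NetworkParameters
    mapping: dec.MappingMatrix
    proportions_raw: pd.DataFrame    # pre-filter spot × annotation
    proportions: pd.DataFrame        # post top-fraction filter (user-facing)
    trace: pd.DataFrame
    seed: int
    latent: np.ndarray = field(repr=False, default=None)
    x_hat: np.ndarray = field(repr=False, default=None)

    # ---------------------------------------------------------- evaluation
    def score(self, truth: pd.DataFrame, post_filter: bool = True) -> dict:
        """RMSE and JSD against a ground-truth proportion table (spot × type;
        aligned on spot ids and type columns)."""
        pred = self.proportions if post_filter else self.proportions_raw
        truth = truth.loc[pred.index]
        cols = [c for c in pred.columns if c in set(truth.columns)]
        if len(cols) != pred.shape[1]:
            raise ValueError("truth table lacks some predicted annotation columns")
        t, p = truth[cols], pred[cols]
        return {"rmse": metrics.rmse(t, p), "jsd": metrics.jsd(t, p),
                "rmse_per_type": dict(zip(cols, metrics.rmse(t, p, scope="per_type")))}

    # ------------------------------------------------------------- display
    def summary(self) -> str:
        cfg = self.model.config
        prov = self.model.provenance
        final = {}
        for stage in ("vgae", "cgan", "mapping"):
            sub = self.trace[self.trace["stage"] == stage]
            if len(sub):
                col = {"vgae": "L_re", "cgan": "L_cyc", "mapping": "L_map"}[stage]
                final[stage] = (len(sub), float(sub[col].iloc[0]),
                                float(sub[col].iloc[-1]))
        lines = [
            "Spatial deconvolution results",
            "=============================",
            f"spots: {prov['n_spots']}   genes: {prov['genes_harmonized']}   "
            f"reference cells: {prov['n_cells']}   annotations: {prov['n_annotations']}",
            f"seed: {self.seed}   k_neighbors: {cfg.k_neighbors}   "
            f"alpha/beta/gamma: {cfg.alpha}/{cfg.beta}/{cfg.gamma}",
        ]
        for stage, (n, first, last) in final.items():
            lines.append(f"stage {stage:8s}: {n:5d} epochs   "
                         f"loss {first:.4f} -> {last:.4f}")
        mean_prop = self.proportions.mean(axis=0).sort_values(ascending=False)
        lines.append("mean proportions (post-filter):")
        for name, v in mean_prop.items():
            lines.append(f"  {name:20s} {v:.4f}")
        return "\n".join(lines)

    # --------------------------------------------------------- persistence
    def save(self, out_dir) -> Path:
        """Write proportions, mapping matrix, traces and the resolved config."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.proportions.to_csv(out / "proportions.csv")
        self.proportions_raw.to_csv(out / "proportions_prefilter.csv")
        self.trace.to_csv(out / "loss_trace.csv", index=False)
        np.savez_compressed(out / "mapping_matrix.npz",
                            logits=self.mapping.logits,
                            matrix=self.mapping.matrix)
        pd.Series(self.model.sc.cell_ids).to_csv(out / "mapping_cell_ids.csv",
                                                 index=False, header=["cell_id"])
        pd.Series(self.model.st.spot_ids).to_csv(out / "mapping_spot_ids.csv",
                                                 index=False, header=["spot_id"])
        self.model.config.to_yaml(out / "config.yaml")
        with open(out / "run.json", "w") as fh:
            json.dump({"seed": self.seed, **self.model.provenance}, fh, indent=2)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
        return out

    # ------------------------------------------------------------ plotting
    def plot_proportions(self, annotation: str, ax=None):
        """Scatter the spots colored by one annotation's proportion."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        coords = self.model.st.coordinates
        sc_ = ax.scatter(coords[:, 0], coords[:, 1],
                         c=self.proportions[annotation].to_numpy(),
                         cmap="viridis", s=30)
        ax.set_title(annotation)
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        plt.colorbar(sc_, ax=ax, label="proportion")
        return ax
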