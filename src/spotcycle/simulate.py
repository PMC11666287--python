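"""Paired synthetic scRNA-seq + spatial data with known spot compositions.

The generator emulates the gridded single-cell benchmark design used for
imaging-based platforms: single cells with cell-type-specific
negative-binomial count profiles are placed in a 2-D field according to a
spatial pattern, the field is divided into a square grid, the cells inside
each grid square are pooled into one "spot" by summing their counts, and the
per-spot label frequencies of the pooled cells are the ground-truth
proportions.

Cell-type identity is carried by marker genes: each type elevates its own
block of ``n_markers_per_type`` genes by ``marker_fold`` over a shared
baseline. The reference and spatial cell pools are drawn independently from
the same type-specific means, so a deconvolution method cannot succeed by
memorizing individual profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import SingleCellDataset, SpatialDataset
from . import io as scio

__all__ = ["SimulationConfig", "GroundTruth", "simulate_reference",
           "simulate_spatial", "simulate_pair", "write_fixture", "PRESETS"]


@dataclass
class SimulationConfig:
    n_types: int = 4
    n_cells: int = 800              # reference pool size
    n_genes: int = 200
    n_markers_per_type: int = 10
    marker_fold: float = 5.0
    grid_side: int = 8              # spots = grid_side**2
    cells_per_spot: int = 6         # mean pooled cells per grid square
    spatial_pattern: str = "blocks"  # blocks | gradient | random
    nb_dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_markers_per_type * self.n_types > self.n_genes:
            raise ValueError("marker blocks exceed the number of genes")
        for name in ("n_types", "n_cells", "n_genes", "grid_side", "cells_per_spot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spatial_pattern not in ("blocks", "gradient", "random"):
            raise ValueError(f"unknown spatial_pattern {self.spatial_pattern!r}")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")

    @property
    def type_labels(self) -> np.ndarray:
        return np.array([f"type{t:02d}" for t in range(self.n_types)], dtype=object)


PRESETS = {
    "small": SimulationConfig(n_types=4, n_cells=800, n_genes=200,
                              n_markers_per_type=10, grid_side=8,
                              cells_per_spot=6),
    "medium": SimulationConfig(n_types=6, n_cells=2400, n_genes=1000,
                               n_markers_per_type=15, grid_side=16,
                               cells_per_spot=8),
}


@dataclass
class GroundTruth:
    proportions: pd.DataFrame        # spot × type, rows sum to 1
    cell_positions: np.ndarray       # (n_placed_cells, 2)
    cell_to_spot: np.ndarray         # spot row per placed cell (-1 if its spot was dropped)
    dropped_spots: list = field(default_factory=list)
    cell_expression: np.ndarray | None = None   # pooled cells' counts (conservation checks)


def _type_means(config: SimulationConfig) -> np.ndarray:
    """Per-type mean expression vectors, deterministic in config.seed."""
    rng = np.random.default_rng([config.seed, 0])
    baseline = rng.gamma(shape=2.0, scale=1.0, size=config.n_genes) + 0.1
    means = np.tile(baseline, (config.n_types, 1))
    for t in range(config.n_types):
        lo = t * config.n_markers_per_type
        means[t, lo:lo + config.n_markers_per_type] *= config.marker_fold
    return means


def _nb_counts(rng: np.random.Generator, means: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial draws with Var = m + dispersion·m² (gamma–Poisson)."""
    if dispersion <= 0:
        return rng.poisson(means).astype(np.float64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, means / shape)
    return rng.poisson(lam).astype(np.float64)


def _even_types(n_cells: int, n_types: int) -> np.ndarray:
    reps = [n_cells // n_types + (1 if t < n_cells % n_types else 0)
            for t in range(n_types)]
    return np.repeat(np.arange(n_types), reps)


def simulate_reference(config: SimulationConfig) -> SingleCellDataset:
    """Reference scRNA-seq pool: cells split evenly across types."""
    rng = np.random.default_rng([config.seed, 1])
    means = _type_means(config)
    types = _even_types(config.n_cells, config.n_types)
    counts = _nb_counts(rng, means[types], config.nb_dispersion)
    labels = config.type_labels[types]
    return SingleCellDataset(
        counts,
        np.array([f"ref_cell{i:05d}" for i in range(config.n_cells)], dtype=object),
        np.array([f"gene{g:05d}" for g in range(config.n_genes)], dtype=object),
        labels,
    )


def _place_cells(config: SimulationConfig, rng: np.random.Generator,
                 n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign types and 2-D positions in [0, grid_side)² per the pattern."""
    g = config.grid_side
    if config.spatial_pattern == "random":
        types = rng.integers(0, config.n_types, size=n_cells)
        pos = rng.uniform(0, g, size=(n_cells, 2))
        return types, pos
    if config.spatial_pattern == "gradient":
        pos = rng.uniform(0, g, size=(n_cells, 2))
        centers = (np.arange(config.n_types) + 0.5) / config.n_types
        width = 1.0 / config.n_types
        w = np.exp(-0.5 * ((pos[:, 0:1] / g - centers) / width) ** 2)
        w /= w.sum(axis=1, keepdims=True)
        types = np.array([rng.choice(config.n_types, p=row) for row in w])
        return types, pos
    # blocks: contiguous rectangles, one dominant type each, no mixing
    types = _even_types(n_cells, config.n_types)
    nbx = int(np.ceil(np.sqrt(config.n_types)))
    nby = int(np.ceil(config.n_types / nbx))
    pos = np.empty((n_cells, 2))
    for t in range(config.n_types):
        mask = types == t
        bx, by = t % nbx, t // nbx
        x0, x1 = g * bx / nbx, g * (bx + 1) / nbx
        y0, y1 = g * by / nby, g * (by + 1) / nby
        pos[mask, 0] = rng.uniform(x0, x1, size=mask.sum())
        pos[mask, 1] = rng.uniform(y0, y1, size=mask.sum())
    perm = rng.permutation(n_cells)
    return types[perm], pos[perm]


def simulate_spatial(config: SimulationConfig,
                     reference: SingleCellDataset) -> tuple[SpatialDataset, GroundTruth]:
    """Grid an independent cell pool into multi-cell spots.

    The pooled cells are fresh negative-binomial draws from the same
    type-specific means as ``reference`` (disjoint pool). Spot expression is
    the exact integer sum of its member cells; empty grid squares are
    dropped and recorded.
    """
    rng = np.random.default_rng([config.seed, 2])
    g = config.grid_side
    n_cells = g * g * config.cells_per_spot
    types, pos = _place_cells(config, rng, n_cells)
    means = _type_means(config)
    counts = _nb_counts(rng, means[types], config.nb_dispersion)

    ix = np.clip(pos[:, 0].astype(int), 0, g - 1)
    iy = np.clip(pos[:, 1].astype(int), 0, g - 1)
    spot_of_cell = iy * g + ix

    n_spots = g * g
    expr = np.zeros((n_spots, config.n_genes))
    np.add.at(expr, spot_of_cell, counts)
    tally = np.zeros((n_spots, config.n_types))
    np.add.at(tally, (spot_of_cell, types), 1.0)

    occupied = tally.sum(axis=1) > 0
    if occupied.sum() < 0.5 * n_spots:
        warnings.warn("more than 50% of grid spots are empty; "
                      "consider a coarser grid", stacklevel=2)
    keep = np.flatnonzero(occupied)
    dropped = [f"spot{s:04d}" for s in np.flatnonzero(~occupied)]
    cx = (keep % g) + 0.5
    cy = (keep // g) + 0.5

    spot_ids = np.array([f"spot{s:04d}" for s in keep], dtype=object)
    st = SpatialDataset(expr[keep], np.column_stack([cx, cy]),
                        spot_ids, reference.gene_ids.copy())
    props = tally[keep] / tally[keep].sum(axis=1, keepdims=True)
    new_index = -np.ones(n_spots, dtype=int)
    new_index[keep] = np.arange(len(keep))
    gt = GroundTruth(
        proportions=pd.DataFrame(props, index=pd.Index(spot_ids, name="spot_id"),
                                 columns=config.type_labels),
        cell_positions=pos,
        cell_to_spot=new_index[spot_of_cell],
        dropped_spots=dropped,
        cell_expression=counts,
    )
    return st, gt


def simulate_pair(config: SimulationConfig):
    """Convenience: reference pool, gridded spatial data and ground truth."""
    ref = simulate_reference(config)
    st, gt = simulate_spatial(config, ref)
    return ref, st, gt


def write_fixture(reference: SingleCellDataset, st: SpatialDataset,
                  truth: GroundTruth, out_dir,
                  config: SimulationConfig | None = None) -> dict:
    """Write a loadable fixture directory: st/ and sc/ MTX triplets plus the
    ground-truth proportions CSV (and the config, when given)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scio.write_spatial(st, out_dir / "st", format="mtx_dir")
    scio.write_single_cell(reference, out_dir / "sc", format="mtx_dir")
    truth.proportions.to_csv(out_dir / "ground_truth.csv")
    manifest = {
        "st": "st", "sc": "sc", "ground_truth": "ground_truth.csv",
        "annotation_key": "cell_type",
        "n_spots": st.n_spots, "n_genes": st.n_genes,
        "n_cells": reference.n_cells,
        "n_types": int(truth.proportions.shape[1]),
    }
    if config is not None:
        import yaml
        with open(out_dir / "simulation.yaml", "w") as fh:
            yaml.safe_dump(asdict(config), fh)
        manifest["simulation"] = "simulation.yaml"
    import json
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
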