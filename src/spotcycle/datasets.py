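"""In-memory containers for spatial and single-cell expression data.

A :class:`SpatialDataset` is a spot × gene count (or normalized) matrix with
2-D coordinates; a :class:`SingleCellDataset` is a cell × gene matrix with a
per-cell categorical annotation (typically cell type). Both validate their
invariants on construction so that downstream numerics never see duplicate
identifiers, negative expression or non-finite coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_unique(ids: np.ndarray, what: str) -> None:
    vals, counts = np.unique(ids, return_counts=True)
    dups = vals[counts > 1]
    if dups.size:
        raise ValueError(f"duplicate {what}: {', '.join(map(str, dups[:10]))}")


@dataclass
class SpatialDataset:
    """Spot × gene expression with spatial coordinates.

    Parameters
    ----------
    expression : (n_spot, n_gene) non-negative array
    coordinates : (n_spot, 2) finite array, units of the source platform
    spot_ids, gene_ids : unique string identifiers
    """

    expression: np.ndarray
    coordinates: np.ndarray
    spot_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=np.float64)
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n_spot, n_gene = self.expression.shape
        if self.coordinates.shape != (n_spot, 2):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{n_spot} spots")
        if len(self.spot_ids) != n_spot or len(self.gene_ids) != n_gene:
            raise ValueError("id lengths do not match the expression matrix")
        _check_unique(self.spot_ids, "spot ids")
        _check_unique(self.gene_ids, "gene ids")
        if (self.expression < 0).any():
            raise ValueError("expression has negative entries")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def subset_genes(self, gene_names) -> "SpatialDataset":
        idx = _gene_index(self.gene_ids, gene_names)
        return SpatialDataset(self.expression[:, idx], self.coordinates,
                              self.spot_ids, self.gene_ids[idx])


@dataclass
class SingleCellDataset:
    """Cell × gene expression with one categorical annotation per cell."""

    expression: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    annotations: np.ndarray

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=np.float64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.annotations = np.asarray(self.annotations, dtype=object)
        n_cell, n_gene = self.expression.shape
        if len(self.cell_ids) != n_cell or len(self.gene_ids) != n_gene:
            raise ValueError("id lengths do not match the expression matrix")
        if len(self.annotations) != n_cell:
            raise ValueError("annotations length does not match cell count")
        if n_cell == 0 or any(a is None or str(a) == "" for a in self.annotations):
            raise ValueError("every cell needs a non-empty annotation")
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")
        if (self.expression < 0).any():
            raise ValueError("expression has negative entries")

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def subset_genes(self, gene_names) -> "SingleCellDataset":
        idx = _gene_index(self.gene_ids, gene_names)
        return SingleCellDataset(self.expression[:, idx], self.cell_ids,
                                 self.gene_ids[idx], self.annotations)


@dataclass
class AnnotationMatrix:
    """One-hot cell × annotation matrix S; row i marks cell i's label."""

    matrix: np.ndarray
    annot_labels: np.ndarray = field(default=None)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.annot_labels = np.asarray(self.annot_labels, dtype=object)
        rows = self.matrix.sum(axis=1)
        if not np.allclose(rows, 1.0) or not ((self.matrix == 0) | (self.matrix == 1)).all():
            raise ValueError("annotation matrix must be one-hot")

    @property
    def n_annot(self) -> int:
        return self.matrix.shape[1]


def _gene_index(gene_ids: np.ndarray, wanted) -> np.ndarray:
    lookup = {g: i for i, g in enumerate(gene_ids)}
    try:
        return np.array([lookup[g] for g in wanted], dtype=np.intp)
    except KeyError as e:  # pragma: no cover - defensive
        raise KeyError(f"gene {e.args[0]!r} not present") from None
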