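"""Cell-to-spot mapping and annotation projection.

The mapping matrix M (N_cell × N_spot) is parameterized as a per-column
softmax over unconstrained logits, so each column is a probability
distribution over reference cells by construction. M is fitted against the
frozen pre-trained network by minimizing

    L_map = L_d(ĉ_z) + L_reg + β · ||X̂ − P_st||² / N_spot

where P_st = Mᵀ X_sc is the predicted ST expression (a convex combination of
cell profiles per spot), ĉ_z = [p_z; b_z] stacks the encoder embeddings of
P_st and of the frozen reconstruction X̂, and L_reg is a spatial contrastive
term on the cosine similarities of p_z that pulls neighboring spots together
and pushes non-neighbors apart. Only M's logits receive gradients; the
discriminator term reaches M through gradient reversal so p_z is driven
toward the b_z domain.

Annotations are projected onto spots as P = Mᵀ S and, mirroring the method's
post-processing, only the top 15% of annotation categories per spot are
retained (at least one) before renormalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor, concat, grad_reverse
from .graph import SpatialGraph
from .nn import EdgeIndex, NetworkParameters, nll_from_log_probs
from .cgan import _encode_t, _edges

__all__ = [
    "MappingMatrix",
    "PredictedST",
    "SpotAnnotationProbabilities",
    "normalize_mapping",
    "project_sc_to_st",
    "spatial_regularization_loss",
    "mapping_loss",
    "fit_mapping",
    "project_annotations",
    "filter_top_annotations",
]

_EPS = 1e-12


@dataclass
class MappingMatrix:
    """Trainable logits and the derived column-stochastic matrix M."""

    logits: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        return normalize_mapping(self.logits)


@dataclass
class PredictedST:
    matrix: np.ndarray
    latent: np.ndarray | None = None


@dataclass
class SpotAnnotationProbabilities:
    matrix: np.ndarray
    annot_labels: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.annot_labels = np.asarray(self.annot_labels, dtype=object)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("annotation probability rows must sum to 1")

    def to_frame(self, spot_ids=None) -> pd.DataFrame:
        idx = pd.Index(spot_ids, name="spot_id") if spot_ids is not None else None
        return pd.DataFrame(self.matrix, index=idx, columns=self.annot_labels)


def normalize_mapping(logits: np.ndarray) -> np.ndarray:
    """Column-wise softmax: every spot column becomes a distribution over cells."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.isfinite(logits).all():
        raise ValueError("logits must be finite")
    e = np.exp(logits - logits.max(axis=0, keepdims=True))
    return e / e.sum(axis=0, keepdims=True)


def project_sc_to_st(M: np.ndarray, X_sc: np.ndarray) -> np.ndarray:
    """P_st = Mᵀ X_sc — each spot's profile is a convex mix of cell profiles."""
    M = M.matrix if isinstance(M, MappingMatrix) else np.asarray(M, dtype=np.float64)
    X_sc = np.asarray(X_sc, dtype=np.float64)
    if M.shape[0] != X_sc.shape[0]:
        raise ValueError(
            f"M has {M.shape[0]} cells but X_sc has {X_sc.shape[0]} rows")
    return M.T @ X_sc


# ---------------------------------------------------- spatial regularization

def _cosine_t(p_z: Tensor) -> Tensor:
    sq = (p_z ** 2).sum(axis=1, keepdims=True)
    if (sq.data <= 0).any():
        warnings.warn("zero-norm embedding rows: their cosine similarities are 0")
    inv = (sq + _EPS) ** -0.5
    zn = p_z * inv
    return zn @ zn.T


def _reg_mask(graph: SpatialGraph, negatives,
              rng: np.random.Generator | None) -> tuple[np.ndarray, np.ndarray]:
    """Positive (neighbor) and negative (sampled non-neighbor) pair masks."""
    A = graph.adjacency
    n = A.shape[0]
    non_nbr = (1.0 - A) - np.eye(n)
    non_nbr = np.clip(non_nbr, 0.0, 1.0)
    if negatives == "all":
        return A, non_nbr
    m = int(negatives)
    if rng is None:
        raise ValueError("sampled negatives need an rng")
    neg = np.zeros((n, n))
    for i in range(n):
        pool = np.flatnonzero(non_nbr[i])
        if pool.size:
            take = rng.choice(pool, size=min(m, pool.size), replace=False)
            neg[i, take] = 1.0
    return A, neg


def spatial_regularization_loss(p_z, graph: SpatialGraph, negatives="all",
                                rng: np.random.Generator | None = None) -> float:
    """L_reg = −Σ_i [Σ_{j∈R_i} log σ(C_ij) + Σ_{k∉R_i} log(1 − σ(C_ik))].

    ``negatives`` is ``"all"`` for the exact non-neighbor sum or an integer m
    for m uniformly sampled non-neighbors per spot (rng required). Self-pairs
    are excluded from both sums.
    """
    return float(_reg_loss_t(Tensor(np.asarray(p_z, dtype=np.float64)),
                             *_reg_mask(graph, negatives, rng)).data)


def _reg_loss_t(p_z: Tensor, pos_mask: np.ndarray, neg_mask: np.ndarray) -> Tensor:
    C = _cosine_t(p_z)
    sig = C.sigmoid()
    pos = (Tensor(pos_mask) * (sig + _EPS).log()).sum()
    neg = (Tensor(neg_mask) * (1.0 - sig + _EPS).log()).sum()
    return -(pos + neg)


def mapping_loss(L_d_value: float, L_reg_value: float, x_hat, P_st,
                 beta: float) -> float:
    """L_map = L_d + L_reg + β·||X̂ − P_st||²/N_spot."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    x_hat = np.asarray(x_hat, dtype=np.float64)
    P_st = np.asarray(P_st, dtype=np.float64)
    if x_hat.shape != P_st.shape:
        raise ValueError("x_hat and P_st must share a shape")
    sq = ((x_hat - P_st) ** 2).sum() / x_hat.shape[0]
    return float(L_d_value) + float(L_reg_value) + float(beta) * sq


# ------------------------------------------------------------------ fitting

def fit_mapping(X_sc, x_hat, graph: SpatialGraph, params: NetworkParameters,
                config, rng: np.random.Generator | None = None):
    """Optimize the mapping logits against the frozen network.

    Returns ``(MappingMatrix, trace)``. Per epoch: form P_st = Mᵀ X_sc,
    encode it (evaluation mode, μ only) to p_z, stack with the constant b_z
    embedding of the frozen reconstruction, evaluate L_map and update the
    logits with Adam. Ablation flags ``no_disc`` / ``no_reg`` drop their
    terms.
    """
    X_sc = np.asarray(X_sc, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    n_cell, n_spot = X_sc.shape[0], x_hat.shape[0]
    if rng is None:
        rng = np.random.default_rng(getattr(config, "seed", 0))
    edges = _edges(graph)

    # freeze the network: gradients flow through activations, not weights
    frozen = [(p, p.requires_grad) for p in params.all_parameters()]
    for p, _ in frozen:
        p.requires_grad = False
    try:
        logits = Tensor(rng.standard_normal((n_cell, n_spot)), requires_grad=True)
        lr = getattr(config, "mapping_learning_rate", None) or config.learning_rate
        opt = Adam([logits], lr=lr, weight_decay=config.weight_decay)
        Xsc_t = Tensor(X_sc)
        xhat_t = Tensor(x_hat)

        b_mu, _ = _encode_t(xhat_t, edges, params)
        b_z = Tensor(b_mu.data)  # constant back-embedding of the frozen X̂
        labels = np.concatenate([np.zeros(n_spot, dtype=np.intp),
                                 np.ones(n_spot, dtype=np.intp)])

        use_disc = not getattr(config, "no_disc", False)
        use_reg = not getattr(config, "no_reg", False)
        negatives = getattr(config, "reg_negatives", 5)

        rows = []
        for epoch in range(config.epochs_mapping):
            opt.zero_grad()
            shifted = logits - logits.data.max(axis=0, keepdims=True)
            e = shifted.exp()
            M = e * e.sum(axis=0, keepdims=True) ** -1.0
            P_st = M.T @ Xsc_t
            mu_p, _ = _encode_t(P_st, edges, params)

            L_d_t = Tensor(0.0)
            if use_disc:
                c_hat = concat([grad_reverse(mu_p), b_z], axis=0)
                L_d_t = nll_from_log_probs(params.discriminator.log_probs(c_hat),
                                           labels)
            L_reg_t = Tensor(0.0)
            if use_reg:
                L_reg_t = _reg_loss_t(mu_p, *_reg_mask(graph, negatives, rng))
            sq = ((xhat_t - P_st) ** 2).sum() * (1.0 / n_spot)
            L_map = L_d_t + L_reg_t + config.beta * sq
            if not np.isfinite(L_map.item()):
                raise RuntimeError(f"non-finite mapping loss at epoch {epoch}")
            L_map.backward()
            opt.step()
            rows.append({"stage": "mapping", "epoch": epoch,
                         "L_map": L_map.item(), "L_d": L_d_t.item(),
                         "L_reg": L_reg_t.item(), "L_expr": float(sq.data)})
        trace = pd.DataFrame(rows, columns=["stage", "epoch", "L_map", "L_d",
                                            "L_reg", "L_expr"])
        return MappingMatrix(logits.data.copy()), trace
    finally:
        for p, flag in frozen:
            p.requires_grad = flag


# ------------------------------------------------------------- projection

def project_annotations(M, S, annot_labels=None) -> SpotAnnotationProbabilities:
    """P = Mᵀ S: per-spot annotation proportions; rows sum to 1."""
    from .datasets import AnnotationMatrix
    if isinstance(S, AnnotationMatrix):
        annot_labels = S.annot_labels if annot_labels is None else annot_labels
        S = S.matrix
    M = M.matrix if isinstance(M, MappingMatrix) else np.asarray(M, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if M.shape[0] != S.shape[0]:
        raise ValueError(f"M has {M.shape[0]} cells but S has {S.shape[0]} rows")
    if annot_labels is None:
        annot_labels = np.array([f"annot{j}" for j in range(S.shape[1])], dtype=object)
    return SpotAnnotationProbabilities(M.T @ S, annot_labels)


def filter_top_annotations(P: SpotAnnotationProbabilities,
                           fraction: float = 0.15) -> SpotAnnotationProbabilities:
    """Keep the top ``max(1, ⌈fraction·N_annot⌉)`` annotations per spot and
    renormalize; ties at the cutoff go to the lower annotation index."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    mat = P.matrix
    n_annot = mat.shape[1]
    m = max(1, math.ceil(fraction * n_annot))
    if m >= n_annot:
        return SpotAnnotationProbabilities(mat.copy(), P.annot_labels)
    out = np.zeros_like(mat)
    for i, row in enumerate(mat):
        keep = np.argsort(-row, kind="stable")[:m]  # stable: lower index wins ties
        out[i, keep] = row[keep]
    out /= out.sum(axis=1, keepdims=True)
    return SpotAnnotationProbabilities(out, P.annot_labels)
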