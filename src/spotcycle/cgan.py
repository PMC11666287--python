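"""Variational graph autoencoder with cycle-consistent adversarial alignment.

Pre-training has two stages. Stage 1 fits the VGAE alone by minimizing

    L_re = ||X - X̂||² / N  +  γ · ( BCE(A, Â) + KL[q(z|X,A) ‖ N(0, I)] / N )

(squared-error and KL terms are reduced per spot; BCE is the mean over all
adjacency entries). Stage 2 adds the cycle: the reconstruction X̂ is
re-encoded to a back-embedding b_z, a two-layer MLP discriminator is trained
to tell z rows from b_z rows, and the generator minimizes

    L_cyc = L_d(c_z) + α · L_re

with the discriminator term entering the generator update through gradient
reversal (or label flipping, per config), so that z and b_z are driven into
one latent distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor, as_tensor, concat, grad_reverse
from .graph import SpatialGraph
from .nn import EdgeIndex, NetworkParameters, nll_from_log_probs

__all__ = [
    "LatentState",
    "Reconstruction",
    "DomainBatch",
    "encode",
    "reparameterize",
    "decode_expression",
    "decode_adjacency",
    "reconstruction_loss",
    "domain_discriminator_loss",
    "cycle_forward",
    "cgan_loss",
    "pretrain",
]

_EPS = 1e-12  # probability clamp inside logs


@dataclass
class LatentState:
    """Per-spot Gaussian posterior (μ, log σ²) and the drawn sample z."""

    mu: np.ndarray
    logvar: np.ndarray
    z: np.ndarray
    eps: np.ndarray | None = None


@dataclass
class Reconstruction:
    x_hat: np.ndarray
    a_hat: np.ndarray


@dataclass
class DomainBatch:
    """Stacked [z; b_z] embeddings with their true domain indicator."""

    embeddings: np.ndarray
    domain_labels: np.ndarray


def _edges(graph) -> EdgeIndex:
    if isinstance(graph, EdgeIndex):
        return graph
    if isinstance(graph, SpatialGraph):
        return EdgeIndex.from_graph(graph)
    return EdgeIndex.from_adjacency(np.asarray(graph))


def _adjacency(graph) -> np.ndarray:
    if isinstance(graph, SpatialGraph):
        return graph.adjacency
    return np.asarray(graph, dtype=np.float64)


# ----------------------------------------------------------- tensor forward

def _encode_t(X: Tensor, edges: EdgeIndex, params: NetworkParameters):
    h = params.enc0(X, edges)
    return params.enc_mu(h, edges), params.enc_logvar(h, edges)


def _decode_t(z: Tensor, edges: EdgeIndex, params: NetworkParameters) -> Tensor:
    return params.dec2(params.dec1(z, edges), edges)


def _reparam_t(mu: Tensor, logvar: Tensor, eps: np.ndarray, literal: bool = False) -> Tensor:
    if literal:
        return mu + logvar * eps
    return mu + (logvar * 0.5).exp() * eps


def _recon_loss_t(X: Tensor, x_hat: Tensor, A: np.ndarray, a_hat: Tensor,
                  mu: Tensor, logvar: Tensor, gamma: float) -> Tensor:
    n = X.shape[0]
    sq = ((X - x_hat) ** 2).sum() * (1.0 / n)
    if gamma == 0.0:
        return sq
    bce = -(Tensor(A) * (a_hat + _EPS).log()
            + Tensor(1.0 - A) * (1.0 - a_hat + _EPS).log()).mean()
    kl = (-0.5 / n) * (1.0 + logvar - mu ** 2 - logvar.exp()).sum()
    return sq + gamma * (bce + kl)


# --------------------------------------------------------------- public ops

def encode(X, graph, params: NetworkParameters,
           eps: np.ndarray | None = None, literal: bool = False) -> LatentState:
    """Run the graph encoder; ``eps=None`` means evaluation mode (z = μ)."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != params.dims[0]:
        raise ValueError(f"X has {X.shape[1]} genes, encoder expects {params.dims[0]}")
    edges = _edges(graph)
    if edges.n_nodes != X.shape[0]:
        raise ValueError("graph size does not match the number of spots")
    mu_t, logvar_t = _encode_t(Tensor(X), edges, params)
    mu, logvar = mu_t.data, logvar_t.data
    if eps is None:
        z = mu.copy()
        eps_used = np.zeros_like(mu)
    else:
        eps_used = np.asarray(eps, dtype=np.float64)
        z = reparameterize(LatentState(mu, logvar, mu), eps_used, literal=literal)
    return LatentState(mu, logvar, z, eps_used)


def reparameterize(state: LatentState, eps: np.ndarray, literal: bool = False) -> np.ndarray:
    """z = μ + exp(½·log σ²) ⊙ ε (standard); ``literal=True`` uses μ + log σ²·ε."""
    eps = np.asarray(eps, dtype=np.float64)
    if eps.shape != state.mu.shape:
        raise ValueError("eps shape must match mu")
    if literal:
        return state.mu + state.logvar * eps
    return state.mu + np.exp(0.5 * state.logvar) * eps


def decode_expression(z, graph, params: NetworkParameters) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    if z.shape[1] != params.dims[2]:
        raise ValueError(f"z has {z.shape[1]} dims, decoder expects {params.dims[2]}")
    return _decode_t(Tensor(z), _edges(graph), params).data


def decode_adjacency(z) -> np.ndarray:
    """Â = sigmoid(z zᵀ); symmetric with entries in (0, 1)."""
    z = np.asarray(z, dtype=np.float64)
    return Tensor(z @ z.T).sigmoid().data


def reconstruction_loss(X, x_hat, A, a_hat, mu, logvar, gamma: float) -> float:
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return float(_recon_loss_t(Tensor(np.asarray(X, dtype=np.float64)),
                               as_tensor(np.asarray(x_hat, dtype=np.float64)),
                               _adjacency(A), as_tensor(np.asarray(a_hat, dtype=np.float64)),
                               as_tensor(np.asarray(mu, dtype=np.float64)),
                               as_tensor(np.asarray(logvar, dtype=np.float64)),
                               float(gamma)).data)


def domain_discriminator_loss(batch, probs) -> float:
    """L_d = −(1/2N) Σ_i Σ_d D_id log p_id over the stacked embedding rows.

    ``batch`` may be a :class:`DomainBatch` or a plain label vector. Zero
    probabilities at the true label are clamped at 1e-12.
    """
    labels = batch.domain_labels if isinstance(batch, DomainBatch) else batch
    labels = np.asarray(labels, dtype=np.intp)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[0] != len(labels):
        raise ValueError("probs must be (n_rows, n_domains)")
    p_true = np.clip(probs[np.arange(len(labels)), labels], _EPS, None)
    return float(-np.mean(np.log(p_true)))


def cycle_forward(X, graph, params: NetworkParameters,
                  eps: np.ndarray | None = None,
                  eps_back: np.ndarray | None = None, literal: bool = False):
    """Encode → decode → re-encode; returns (z state, reconstruction, b_z state)."""
    state = encode(X, graph, params, eps=eps, literal=literal)
    x_hat = decode_expression(state.z, graph, params)
    a_hat = decode_adjacency(state.z)
    back = encode(x_hat, graph, params, eps=eps_back, literal=literal)
    return state, Reconstruction(x_hat, a_hat), back


def cgan_loss(L_d_value: float, L_re_value: float, alpha: float) -> float:
    """L_cyc = L_d + α·L_re."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return float(L_d_value) + float(alpha) * float(L_re_value)


# ---------------------------------------------------------------- training

def _check_finite(value: float, stage: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss in stage {stage!r} at epoch {epoch}")


def pretrain(X, graph, params: NetworkParameters, config,
             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Two-stage pre-training; mutates ``params`` in place, returns the trace.

    Stage "vgae" minimizes L_re for ``config.epochs_vgae`` epochs. Stage
    "cgan" alternates a discriminator step (L_d on detached [z; b_z]) with a
    generator step on L_cyc for ``config.epochs_cgan`` epochs; skipped when
    ``config.no_cyc`` is set (plain VGAE, per the ablation contract).
    """
    X = np.asarray(X, dtype=np.float64)
    A = _adjacency(graph)
    edges = _edges(graph)
    n, d_z = X.shape[0], params.dims[2]
    if rng is None:
        rng = np.random.default_rng(getattr(config, "seed", 0))
    literal = getattr(config, "reparam_literal", False)
    Xt = Tensor(X)

    gen_opt = Adam(params.generator_parameters(), lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    disc_opt = Adam(params.discriminator_parameters(), lr=config.learning_rate,
                    weight_decay=config.weight_decay)
    rows = []

    def forward(sample: bool = True):
        mu, logvar = _encode_t(Xt, edges, params)
        eps = rng.standard_normal((n, d_z)) if sample else np.zeros((n, d_z))
        z = _reparam_t(mu, logvar, eps, literal)
        x_hat = _decode_t(z, edges, params)
        a_hat = (z @ z.T).sigmoid()
        L_re = _recon_loss_t(Xt, x_hat, A, a_hat, mu, logvar, config.gamma)
        return mu, logvar, z, x_hat, L_re

    for epoch in range(config.epochs_vgae):
        gen_opt.zero_grad()
        *_, L_re = forward()
        _check_finite(L_re.item(), "vgae", epoch)
        L_re.backward()
        gen_opt.step()
        rows.append({"stage": "vgae", "epoch": epoch, "L_re": L_re.item(),
                     "L_d": np.nan, "L_cyc": np.nan})

    labels = np.concatenate([np.zeros(n, dtype=np.intp), np.ones(n, dtype=np.intp)])
    adversarial_mode = getattr(config, "adversarial_mode", "grad_reversal")
    cgan_epochs = 0 if getattr(config, "no_cyc", False) else config.epochs_cgan

    for epoch in range(cgan_epochs):
        mu, logvar, z, x_hat, L_re = forward()
        mu_b, logvar_b = _encode_t(x_hat, edges, params)
        b_z = _reparam_t(mu_b, logvar_b, rng.standard_normal((n, d_z)), literal)

        # discriminator step on detached embeddings
        c_det = Tensor(np.concatenate([z.data, b_z.data], axis=0))
        disc_opt.zero_grad()
        L_d = nll_from_log_probs(params.discriminator.log_probs(c_det), labels)
        _check_finite(L_d.item(), "cgan/disc", epoch)
        L_d.backward()
        disc_opt.step()

        # generator step
        c_z = concat([z, b_z], axis=0)
        gen_opt.zero_grad()
        if adversarial_mode == "label_flip":
            L_d_gen = nll_from_log_probs(params.discriminator.log_probs(c_z),
                                         1 - labels)
        else:
            L_d_gen = nll_from_log_probs(
                params.discriminator.log_probs(grad_reverse(c_z)), labels)
        L_cyc = L_d_gen + config.alpha * L_re
        _check_finite(L_cyc.item(), "cgan/gen", epoch)
        L_cyc.backward()
        gen_opt.step()
        rows.append({"stage": "cgan", "epoch": epoch, "L_re": L_re.item(),
                     "L_d": L_d.item(), "L_cyc": L_cyc.item()})

    return pd.DataFrame(rows, columns=["stage", "epoch", "L_re", "L_d", "L_cyc"])
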