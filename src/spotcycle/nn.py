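"""Graph-attention layers, the variational graph autoencoder stack and the
domain discriminator, built on the package's reverse-mode autodiff.

The attention layer follows the GATv2 formulation: for an edge j→i the
unnormalized score is ``aᵀ LeakyReLU(W_l x_i + W_r x_j)``; scores are
softmax-normalized over each target node's in-neighborhood (self-loop
included) and messages are the W_r-transformed source features. Message
passing is edge-list based (O(E·d)), so sparse spot graphs stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, as_tensor, concat, gather, scatter_sum

__all__ = ["EdgeIndex", "GATv2Layer", "MLPDiscriminator", "NetworkParameters"]


@dataclass
class EdgeIndex:
    """Directed edges (src → dst) with self-loops, for message passing."""

    src: np.ndarray
    dst: np.ndarray
    n_nodes: int

    @classmethod
    def from_adjacency(cls, A: np.ndarray) -> "EdgeIndex":
        A = np.asarray(A)
        n = A.shape[0]
        src, dst = np.nonzero(A.T)  # A[i, j] = 1 means j is a neighbor of i
        src = np.concatenate([src, np.arange(n)])
        dst = np.concatenate([dst, np.arange(n)])
        order = np.lexsort((src, dst))
        return cls(src[order], dst[order], n)

    @classmethod
    def from_graph(cls, graph) -> "EdgeIndex":
        return cls.from_adjacency(graph.adjacency)


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class GATv2Layer:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 activation: str | None = None, negative_slope: float = 0.2):
        self.d_in, self.d_out = d_in, d_out
        self.activation = activation
        self.negative_slope = negative_slope
        self.W_l = Tensor(_glorot(rng, (d_in, d_out)), requires_grad=True)
        self.W_r = Tensor(_glorot(rng, (d_in, d_out)), requires_grad=True)
        self.att = Tensor(_glorot(rng, (d_out, 1)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W_l, self.W_r, self.att, self.bias]

    def __call__(self, X, edges: EdgeIndex) -> Tensor:
        X = as_tensor(X)
        Hl = X @ self.W_l
        Hr = X @ self.W_r
        e = (gather(Hl, edges.dst) + gather(Hr, edges.src)).leaky_relu(
            self.negative_slope) @ self.att                        # (E, 1)
        # constant per-target shift for a numerically stable softmax
        shift = np.full(edges.n_nodes, -np.inf)
        np.maximum.at(shift, edges.dst, e.data[:, 0])
        ex = (e - shift[edges.dst, None]).exp()
        denom = scatter_sum(ex, edges.dst, edges.n_nodes)           # (N, 1)
        alpha = ex * gather(denom, edges.dst) ** -1.0
        out = scatter_sum(gather(Hr, edges.src) * alpha, edges.dst,
                          edges.n_nodes) + self.bias
        if self.activation == "elu":
            out = out.elu()
        return out


class MLPDiscriminator:
    """Two-layer MLP mapping a latent embedding to 2 domain logits."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.W1 = Tensor(_glorot(rng, (d_in, d_hidden)), requires_grad=True)
        self.b1 = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.W2 = Tensor(_glorot(rng, (d_hidden, 2)), requires_grad=True)
        self.b2 = Tensor(np.zeros(2), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def logits(self, emb) -> Tensor:
        h = (as_tensor(emb) @ self.W1 + self.b1).elu()
        return h @ self.W2 + self.b2

    def log_probs(self, emb) -> Tensor:
        """Row-wise log-softmax of the domain logits (numerically stable)."""
        s = self.logits(emb)
        shifted = s - s.data.max(axis=1, keepdims=True)
        return shifted - shifted.exp().sum(axis=1, keepdims=True).log()


@dataclass
class NetworkParameters:
    """All trainable weights: the VGAE stack plus the domain discriminator.

    Encoder: GATv2 d_in→d_hidden (ELU), then two parallel GATv2 heads
    d_hidden→d_latent producing μ and log σ². Expression decoder mirrors the
    encoder: GATv2 d_latent→d_hidden (ELU), GATv2 d_hidden→d_in.
    """

    enc0: GATv2Layer
    enc_mu: GATv2Layer
    enc_logvar: GATv2Layer
    dec1: GATv2Layer
    dec2: GATv2Layer
    discriminator: MLPDiscriminator
    dims: tuple[int, int, int] = field(default=(0, 0, 0))

    @classmethod
    def init(cls, d_in: int, d_hidden: int, d_latent: int,
             rng: np.random.Generator, d_disc: int = 64) -> "NetworkParameters":
        return cls(
            enc0=GATv2Layer(d_in, d_hidden, rng, activation="elu"),
            enc_mu=GATv2Layer(d_hidden, d_latent, rng),
            enc_logvar=GATv2Layer(d_hidden, d_latent, rng),
            dec1=GATv2Layer(d_latent, d_hidden, rng, activation="elu"),
            dec2=GATv2Layer(d_hidden, d_in, rng),
            discriminator=MLPDiscriminator(d_latent, d_disc, rng),
            dims=(d_in, d_hidden, d_latent),
        )

    def generator_parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in (self.enc0, self.enc_mu, self.enc_logvar, self.dec1, self.dec2):
            out.extend(layer.parameters())
        return out

    def discriminator_parameters(self) -> list[Tensor]:
        return self.discriminator.parameters()

    def all_parameters(self) -> list[Tensor]:
        return self.generator_parameters() + self.discriminator_parameters()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.all_parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.all_parameters(), arrays):
            p.data[...] = a


def nll_from_log_probs(log_probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-probability of the true label (one-hot selection)."""
    labels = np.asarray(labels, dtype=np.intp)
    onehot = np.zeros(log_probs.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(log_probs * onehot).sum() * (1.0 / len(labels))
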