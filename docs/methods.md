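# Methods

## Model

The package estimates per-spot cell-type proportions from two inputs: an ST
dataset (spot × gene counts, 2-D coordinates) and an scRNA-seq reference
(cell × gene counts, one categorical annotation per cell). Three stages run
in sequence.

**Spatial graph.** Spots are connected by a K-nearest-neighbor graph on
Euclidean coordinate distance, symmetrized by the union rule ($A_{ij} =
A_{ji} = 1$ when either endpoint lists the other among its $k$ nearest).
Distance ties are broken toward the lower spot index, so the graph is
deterministic even on degenerate coordinate sets. The adjacency stores no
self-edges; attention layers add a self-loop internally.

**Stage 1 — variational graph autoencoder (VGAE).** The encoder is a GATv2
layer (ELU) into two parallel GATv2 heads producing $\mu$ and $\log
\sigma^2$; for an edge $j \to i$ the attention score is $a^\top
\mathrm{LeakyReLU}(W_l x_i + W_r x_j)$, softmax-normalized over the target's
in-neighborhood, with $W_r x_j$ as the message. Sampling uses the standard
reparameterization $z = \mu + e^{\frac{1}{2}\log\sigma^2} \odot
\varepsilon$ (one $\varepsilon$ draw per forward pass; evaluation mode uses
$z = \mu$; a `reparam_literal` flag switches to $z = \mu + \log\sigma^2
\cdot \varepsilon$ for comparison). The expression decoder mirrors the
encoder; the adjacency decoder is $\hat A = \mathrm{sigm}(zz^\top)$. The
stage-1 objective is the negative evidence lower bound

    L_re = ||X − X̂||² / N_spot + γ·( BCE(A, Â) + KL[q(z|X,A) ‖ N(0,I)] / N_spot )

Reductions: the squared-error and KL terms are summed over entries and
divided by the number of spots; the BCE is the mean over all adjacency
entries. Only relative weights matter and γ absorbs the difference.

**Stage 2 — cycle-consistent adversarial refinement.** The reconstruction
$\hat X$ is re-encoded to a back-embedding $b_z$. A two-layer MLP
discriminator classifies the stacked rows $c_z = [z; b_z]$ by origin with
the cross-entropy $L_d = -\frac{1}{2N}\sum_i\sum_d D_{id}\log p_{id}$.
Updates alternate each epoch: the discriminator minimizes $L_d$ on detached
embeddings; the autoencoder minimizes $L_{cyc} = L_d + \alpha L_{re}$ with
the discriminator term entering through gradient reversal (config switch
`adversarial_mode="label_flip"` uses flipped labels instead). No explicit
$\lVert z - b_z \rVert$ penalty is added — the alignment pressure is purely
adversarial.

**Stage 3 — mapping-matrix deconvolution.** $M$ is parameterized as a
per-column softmax over unconstrained logits (standard-normal initialized
with the run seed), so every spot column is a probability distribution over
reference cells by construction after every optimizer step. The network is
frozen: the encoder supplies the embedding $p_z$ of $P_{st} = M^\top
X_{sc}$ (evaluation mode), $b_z$ is the constant embedding of the frozen
$\hat X$ (computed once with $\varepsilon = 0$), and the frozen
discriminator scores $[p_z; b_z]$ — gradient reversal on that term pushes
$p_z$ toward the $b_z$ domain. The spatial regularizer

    L_reg = − Σ_i [ Σ_{j∈R_i} log σ(C_ij) + Σ_{k∉R_i} log(1 − σ(C_ik)) ]

acts on the cosine-similarity matrix $C$ of $p_z$, with self-pairs excluded
from both sums. The exact non-neighbor sum is quadratic in spots; by
default 5 non-neighbors per spot are resampled each epoch (seeded), and
`reg_negatives="all"` gives the exact sum (used in tests, sensible up to a
few hundred spots). The expression term $\beta\lVert\hat X -
P_{st}\rVert^2 / N_{spot}$ completes $L_{map}$.

Annotation proportions are $P = M^\top S$; rows of $P$ sum to 1 whenever
$M$ is column-stochastic. Per spot, the top $\max(1, \lceil 0.15 \cdot
N_{annot}\rceil)$ annotation categories are retained (ties at the cutoff to
the lower index) and the row renormalized; the post-filter table is the
user-facing output and the default operand of the evaluation metrics
(switchable). The 15% retention is read as a fraction of annotation
*categories* per spot, not a global score percentile.

## Preprocessing

Both matrices are library-size normalized to a **shared** fixed total
(10,000 counts), log1p-transformed, and then per-gene standardized (z-score
within each dataset; constant genes map to 0). The shared total puts spots
and reference cells on one scale so that $\lVert \hat X - P_{st} \rVert^2$
compares like with like. Per-gene standardization matters for a different
reason: without it, per-gene baseline abundance dominates both the
autoencoder objective and the mapping term, the reconstruction blurs
marker-gene contrasts, and the mapping stage cannot identify cell types —
on the synthetic benchmark, recovery degrades from exact to chance.
Standardization is the convention of the graph-attention ST embedding
lineage this model belongs to and is switchable (`scale_genes=False`).

Highly variable genes are selected before harmonization by the
seurat-flavor normalized-dispersion ranking (via scanpy) on log1p
library-size-normalized counts, taking exactly `n_hvg` genes by rank with
deterministic tie-breaks; platform-typical values are 3000 (Visium), 5000
(seqFISH+) or all genes (targeted panels). The gene sets are then
intersected and ordered lexicographically so results do not depend on input
column order.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k_neighbors` | 6 | KNN degree; 6 matches a hex-packed Visium neighborhood |
| `alpha` | 10 | weight of $L_{re}$ inside $L_{cyc}$ |
| `beta` | 1 | weight of the expression-matching term in $L_{map}$ |
| `gamma` | 1 | weight of the adjacency-BCE + KL terms in $L_{re}$ |
| `epochs_vgae / cgan / mapping` | 1000 / 500 / 300 | published three-stage schedule |
| `learning_rate` | 0.001 | Adam, pre-training stages |
| `mapping_learning_rate` | 0.1 | Adam on the mapping logits (see below) |
| `weight_decay` | 5e-4 | classic L2 in Adam, all stages |
| `d_hidden / d_latent / d_disc` | 256 / 64 / 64 | layer widths (unstated in the source method; configurable) |
| `top_fraction` | 0.15 | retained annotation fraction per spot |
| `reg_negatives` | 5 | sampled non-neighbors per spot per epoch |

The mapping stage has its own learning rate because 0.001 cannot move
column-softmax logits materially within 300 full-batch Adam steps (the
per-step displacement is bounded near the learning rate, so the logits stay
within ~0.3 of their initialization regardless of the data); 0.1 is the
rate used by mapping-matrix methods of the Tangram family and recovers the
benchmark compositions, while 0.001 leaves the mapping at its
initialization.

## Synthetic data

The generator emulates gridded single-cell benchmark designs: cell types
are defined by blocks of `n_markers_per_type` marker genes elevated
`marker_fold`-fold over a shared gamma-distributed baseline; counts are
negative-binomial (gamma–Poisson, Var = m + φm², dispersion φ = 0.5 by
default). Cells are placed in a `grid_side`² field by one of three
patterns — `blocks` (contiguous pure rectangles), `gradient` (type
probability drifting along x), `random` — assigned to their containing grid
square, and summed into spot counts (exact integer conservation). Spot
coordinates are grid-square centers; empty squares are dropped and
recorded. Ground-truth proportions are the per-spot label frequencies of
the pooled cells. The reference and the pooled spatial cells are
*independent draws* from the same type means, so deconvolution cannot
memorize individual profiles. Presets: `small` (4 types, 8×8 grid, 200
genes, 800 reference cells) and `medium` (6 types, 16×16 grid, 1000 genes).

What it does not emulate: platform noise (optical crowding, segmentation
error, spot-edge effects), within-type continuous heterogeneity, batch
effects between the reference and the tissue, and unbalanced or missing
cell types. Passing the recovery benchmark therefore shows the pipeline is
correctly wired and identifiable under clean mixtures, not that it matches
field performance on real tissue.

## Benchmark scale and numerical choices

Tests and the acceptance script use the `small` preset with a reduced
schedule (200/100/150 epochs) and widths (64/16/32) so a full
four-variant, five-seed ablation study runs in minutes on one CPU; these
sizes are the package's desk-scale benchmark conditions. Numerical
details: probabilities inside logs are clamped at 1e-12 (never NaN); the
attention softmax subtracts a per-target maximum; zero-norm embedding rows
get cosine similarity 0 with a warning; `filter_top_annotations` uses a
ceiling with a floor of one retained annotation; all arrays are float64 and
every random draw flows from one seeded generator per fit, so identical
seeds reproduce proportions byte-for-byte.

## Known limitations

- On standardized inputs most of the per-gene variance is irreducible
  single-molecule count noise, so the stage-1 reconstruction loss plateaus
  roughly 25–45% below its starting value rather than collapsing toward
  zero; large relative drops occur only when the autoencoder is allowed to
  spend capacity on per-gene baselines (unstandardized input), which is
  precisely the regime where deconvolution fails. The meaningful stage-1
  diagnostic is a steady monotone decrease, not its percentage.
- The discriminator term contributes little on the clean synthetic
  benchmark (removing it barely changes accuracy); its stabilizing role is
  expected to matter on noisier real data.
- Full-graph training keeps every intermediate in memory; the edge-list
  attention is O(E·d), fine for thousands of spots, but no mini-batching is
  implemented.
- Annotations absent from the reference cannot be discovered; proportions
  are always over the reference's label set.
- `join_graphs` assumes the caller has already aligned multi-sample
  coordinates; no registration is performed.
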