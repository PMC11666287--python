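# spotcycle

Cell-type deconvolution of spatial transcriptomics (ST) spots against an
annotated scRNA-seq reference, using a cycle-consistent adversarial graph
autoencoder and a trainable cell-to-spot mapping matrix.

## The problem

Sequencing-based ST platforms measure each capture spot as a mixture over the
several cells it covers. Given a spot × gene matrix $X$ with 2-D coordinates
and a reference cell × gene matrix $X_{sc}$ with one annotation (cell type)
per cell, the task is to estimate, for every spot, the proportion of each
annotation — the spot's cellular composition.

## The method

1. **Spatial graph.** A symmetric binary adjacency $A$ over spots: $A_{ij} =
   A_{ji} = 1$ when $j$ is among the $k$ nearest neighbors of $i$ by
   Euclidean distance (union rule, default $k = 6$).
2. **Pre-training.** A variational graph autoencoder built from GATv2
   attention layers encodes $(X, A)$ into a per-spot Gaussian posterior
   $(\mu, \log\sigma^2)$, samples $z = \mu + e^{\frac{1}{2}\log\sigma^2}
   \odot \varepsilon$, and decodes both the expression
   $\hat X = D_X(z)$ and the adjacency $\hat A = \mathrm{sigm}(zz^\top)$,
   minimizing

   $$L_{re} = \lVert X - \hat X\rVert_2^2 + \gamma\,(\mathrm{BCE}(A, \hat A)
   + \mathrm{KL}[q(z \mid X, A)\,\Vert\, \mathcal N(0, I)]).$$

   A cycle stage then re-encodes $\hat X$ into a back-embedding $b_z$ and
   trains a two-layer MLP domain discriminator to tell $z$ rows from $b_z$
   rows, while the autoencoder minimizes
   $L_{cyc} = L_d(c_z) + \alpha L_{re}$ adversarially (gradient reversal),
   driving both embeddings into one latent distribution.
3. **Deconvolution.** A mapping matrix $M \in \mathbb R^{N_{cell} \times
   N_{spot}}$, column-stochastic by a per-column softmax, projects the
   reference into ST space, $P_{st} = M^\top X_{sc}$. With the network
   frozen, $M$ minimizes

   $$L_{map} = L_d(\hat c_z) + L_{reg} + \beta\,\lVert \hat X -
   P_{st}\rVert_2^2,$$

   where $\hat c_z$ stacks the encoder embeddings of $P_{st}$ and $\hat X$,
   and $L_{reg}$ is a spatial contrastive term on the cosine similarities of
   the $P_{st}$ embedding that pulls neighboring spots together. Annotation
   proportions are $P = M^\top S$ for the one-hot annotation matrix $S$; the
   top 15% of annotation categories per spot are retained and renormalized.

All neural components (GATv2 message passing, the variational autoencoder,
the discriminator, Adam) run on a compact reverse-mode autodiff engine over
NumPy arrays — the package has no deep-learning framework dependency.

## Worked example

```python
import spotcycle as sp

# paired synthetic study: 4 cell types in spatial blocks, 8x8 spot grid,
# 200 genes, disjoint reference / spatial cell pools, known proportions
sim = sp.SimulationConfig(seed=7)
reference, spatial, truth = sp.simulate_pair(sim)

config = sp.RunConfig(epochs_vgae=200, epochs_cgan=100, epochs_mapping=150,
                      d_hidden=64, d_latent=16, d_disc=32)
model = sp.SpatialDeconvolutionModel(spatial, reference, config)
result = model.fit(seed=0)
print(result.summary())
score = result.score(truth.proportions)
print(f"RMSE vs ground truth: {score['rmse']:.4f}")
print(f"JSD  vs ground truth: {score['jsd']:.4f}")
```

Output:

```
Spatial deconvolution results
=============================
spots: 64   genes: 200   reference cells: 800   annotations: 4
seed: 0   k_neighbors: 6   alpha/beta/gamma: 10.0/1.0/1.0
stage vgae    :   200 epochs   loss 230.4245 -> 157.7265
stage cgan    :   100 epochs   loss 1580.1474 -> 1422.2025
stage mapping :   150 epochs   loss 609.1504 -> 420.7144
mean proportions (post-filter):
  type00               0.2500
  type01               0.2500
  type02               0.2500
  type03               0.2500
RMSE vs ground truth: 0.0000
JSD  vs ground truth: 0.0000
```

The per-stage lines show each loss at its first and last epoch. On this
benchmark the four types occupy equal spatial blocks, so the mean
proportions are 0.25 each; the per-spot RMSE/JSD of 0 mean every spot's
composition was recovered exactly after the top-15% filter.

`result.proportions` is the spot × annotation table (rows sum to 1),
`result.mapping.matrix` the fitted cell-to-spot matrix, `result.trace` the
full loss trace, and `result.save(out_dir)` writes all artifacts.

The same pipeline runs from the shell:

```bash
spotcycle make-fixture --preset small --out fixture/
spotcycle deconvolve --st fixture/st --sc fixture/sc \
    --annotation-key cell_type --out run/ --epochs 200,100,150
spotcycle benchmark --fixture fixture/ --out bench/ --repeats 10
```

Ablations (`--ablate no_cyc,no_disc,no_reg`) disable the cycle stage, the
discriminator term, or the spatial regularizer.

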