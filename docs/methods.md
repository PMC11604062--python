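# Methods

## The model

stMMR learns one joint embedding per Visium-style spot from three sources of
information: the normalized expression matrix `G ∈ R^{N×P}` over the `P`
selected highly variable genes, per-spot histology features `H ∈ R^{N×M}`,
and the spot coordinates. The coordinates enter only through an undirected
weighted graph with Gaussian kernel weights

    A_ij = exp(−d(i,j)² / (2 l²)),

where `d` is the Euclidean distance and `l` the kernel bandwidth. Larger `l`
means slower decay of the weight with distance. Each modality is encoded by a
two-layer GCN over the symmetrically normalized adjacency
`Ã_n = D̃^{-1/2}(A + I)D̃^{-1/2}` (first layer rectified, second linear, no
biases), giving `E_G` and `E_H`. A self-attention pass
`E_A = softmax(E·Eᵀ/√d)·E` refines each modality globally; rectified affine
heads produce projections `Q_G`, `Q_H`, which are fused by an affine map of
their concatenation into `E_Q`. The joint representation is

    Z = α·E_Q + β·E_AH + γ·E_AG.

Three objectives shape `Z`:

* **similarity-contrastive alignment** `L_con = ‖Q̃_G Q̃_Gᵀ − Q̃_H Q̃_Hᵀ‖²_F`,
  the squared Frobenius distance between the two modalities' spot–spot
  cosine-similarity matrices (rows of each `Q` scaled to unit L2 norm);
* **ZINB reconstruction** `L_ZINB`, the mean negative log-likelihood of the
  raw counts of the `P` selected genes under a zero-inflated negative
  binomial whose mean, dispersion and dropout are decoded from `Z`;
* **adjacency reconstruction** `L_rec`, the mean squared difference between
  `A` and `A' = sigmoid(cos(Z_i, Z_j))`.

The total loss is `L = a·L_con + b·L_ZINB + c·L_rec`, trained full-batch with
Adam. Because `L_con` is a sum over all N² spot pairs while the other two
terms are per-entry means, the trainer averages the contrastive term per
spot pair by default (`contrastive_scale="mean"`); otherwise the balance of
the objective would depend on the dataset size, and at Visium scale the
contrastive gradients would swamp the reconstruction terms. The raw sum form
is available as `contrastive_scale="sum"`. Domains are obtained by clustering `Z` (Gaussian mixture by default)
and scored by the Adjusted Rand Index when a reference labeling exists.

## Interpretive choices

Several parts of the formulation admit more than one reading; the package
fixes them as follows and exposes the alternatives where meaningful.

* **ZINB target.** The likelihood scores the *raw counts* of the selected
  genes (count models model counts); the log-normalized matrix feeds the
  encoder. The decoder's mean head is an exponential scaled by the per-spot
  library size factor, dispersion is a softplus clamped to `[1e-4, 1e4]`,
  and dropout a logistic output.
* **Attention scale.** The score matrix is divided by `√d` with `d` the
  latent dimension (standard scaled dot-product attention). An experimental
  `attention_scale="distance-matrix"` variant divides scores by the pairwise
  Euclidean distances between embedding rows instead; it is off by default
  and the scaling matrix is treated as a constant in the gradient.
* **Projection input.** `Q_G`/`Q_H` are computed from the encoder outputs
  `E_G`/`E_H`; the attention outputs enter the model only through the fusion
  sum for `Z`.
* **Normalization in the contrastive loss.** "Normalization" is read as
  row-wise unit L2, which makes `Q̃Q̃ᵀ` a cosine-similarity matrix — the
  natural object for similarity contrast — and makes the loss invariant to
  per-modality rescaling.
* **Expression-only mode.** Without image features the β path is removed
  entirely: `E_Q` becomes an affine map of `Q_G` alone, `L_con ≡ 0`, and
  `Z = α·E_Q + γ·E_AG`. This is also the "without histology" ablation.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `n_hvg` | 3000 | HVG count (dispersion = var/mean of scaled counts, ranked descending); common SRT practice |
| `target_sum` | 1e4 | library-size normalization target (counts per spot after scaling) |
| `graph.k_neighbors` | 6 | symmetrized kNN sparsification; matches hexagonal Visium packing; `None` keeps the dense kernel |
| `graph.bandwidth` | auto | median nearest-neighbor distance; scales with the coordinate unit |
| `hidden_dim` | 256 | encoder hidden width |
| `latent_dim` | 64 | embedding width (also the projection width) |
| `decoder_hidden` | 128 | width of the single decoder hidden layer |
| `α, β, γ` | 0.5, 0.25, 0.25 | fusion weights; no constraint to sum to 1 is imposed |
| `a, b, c` | 1, 1, 1 | loss weights; each term is an ablation switch when set to 0 |
| `contrastive_scale` | mean | contrastive term averaged per spot pair (N-independent balance) vs raw Frobenius sum |
| `epochs` | 200 | full-batch Adam steps |
| `learning_rate` | 1e-3 | Adam step size |
| `image.pca_dim` | 50 | PCA reduction applied to image features wider than this (e.g. raw ViT outputs) before encoding |
| `dtype` | float32 | training precision; float64 available for tight numerical work |

Epsilon guards of `1e-12` stabilize every row normalization; softmax and
softplus/log-sum-exp computations are max-shifted. Duplicate coordinates are
allowed (kernel weight 1, logged); spots with zero total counts are dropped
with a warning; a constant gene can never be selected as an HVG.

## Implementation

No GPU framework is assumed: the network runs on a compact reverse-mode
automatic-differentiation tape over numpy arrays (`stmmr._tensor`), with the
ZINB likelihood implemented as a single fused primitive with analytic
gradients. Correctness is enforced by finite-difference gradient checks and
by independent dense/`scipy.stats` oracles in the test suite. Training is
bit-reproducible for a fixed seed on a fixed machine: the only randomness is
the Glorot initialization drawn from one seeded generator.

The adjacency target of `L_rec` is the (possibly kNN-sparsified) kernel
matrix `A` itself with zero diagonal; the reconstruction's diagonal is
`sigmoid(1)`, so a constant diagonal discrepancy is part of the loss floor.

## Synthetic data

The generator (`stmmr.synthetic`) emulates exactly the structure the model
assumes. Spots sit on a unit grid; `K` domains are contiguous rectangular
blocks (the contiguity the spatial kernel exploits, with unambiguous ground
truth). Counts are ZINB: gene-wise NB means are `base_mean`, raised by
`fold_change` for each domain's `n_marker_per_domain` marker genes, with
dispersion `Θ_true` and independent dropout zeros at rate `Π_true`. Image
features are a fixed random linear encoding of domain identity mixed with
Gaussian noise at ratio `image_signal`, so cross-modal consistency — the
premise of the contrastive loss — holds by construction and can be dialed
down. Defaults (N=800 on a 20×40 grid, K=4, 500 genes, 25 markers per
domain, base mean 2, fold change 4, dispersion 2, dropout 0.3, image signal
0.8, image dimension 50) describe a strong-signal regime in which domain
recovery is expected to be nearly perfect.

What the generator does **not** emulate: irregular tissue boundaries,
gradual (non-block) domain transitions, per-spot library-size variation
beyond sampling noise, gene–gene correlation within domains, batch and
platform effects, and real histology texture (features are generated
directly; patch extraction is exercised separately on toy images). Passing
the recovery tests therefore demonstrates internal consistency of the whole
pipeline under the model's own assumptions, not performance on real tissue.

## Problem sizes used in the automated checks

The acceptance checks train the full model and its three ablation variants
(no histology, no attention, no GCN) on five generator seeds of the default
strong-signal configuration above (200 epochs each), evaluate domain
recovery with a seeded Gaussian mixture, and compare the decoder's mean
matrix against the generator's noiseless means gene-by-gene. Deterministic
properties (loss fixed points, oracle equivalence, permutation equivariance,
seeded determinism) run on instances of 6–200 spots; equivariance uses the
float64 mode where 1e-8 agreement is asserted.

## Known limitations

* Full-graph training holds all N×N attention and similarity matrices in
  memory; Visium-scale slices (thousands of spots) are fine, but
  single-molecule-resolution datasets are not the target.
* The Leiden clustering option ignores the requested K and reports its own
  community count.
* The pretrained-ViT feature extractor is an optional adapter (`torch` +
  `timm`); the shipped deterministic stub extractor is a test double, not a
  substitute for learned histology features on real data.
* No multi-slice integration, batch correction, spatial label smoothing, or
  trajectory analysis; the exported embedding is the interface to such
  downstream tools.
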