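# stmmr

Multimodal representation learning for spatial-domain identification in
spatially resolved transcriptomics (SRT).

Sequencing-based SRT platforms such as 10x Visium measure gene expression at
known tissue coordinates and usually come with an H&E histology image. Each
modality sees tissue architecture at a different level: expression reflects
cell state, coordinates carry the spatial layout, and morphology shows what
the cells look like. `stmmr` fuses all three into one per-spot embedding
`Z` that is then clustered into spatial domains (cortical layers, tumor
regions, …) and can be exported for any downstream analysis.

## The model

Spots are connected by a Gaussian-weighted graph,
`A_ij = exp(−d(i,j)²/(2l²))`, and each modality — normalized expression
`G ∈ R^{N×P}` and per-spot image features `H ∈ R^{N×M}` — is encoded by a
two-layer GCN over the symmetrically normalized adjacency
`D̃^{-1/2}(A+I)D̃^{-1/2}`. A self-attention pass
`E_A = softmax(E·Eᵀ/√d)·E` captures global spot–spot relationships within a
modality. Rectified projection heads `Q = relu(E·W_Q + b_Q)` feed both a
fusion layer `E_Q = W_E·concat(Q_G, Q_H) + b_E` and a similarity-contrastive
loss

    L_con = ‖Q̃_G·Q̃_Gᵀ − Q̃_H·Q̃_Hᵀ‖²_F ,

the distance between the two modalities' cosine-similarity structures. The
joint embedding `Z = α·E_Q + β·E_AH + γ·E_AG` is trained to reconstruct the
raw counts through a zero-inflated negative binomial decoder (`L_ZINB`) and
the spatial adjacency through `A' = sigmoid(cos(Z_i, Z_j))` (`L_rec`), with
total objective `L = a·L_con + b·L_ZINB + c·L_rec`. See `docs/methods.md`
for all modeling choices and defaults.

The implementation is pure scientific Python (numpy/scipy autodiff tape, no
GPU framework needed) and is fully seed-deterministic.

## Worked example

Generate a synthetic multimodal dataset with four planted rectangular
domains, run the whole pipeline, and score the recovered domains:

```python
import stmmr

# 800 spots on a 20x40 grid, 4 domains, ZINB counts (dropout 0.3),
# image features carrying domain identity at signal strength 0.8
ds, true_labels, true_means = stmmr.generate(stmmr.SynthConfig(seed=0))

result, model = stmmr.run_pipeline(ds, n_domains=4,
                                   cfg=stmmr.TrainConfig(epochs=200, seed=0))

report = stmmr.evaluate(result.labels, true_labels, n_domains=4)
print(f"ARI  = {report.ari:.3f}")
print(f"NMI  = {report.nmi:.3f}")
l_con, l_zinb, l_rec, total = model.loss_history[-1]
print(f"final losses: L_con={l_con:.2g}  L_ZINB={l_zinb:.2f}  "
      f"L_rec={l_rec:.3f}  L={total:.2f}")
```

Output:

```
ARI  = 1.000
NMI  = 1.000
final losses: L_con=0.00045  L_ZINB=1.65  L_rec=0.263  L=1.91
```

An ARI of 1.0 means the clustering of the learned embedding reproduces the
planted domains exactly (1.0 = identical partitions, 0 = chance).
The final ZINB term is the mean negative log-likelihood per count entry;
`model.zinb_mean` (via `stmmr.reconstructed_expression`) is the denoised
expression profile.

The same pipeline runs from the shell on Visium directories or CSV inputs:

```sh
stmmr synth --out data/                        # write a synthetic dataset
stmmr run --input data/synth_counts.csv --coords data/synth_coords.csv \
          --image-features data/synth_image_features.csv \
          --n-domains 4 --seed 0 --out results/
```

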