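"""Full-batch training of the joint embedding, with seed control and telemetry.

Training is plain full-graph gradient descent with Adam: one forward pass per
epoch over the whole slice, backpropagation through the tape, one parameter
update.  Every source of randomness (parameter initialization) is drawn from
a single seeded generator, so runs are bit-reproducible on the same machine.

The per-epoch record keeps the three loss components and their weighted sum;
a non-finite loss aborts immediately with the epoch and the offending
component, which is the practical failure mode of a too-large learning rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from ._tensor import Tensor
from .data import SRTDataset
from .graph import SpatialGraph, auto_bandwidth, gaussian_adjacency, normalize_adjacency
from .model import (
    EncoderConfig,
    StmmrNetwork,
    adjacency_loss,
    reconstruct_adjacency,
    total_loss,
    zinb_nll,
)

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainedModel", "train", "get_embedding", "run_pipeline"]


@dataclass
class TrainConfig:
    """Everything the training loop needs, seed included."""

    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (a, b, c)
    # "mean" divides the contrastive Frobenius sum by N^2 so the three loss
    # terms stay commensurate regardless of dataset size; "sum" uses it raw
    contrastive_scale: str = "mean"
    fusion_weights: tuple[float, float, float] = (0.5, 0.25, 0.25)  # (α, β, γ)
    hidden_dim: int = 256
    latent_dim: int = 64
    decoder_hidden: int = 128
    use_image: bool = True
    use_gcn: bool = True
    use_attention: bool = True
    attention_scale: str = "dim"
    patience: int | None = None  # optional early stop on total loss
    device: str = "cpu"  # informational; the implementation is CPU numpy
    dtype: str = "float32"  # compute precision; "float64" for tight numerics

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainedModel:
    """Learned parameters, final embedding and the per-epoch loss telemetry."""

    parameters: dict
    embedding: np.ndarray
    loss_history: list[tuple[float, float, float, float]]  # (L_con, L_ZINB, L_rec, L)
    config_snapshot: dict
    zinb_mean: np.ndarray
    spot_ids: list[str] | None = None
    hvg_gene_ids: list[str] | None = field(default=None, repr=False)


class _Adam:
    """Standard Adam on a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, *betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class TrainingDivergedError(RuntimeError):
    pass


def train(
    ds: SRTDataset,
    g: SpatialGraph,
    H: np.ndarray | None = None,
    cfg: TrainConfig | None = None,
) -> TrainedModel:
    """Train the full model on a preprocessed dataset and its spatial graph.

    ``H`` overrides ``ds.image_features``; passing neither puts the model in
    expression-only mode regardless of ``cfg.use_image``.
    """
    cfg = cfg or TrainConfig()
    if ds.norm_expr is None or ds.hvg_raw_counts is None:
        raise ValueError("dataset must be preprocessed first (see stmmr.data.preprocess)")
    if g.norm_adj is None:
        raise ValueError("graph must be normalized first (see stmmr.graph.normalize_adjacency)")
    if g.n_spots != ds.n_spots:
        raise ValueError("graph and dataset were built on different spot sets")

    if H is None:
        H = ds.image_features
    use_image = cfg.use_image and H is not None

    enc_cfg = EncoderConfig(
        in_dim_expr=ds.norm_expr.shape[1],
        in_dim_img=None if not use_image else H.shape[1],
        hidden_dim=cfg.hidden_dim,
        latent_dim=cfg.latent_dim,
        decoder_hidden=cfg.decoder_hidden,
        use_image=use_image,
        use_gcn=cfg.use_gcn,
        use_attention=cfg.use_attention,
        attention_scale=cfg.attention_scale,
    )
    dtype = np.float32 if cfg.dtype == "float32" else np.float64
    rng = np.random.default_rng(cfg.seed)
    net = StmmrNetwork(enc_cfg, rng, dtype=dtype)
    opt = _Adam(net.parameters(), lr=cfg.learning_rate)

    lib = ds.library_sizes
    if lib is None:
        lib = np.asarray(ds.raw_counts).sum(axis=1).astype(np.float64)
    size_factors = (lib / np.median(lib)).astype(dtype)

    norm_adj = sp.csr_matrix(g.norm_adj).astype(dtype)  # graph propagation is sparse
    a_target = g.weights.astype(dtype)  # dense kernel matrix, reconstruction target
    counts = np.asarray(ds.hvg_raw_counts, dtype=dtype)
    expr = ds.norm_expr.astype(dtype)
    img = None if not use_image else np.asarray(H, dtype=dtype)
    a_w, b_w, c_w = cfg.loss_weights
    from scipy.special import gammaln

    lgamma_y1 = gammaln(counts + 1.0)  # constant term of the ZINB NLL

    n = ds.n_spots
    con_scale = 1.0 / (n * n) if cfg.contrastive_scale == "mean" else 1.0

    def forward():
        out = net.forward(expr, img, norm_adj, size_factors, cfg.fusion_weights)
        out["L_con"] = out["L_con"] * con_scale  # per-pair contrastive term
        l_zinb = zinb_nll(counts, out["zinb"], _lgamma_y1=lgamma_y1)
        l_rec = adjacency_loss(a_target, reconstruct_adjacency(out["Z"]))
        loss = total_loss(out["L_con"], l_zinb, l_rec, a_w, b_w, c_w)
        return out, l_zinb, l_rec, loss

    history: list[tuple[float, float, float, float]] = []
    best, since_best = np.inf, 0
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        out, l_zinb, l_rec, loss = forward()
        record = (float(out["L_con"]), float(l_zinb), float(l_rec), float(loss))
        if not np.isfinite(record).all():
            names = ("L_con", "L_ZINB", "L_rec", "L")
            bad = [n for n, v in zip(names, record) if not np.isfinite(v)]
            raise TrainingDivergedError(
                f"non-finite loss at epoch {epoch}: {', '.join(bad)} (record={record})"
            )
        loss.backward()
        opt.step()
        history.append(record)
        logger.debug("epoch %d: L_con=%.4g L_ZINB=%.4g L_rec=%.4g L=%.4g", epoch, *record)
        if cfg.patience is not None:
            if record[3] < best - 1e-9:
                best, since_best = record[3], 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    logger.info("early stop at epoch %d (no improvement for %d epochs)", epoch, cfg.patience)
                    break

    out, _, _, _ = forward()  # final states under the trained parameters
    return TrainedModel(
        parameters={k: v.data.copy() for k, v in net.params.items()},
        embedding=out["Z"].data.copy(),
        loss_history=history,
        config_snapshot=asdict(cfg) | {"use_image_effective": use_image},
        zinb_mean=out["zinb"].mean.data.copy(),
        spot_ids=list(ds.spot_ids),
        hvg_gene_ids=ds.hvg_gene_ids,
    )


def get_embedding(m: TrainedModel) -> np.ndarray:
    """The joint representation Z (spots × latent), ready for downstream use."""
    if m.embedding is None:
        raise ValueError("model has no embedding; train it first")
    return m.embedding


def run_pipeline(
    ds: SRTDataset,
    n_domains: int,
    cfg: TrainConfig | None = None,
    n_hvg: int = 3000,
    target_sum: float = 1e4,
    k_neighbors: int | None = 6,
    bandwidth: float | str = "auto",
    cluster_method: str = "gmm",
    image_pca_dim: int | None = 50,
    image_extractor: str = "stub",
    patch_side: int | None = None,
):
    """End-to-end convenience: preprocess → graph → train → cluster.

    Returns ``(DomainResult, TrainedModel)``.  When the dataset carries an
    H&E image but no precomputed per-spot features, patches are cropped at
    the spot coordinates (side from the Visium spot diameter when known,
    else 32 px) and featurized by the configured extractor.  High-dimensional
    image features (e.g. raw ViT outputs) are optionally PCA-reduced to
    ``image_pca_dim`` before encoding.
    """
    from .data import DomainResult, preprocess
    from .domains import cluster_embedding

    cfg = cfg or TrainConfig()
    if ds.norm_expr is None:
        ds = preprocess(ds, n_hvg=n_hvg, target_sum=target_sum)
    bw = auto_bandwidth(ds.coords) if bandwidth == "auto" else float(bandwidth)
    g = normalize_adjacency(gaussian_adjacency(ds.coords, bw, k_neighbors))

    H = ds.image_features
    if H is None and ds.image is not None and image_extractor is not None:
        from .histology import ViTExtractor, extract_patches, featurize, stub_extractor

        if patch_side is None:
            diameter = (ds.scalefactors or {}).get("spot_diameter_fullres")
            patch_side = int(round(diameter)) if diameter else 32
        ex = ViTExtractor() if image_extractor == "vit-adapter" else stub_extractor(64, seed=cfg.seed)
        H = featurize(extract_patches(ds.image, ds.coords, patch_side), ex)
    if H is not None and image_pca_dim is not None:
        n_comp = min(image_pca_dim, H.shape[0])
        if n_comp < H.shape[1]:
            from sklearn.decomposition import PCA

            H = PCA(n_components=n_comp, random_state=cfg.seed).fit_transform(H)

    model = train(ds, g, H=H, cfg=cfg)
    labels = cluster_embedding(model.embedding, n_domains, method=cluster_method, seed=cfg.seed)
    result = DomainResult(
        labels=labels, embedding=model.embedding, n_domains=n_domains, spot_ids=list(ds.spot_ids)
    )
    return result, model
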