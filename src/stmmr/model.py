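"""The stMMR network: encoders, attention, fusion, decoders and losses.

Architecture (one forward pass over the whole slice):

1.  Each modality (normalized expression ``G``, image features ``H``) is
    encoded by a two-layer GCN over the symmetrically normalized spatial
    adjacency: ``E = Ã_n · act(Ã_n · X · W0) · W1`` (no biases; first layer
    rectified, second linear), giving ``E_G`` and ``E_H``.
2.  A normalized self-attention module captures global spot–spot
    relationships within each modality:
    ``E_A = softmax(E·Eᵀ/√d) · E`` with ``d`` the latent dimension.
3.  Each encoder output is projected through a rectified affine head,
    ``Q = relu(E·W_Q + b_Q)``; the two projections are aligned by a
    similarity-contrastive loss, the squared Frobenius distance between the
    modalities' spot–spot cosine-similarity matrices.
4.  The projections are fused, ``E_Q = concat(Q_G, Q_H)·W_E + b_E``, and the
    joint representation is the weighted sum
    ``Z = α·E_Q + β·E_AH + γ·E_AG``.
5.  ``Z`` is decoded two ways: a ZINB head (mean/dispersion/dropout) scores
    the raw counts of the selected genes, and the adjacency is re-estimated
    as ``A' = sigmoid(cosine(Z_i, Z_j))`` and scored against the input graph
    by mean squared error.

The total objective is ``L = a·L_con + b·L_ZINB + c·L_rec``.

All operations accept plain numpy arrays or :class:`~stmmr._tensor.Tensor`
objects and return tensors, so the same code path serves unit tests (wrap,
compute, read ``.data``) and training (backpropagate through the tape).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, as_tensor, concat, spmm

__all__ = [
    "EncoderConfig",
    "ZINBParams",
    "gcn_encode",
    "self_attention",
    "project",
    "fuse",
    "combine",
    "contrastive_loss",
    "zinb_nll",
    "reconstruct_adjacency",
    "adjacency_loss",
    "total_loss",
    "StmmrNetwork",
]

EPS = 1e-12  # guard for all row normalizations


@dataclass
class EncoderConfig:
    """Shapes and switches of the network."""

    in_dim_expr: int
    in_dim_img: int | None
    hidden_dim: int = 256
    latent_dim: int = 64
    proj_dim: int | None = None  # defaults to latent_dim
    decoder_hidden: int = 128
    use_image: bool = True
    use_gcn: bool = True
    use_attention: bool = True
    attention_scale: str = "dim"  # {"dim", "distance-matrix"} (experimental)

    def __post_init__(self):
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be at least 2")
        if self.proj_dim is None:
            self.proj_dim = self.latent_dim
        if self.use_image and not self.in_dim_img:
            raise ValueError("use_image requires in_dim_img")


@dataclass
class ZINBParams:
    """Mean, dispersion and dropout of the zero-inflated NB reconstruction."""

    mean: object  # spots × P, > 0
    dispersion: object  # spots × P, > 0
    dropout: object  # spots × P, in (0, 1)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def gcn_encode(features, norm_adj, W0, W1, activation: str = "relu", propagate: bool = True) -> Tensor:
    """Two-layer graph-convolutional encoder.

    ``E1 = act(Ã_n · X · W0)``, ``E2 = Ã_n · E1 · W1`` (second layer linear,
    no biases).  With ``propagate=False`` the adjacency products are skipped
    and the encoder degenerates to a per-spot two-layer map (the "without
    GCN" ablation).
    """
    x, w0, w1 = as_tensor(features), as_tensor(W0), as_tensor(W1)
    h = spmm(norm_adj, x) if propagate else x
    h = h @ w0
    if activation == "relu":
        h = h.relu()
    elif activation != "linear":
        raise ValueError(f"unknown activation {activation!r}")
    h = spmm(norm_adj, h) if propagate else h
    return h @ w1


def self_attention(E, scale: str = "dim") -> Tensor:
    """Normalized self-attention over spots: ``softmax(E·Eᵀ/√d) · E``.

    ``scale="dim"`` (default) divides the score matrix by the square root of
    the latent dimension; ``scale="distance-matrix"`` is an experimental
    variant dividing scores by the pairwise Euclidean distances between
    embedding rows (detached, epsilon-guarded, unit diagonal).  Output rows
    are convex combinations of input rows.
    """
    e = as_tensor(E)
    scores = e @ e.T
    if scale == "dim":
        scores = scores * (1.0 / np.sqrt(e.shape[1]))
    elif scale == "distance-matrix":
        x = e.data
        sq = (x**2).sum(axis=1)
        d = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2.0 * (x @ x.T), 0.0))
        np.fill_diagonal(d, 1.0)
        scores = scores * (1.0 / np.maximum(d, EPS))
    else:
        raise ValueError(f"unknown attention scale {scale!r}")
    return scores.row_softmax() @ e


def project(E, W_Q, b_Q) -> Tensor:
    """Rectified affine projection head ``Q = relu(E·W_Q + b_Q)``."""
    return (as_tensor(E) @ as_tensor(W_Q) + as_tensor(b_Q)).relu()


def fuse(Q_G, Q_H, W_E, b_E) -> Tensor:
    """Cross-modal fusion ``E_Q = concat(Q_G, Q_H)·W_E + b_E`` (Q_G block first)."""
    qg, qh = as_tensor(Q_G), as_tensor(Q_H)
    if qg.shape != qh.shape:
        raise ValueError(f"projection shapes disagree: {qg.shape} vs {qh.shape}")
    return concat([qg, qh], axis=1) @ as_tensor(W_E) + as_tensor(b_E)


def combine(E_Q, E_AH, E_AG, alpha: float, beta: float, gamma: float) -> Tensor:
    """Joint representation ``Z = α·E_Q + β·E_AH + γ·E_AG``."""
    return alpha * as_tensor(E_Q) + beta * as_tensor(E_AH) + gamma * as_tensor(E_AG)


def _row_normalize(t: Tensor) -> Tensor:
    norm = (t * t).sum(axis=1, keepdims=True).sqrt()
    return t / (norm + EPS)


def contrastive_loss(Q_G, Q_H) -> Tensor:
    """Similarity-contrastive alignment of the two modalities.

    Rows of each projection are scaled to unit L2 norm, making ``Q̃·Q̃ᵀ`` a
    spot–spot cosine-similarity matrix; the loss is the squared Frobenius
    norm of the difference between the two modalities' similarity matrices.
    Zero exactly when the similarity structures coincide (e.g. ``Q_H = c·Q_G``
    for any ``c > 0``).
    """
    sg = (lambda q: q @ q.T)(_row_normalize(as_tensor(Q_G)))
    sh = (lambda q: q @ q.T)(_row_normalize(as_tensor(Q_H)))
    diff = sg - sh
    return (diff * diff).sum()


def zinb_nll(counts, params: ZINBParams, _lgamma_y1: np.ndarray | None = None) -> Tensor:
    """Mean negative log-likelihood of counts under the ZINB model.

    For a count ``y`` with NB mean ``μ``, dispersion ``θ`` and zero-inflation
    ``π``::

        P(y) = π·[y = 0] + (1 − π)·NB(y; μ, θ)
        NB(y) = Γ(y+θ)/(Γ(θ) y!) · (θ/(θ+μ))^θ · (μ/(θ+μ))^y

    Everything is computed in log space; the ``y = 0`` case uses a stable
    log-sum-exp of the inflation and NB branches.  Returns the mean over all
    matrix entries.
    """
    from scipy.special import digamma, gammaln

    y = np.asarray(counts.data if isinstance(counts, Tensor) else counts)
    if (y < 0).any():
        raise ValueError("counts must be nonnegative")
    mu, theta, pi = as_tensor(params.mean), as_tensor(params.dispersion), as_tensor(params.dropout)
    # fused primitive: one vectorized forward, analytic gradients on backward
    m, t, p = (
        np.broadcast_to(mu.data, y.shape),
        np.broadcast_to(theta.data, y.shape),
        np.broadcast_to(pi.data, y.shape),
    )
    tm = t + m
    log_r = np.log(t + EPS) - np.log(tm + EPS)  # log(theta / (theta + mu))
    if _lgamma_y1 is None:
        _lgamma_y1 = gammaln(y + 1.0)  # constant in the parameters; cacheable
    log_nb = (
        gammaln(y + t)
        - gammaln(t)
        - _lgamma_y1
        + t * log_r
        + y * (np.log(m + EPS) - np.log(tm + EPS))
    )
    log_pi = np.log(p + EPS)
    log_1mpi = np.log(1.0 - p + EPS)
    zero = y == 0
    pos_ll = log_1mpi + log_nb
    loglik = np.where(zero, np.logaddexp(log_pi, pos_ll), pos_ll)
    nll = -loglik.mean()

    def backward(gout):
        scale = -float(gout) / y.size
        # NB-branch derivatives (valid for every entry; the y=0 branch gets
        # them weighted by the posterior probability of the NB component)
        g_t_nb = digamma(y + t) - digamma(t) + log_r + 1.0 - (t + y) / tm
        g_m_nb = y / (m + EPS) - (t + y) / tm
        w_nb = np.where(zero, np.exp(pos_ll - loglik), 1.0)
        d_t = w_nb * g_t_nb
        d_m = w_nb * g_m_nb
        w_pi = np.exp(log_pi - loglik)
        d_p = np.where(
            zero, w_pi / (p + EPS) - w_nb / (1.0 - p + EPS), -1.0 / (1.0 - p + EPS)
        )
        from ._tensor import _unbroadcast

        return (
            _unbroadcast(scale * d_m, mu.shape),
            _unbroadcast(scale * d_t, theta.shape),
            _unbroadcast(scale * d_p, pi.shape),
        )

    return Tensor._op(nll, (mu, theta, pi), backward)


def reconstruct_adjacency(Z) -> Tensor:
    """Estimate the adjacency from the embedding: ``A' = sigmoid(cos(Z_i, Z_j))``.

    Symmetric; entries lie in ``(sigmoid(−1), sigmoid(1))``; the diagonal is
    ``sigmoid(1) ≈ 0.7311``.
    """
    zn = _row_normalize(as_tensor(Z))
    return (zn @ zn.T).sigmoid()


def adjacency_loss(A, A_prime) -> Tensor:
    """Mean squared difference ``(1/N²) Σ_ij (A_ij − A'_ij)²``."""
    a, ap = as_tensor(A), as_tensor(A_prime)
    if a.shape != ap.shape:
        raise ValueError(f"adjacency shapes disagree: {a.shape} vs {ap.shape}")
    diff = a - ap
    return (diff * diff).mean(axis=None)


def total_loss(l_con, l_zinb, l_rec, a: float, b: float, c: float):
    """Weighted objective ``L = a·L_con + b·L_ZINB + c·L_rec``."""
    return a * as_tensor(l_con) + b * as_tensor(l_zinb) + c * as_tensor(l_rec)


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class StmmrNetwork:
    """Parameter container and forward pass of the full model.

    Weight matrices are Glorot-uniform initialized from a seeded generator;
    biases start at zero.  The three ablation switches of
    :class:`EncoderConfig` reproduce the "without histology", "without GCN"
    and "without attention" variants.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator, dtype=np.float64):
        self.cfg = cfg
        p: dict[str, Tensor] = {}

        def param(name, arr):
            p[name] = Tensor(np.asarray(arr, dtype=dtype), requires_grad=True)

        h, d, q = cfg.hidden_dim, cfg.latent_dim, cfg.proj_dim
        param("Wg0", _glorot(rng, cfg.in_dim_expr, h))
        param("Wg1", _glorot(rng, h, d))
        if cfg.use_image:
            param("Wh0", _glorot(rng, cfg.in_dim_img, h))
            param("Wh1", _glorot(rng, h, d))
        param("Wq_g", _glorot(rng, d, q))
        param("bq_g", np.zeros(q))
        if cfg.use_image:
            param("Wq_h", _glorot(rng, d, q))
            param("bq_h", np.zeros(q))
            param("We", _glorot(rng, 2 * q, d))
        else:
            param("We", _glorot(rng, q, d))  # expression-only fusion head
        param("be", np.zeros(d))
        dh = cfg.decoder_hidden
        param("Wd", _glorot(rng, d, dh))
        param("bd", np.zeros(dh))
        for head in ("mean", "disp", "drop"):
            param(f"W_{head}", _glorot(rng, dh, cfg.in_dim_expr))
            param(f"b_{head}", np.zeros(cfg.in_dim_expr))
        self.params = p

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def forward(
        self,
        G: np.ndarray,
        H: np.ndarray | None,
        norm_adj,
        size_factors: np.ndarray,
        fusion_weights: tuple[float, float, float],
    ) -> dict:
        """One full forward pass; returns all intermediate representations."""
        cfg, p = self.cfg, self.params
        alpha, beta, gamma = fusion_weights

        e_g = gcn_encode(G, norm_adj, p["Wg0"], p["Wg1"], propagate=cfg.use_gcn)
        e_ag = self_attention(e_g, cfg.attention_scale) if cfg.use_attention else e_g
        q_g = project(e_g, p["Wq_g"], p["bq_g"])

        if cfg.use_image:
            if H is None:
                raise ValueError("model configured with use_image but no image features given")
            e_h = gcn_encode(H, norm_adj, p["Wh0"], p["Wh1"], propagate=cfg.use_gcn)
            e_ah = self_attention(e_h, cfg.attention_scale) if cfg.use_attention else e_h
            q_h = project(e_h, p["Wq_h"], p["bq_h"])
            e_q = fuse(q_g, q_h, p["We"], p["be"])
            l_con = contrastive_loss(q_g, q_h)
            z = combine(e_q, e_ah, e_ag, alpha, beta, gamma)
        else:
            # expression-only degenerate form: no image path, no β term
            e_h = e_ah = q_h = None
            e_q = q_g @ p["We"] + p["be"]
            l_con = Tensor(0.0)
            z = alpha * e_q + gamma * e_ag

        d_hidden = (z @ p["Wd"] + p["bd"]).relu()
        sf = as_tensor(size_factors[:, None])
        mean = sf * (d_hidden @ p["W_mean"] + p["b_mean"]).clip(-12.0, 12.0).exp()
        dispersion = (d_hidden @ p["W_disp"] + p["b_disp"]).softplus().clip(1e-4, 1e4)
        dropout = (d_hidden @ p["W_drop"] + p["b_drop"]).sigmoid()

        return {
            "E_G": e_g,
            "E_H": e_h,
            "E_AG": e_ag,
            "E_AH": e_ah,
            "Q_G": q_g,
            "Q_H": q_h,
            "E_Q": e_q,
            "Z": z,
            "L_con": l_con,
            "zinb": ZINBParams(mean=mean, dispersion=dispersion, dropout=dropout),
        }
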