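"""Synthetic multimodal SRT datasets with known domain structure.

The generator emulates the data model the method assumes: spots on a regular
grid, spatially contiguous domains (rectangular blocks), ZINB-distributed
counts whose negative-binomial mean is elevated for each domain's marker
genes, and per-spot image features that are a noisy linear encoding of domain
identity — so expression and "histology" carry consistent but complementary
domain signal, and the strength of the image channel is a dial
(``image_signal``).

Ground truth (labels and the noiseless NB mean matrix) is returned alongside
the dataset so recovery and denoising can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SRTDataset

__all__ = ["SynthConfig", "generate", "zero_fraction"]


@dataclass
class SynthConfig:
    """Generator settings; defaults give a strong-signal 4-domain dataset."""

    n_spots: int = 800
    grid_shape: tuple[int, int] = (20, 40)  # rows × cols; rows*cols == n_spots
    n_domains: int = 4
    n_genes: int = 500
    n_marker_per_domain: int = 25
    base_mean: float = 2.0  # NB mean of background genes
    fold_change: float = 4.0  # marker upregulation factor (> 1)
    dispersion: float = 2.0  # NB dispersion theta
    dropout: float = 0.3  # zero-inflation probability in [0, 1)
    image_signal: float = 0.8  # domain signal strength in image features, [0, 1]
    image_dim: int = 50
    seed: int = 0

    def validate(self) -> None:
        r, c = self.grid_shape
        if r * c != self.n_spots:
            raise ValueError(f"grid_shape {self.grid_shape} does not tile n_spots={self.n_spots}")
        if self.n_domains < 2:
            raise ValueError("need at least 2 domains")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if not 0 <= self.image_signal <= 1:
            raise ValueError("image_signal must lie in [0, 1]")
        if self.n_marker_per_domain * self.n_domains > self.n_genes:
            raise ValueError("more marker genes than genes")


def _block_labels(rows: int, cols: int, k: int) -> np.ndarray:
    """Tile the grid into K contiguous rectangular blocks (K domains).

    The grid is cut into ``kr`` row bands × ``kc`` column bands with
    ``kr * kc = K`` and ``kr`` the largest divisor of K not exceeding
    ``sqrt(K)``; bands are as equal as integer division allows.
    """
    kr = max(d for d in range(1, int(np.sqrt(k)) + 1) if k % d == 0)
    kc = k // kr
    row_band = np.minimum(np.arange(rows) * kr // rows, kr - 1)
    col_band = np.minimum(np.arange(cols) * kc // cols, kc - 1)
    return (row_band[:, None] * kc + col_band[None, :]).ravel()


def generate(cfg: SynthConfig) -> tuple[SRTDataset, np.ndarray, np.ndarray]:
    """Draw one synthetic dataset.

    Returns ``(dataset, true_labels, true_means)`` where ``true_means`` is the
    spots × genes noiseless NB mean matrix (before zero inflation).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([cc.ravel(), rr.ravel()]).astype(np.float64)  # (x, y)
    labels = _block_labels(rows, cols, cfg.n_domains)

    # per-domain mean profile: background base_mean, markers upregulated
    mean_profile = np.full((cfg.n_domains, cfg.n_genes), cfg.base_mean)
    for d in range(cfg.n_domains):
        lo = d * cfg.n_marker_per_domain
        mean_profile[d, lo : lo + cfg.n_marker_per_domain] *= cfg.fold_change
    true_means = mean_profile[labels]

    # ZINB draw: gamma-Poisson (NB) then independent dropout zeros
    theta = cfg.dispersion
    nb = rng.negative_binomial(theta, theta / (theta + true_means))
    drop = rng.random(nb.shape) < cfg.dropout
    counts = np.where(drop, 0, nb).astype(np.int64)

    # image features: noisy fixed linear encoding of domain identity
    enc = rng.normal(size=(cfg.n_domains, cfg.image_dim))
    noise = rng.normal(size=(cfg.n_spots, cfg.image_dim))
    image_features = cfg.image_signal * enc[labels] + (1.0 - cfg.image_signal) * noise

    ds = SRTDataset(
        spot_ids=[f"spot_{i:05d}" for i in range(cfg.n_spots)],
        raw_counts=counts,
        coords=coords,
        gene_ids=[f"gene_{j:04d}" for j in range(cfg.n_genes)],
        image_features=image_features,
        ground_truth=labels.copy(),
    )
    return ds, labels, true_means


def zero_fraction(ds: SRTDataset) -> float:
    """Fraction of zero entries in the raw count matrix (sparsity diagnostic)."""
    counts = np.asarray(ds.raw_counts)
    return float((counts == 0).mean())
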