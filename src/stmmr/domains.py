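"""Clustering of the joint embedding into spatial domains, and evaluation.

The default clustering is a seeded Gaussian mixture with K components and
full covariance (the mclust-style choice common in this method family);
k-means and Leiden community detection are exposed as alternatives (Leiden
finds its own number of communities and ignores K).  Agreement with a
reference partition is scored by the Adjusted Rand Index and normalized
mutual information, both label-permutation invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.mixture import GaussianMixture

from .train import TrainedModel

__all__ = [
    "EvalReport",
    "cluster_embedding",
    "adjusted_rand_index",
    "evaluate",
    "reconstructed_expression",
]


@dataclass
class EvalReport:
    """Partition-agreement metrics against a reference labeling."""

    ari: float
    nmi: float
    n_domains: int
    label_map: dict[int, int]  # cluster → best-matching reference label (display only)


def cluster_embedding(Z: np.ndarray, K: int, method: str = "gmm", seed: int = 0) -> np.ndarray:
    """Cluster the embedding into K domains; labels in ``0..K-1``.

    ``method="leiden"`` ignores K and returns the achieved community count.
    Deterministic given ``seed``.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if not np.isfinite(Z).all():
        raise ValueError("embedding contains non-finite values")
    n = Z.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds the number of spots ({n})")
    if K == 1 and method != "leiden":
        return np.zeros(n, dtype=int)

    if method == "gmm":
        gm = GaussianMixture(
            n_components=K,
            covariance_type="full",
            reg_covar=1e-4,
            n_init=5,
            init_params="k-means++",
            random_state=seed,
            max_iter=300,
        )
        return gm.fit_predict(Z).astype(int)
    if method == "kmeans":
        km = KMeans(n_clusters=K, n_init=10, random_state=seed)
        return km.fit_predict(Z).astype(int)
    if method == "leiden":
        return _leiden(Z, seed)
    raise ValueError(f"unknown clustering method {method!r}")


def _leiden(Z: np.ndarray, seed: int, n_neighbors: int = 15) -> np.ndarray:
    import igraph as ig
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    k = min(n_neighbors + 1, Z.shape[0])
    idx = NearestNeighbors(n_neighbors=k).fit(Z).kneighbors(Z, return_distance=False)[:, 1:]
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row}
    graph = ig.Graph(n=Z.shape[0], edges=sorted(edges))
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition, seed=seed
    )
    return np.asarray(part.membership, dtype=int)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model ARI from the contingency table of two partitions."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors differ in length")
    if labels_a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(labels_a, labels_b))


def evaluate(labels, reference, n_domains: int | None = None) -> EvalReport:
    """Score a domain labeling against a reference partition."""
    labels, reference = np.asarray(labels), np.asarray(reference)
    label_map = {}
    for c in np.unique(labels):
        ref, counts = np.unique(reference[labels == c], return_counts=True)
        label_map[int(c)] = int(ref[np.argmax(counts)])
    return EvalReport(
        ari=adjusted_rand_index(labels, reference),
        nmi=float(normalized_mutual_info_score(labels, reference)),
        n_domains=int(n_domains if n_domains is not None else np.unique(labels).size),
        label_map=label_map,
    )


def reconstructed_expression(m: TrainedModel) -> np.ndarray:
    """The ZINB mean matrix — the denoised expression profile (spots × P)."""
    if m.zinb_mean is None:
        raise ValueError("model has no reconstruction; train it first")
    return m.zinb_mean
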