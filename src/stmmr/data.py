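"""Loading, validation, normalization and export of SRT datasets.

Supported inputs are 10x Visium-style directories (matrix-market triplet or
HDF5 feature–barcode matrix plus a tissue-positions table) and a generic
tabular layout (counts CSV/MTX, coordinates CSV, optional precomputed per-spot
image-feature CSV).  Everything is held in :class:`SRTDataset`, a plain
container of aligned numpy arrays; row order is defined by the counts source
and all other tables are reindexed to it.

:func:`preprocess` applies the standard SRT recipe — library-size scaling to a
common target sum, ``log1p``, and dispersion-ranked selection of highly
variable genes (HVGs).  The raw counts of the selected genes are retained as
the reconstruction target of the ZINB decoder (counts are what a count
likelihood models), while the normalized matrix feeds the expression encoder.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "SRTDataset",
    "DomainResult",
    "load_visium",
    "load_tabular",
    "preprocess",
    "write_result",
]


@dataclass
class SRTDataset:
    """Aligned per-spot tables of one SRT slice.

    ``raw_counts`` is spots × genes (all genes); after :func:`preprocess`,
    ``norm_expr`` holds the log-normalized expression of the ``P`` selected
    HVGs (column order given by ``hvg_gene_ids``) and ``hvg_raw_counts`` the
    raw counts of those same genes.
    """

    spot_ids: list[str]
    raw_counts: np.ndarray
    coords: np.ndarray
    gene_ids: list[str]
    norm_expr: np.ndarray | None = None
    hvg_gene_ids: list[str] | None = None
    hvg_raw_counts: np.ndarray | None = None
    library_sizes: np.ndarray | None = None
    image_features: np.ndarray | None = None
    image: np.ndarray | None = field(default=None, repr=False)
    scalefactors: dict | None = None
    ground_truth: np.ndarray | None = None

    def __post_init__(self):
        self.raw_counts = np.asarray(self.raw_counts)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        n = self.raw_counts.shape[0]
        if len(self.spot_ids) != n or self.coords.shape[0] != n:
            raise ValueError("spot_ids / raw_counts / coords row counts disagree")
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicate spot identifiers")
        if self.raw_counts.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length does not match raw_counts columns")
        if (self.raw_counts < 0).any():
            raise ValueError("raw counts must be nonnegative")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain non-finite values")
        if self.image_features is not None:
            self.image_features = np.asarray(self.image_features, dtype=np.float64)
            if self.image_features.shape[0] != n:
                raise ValueError("image_features row count does not match spots")

    @property
    def n_spots(self) -> int:
        return self.raw_counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.raw_counts.shape[1]


@dataclass
class DomainResult:
    """Per-spot domain labels plus the joint embedding they came from."""

    labels: np.ndarray
    embedding: np.ndarray
    n_domains: int
    spot_ids: list[str] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape[0] != self.embedding.shape[0]:
            raise ValueError("labels and embedding row counts disagree")
        if self.labels.min(initial=0) < 0 or (
            self.labels.size and self.labels.max() >= self.n_domains
        ):
            raise ValueError("labels must lie in 0..K-1")


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _find_first(root: Path, names: list[str]) -> Path | None:
    for name in names:
        for cand in (root / name, root / "spatial" / name):
            if cand.exists():
                return cand
    return None


def _read_mtx_triplet(mtx_dir: Path):
    """Read a 10x matrix-market triplet directory (genes × barcodes)."""

    def pick(stems):
        for s in stems:
            for suffix in ("", ".gz"):
                p = mtx_dir / (s + suffix)
                if p.exists():
                    return p
        return None

    mtx = pick(["matrix.mtx"])
    barcodes = pick(["barcodes.tsv"])
    features = pick(["features.tsv", "genes.tsv"])
    if mtx is None or barcodes is None or features is None:
        missing = [
            n
            for n, p in [("matrix.mtx", mtx), ("barcodes.tsv", barcodes), ("features.tsv", features)]
            if p is None
        ]
        raise FileNotFoundError(f"Visium matrix directory {mtx_dir} is missing: {', '.join(missing)}")
    m = scipy.io.mmread(mtx).tocsr()
    with _open_maybe_gz(barcodes) as fh:
        bcs = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gz(features) as fh:
        genes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    counts = np.asarray(m.todense()).T  # -> spots × genes
    return counts, bcs, genes


def _read_positions(path: Path) -> pd.DataFrame:
    """Read a Visium tissue-positions table into (barcode, in_tissue, x, y)."""
    head = pd.read_csv(path, nrows=1, header=None)
    has_header = isinstance(head.iloc[0, 1], str)
    df = pd.read_csv(path, header=0 if has_header else None)
    df.columns = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"][
        : df.shape[1]
    ]
    return df


def load_visium(dir_path) -> "SRTDataset":
    """Load a 10x Visium-style directory into an :class:`SRTDataset`.

    The directory must contain a count matrix — either an HDF5 feature–barcode
    file (``*_feature_bc_matrix.h5``) or a matrix-market triplet directory —
    and a tissue-positions table.  Only in-tissue spots are kept; coordinates
    are the pixel coordinates ``(x, y) = (pxl_col, pxl_row)`` of the positions
    table.  The H&E image and scale-factors JSON are loaded when present.
    """
    root = Path(dir_path)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")

    counts = bcs = genes = None
    h5 = sorted(root.glob("*feature_bc_matrix.h5"))
    mtx_dirs = [
        d
        for d in [root / "filtered_feature_bc_matrix", root / "raw_feature_bc_matrix", root]
        if any(d.glob("matrix.mtx*"))
    ]
    if h5:
        import scanpy as sc

        adata = sc.read_10x_h5(h5[0])
        counts = np.asarray(
            adata.X.todense() if sp.issparse(adata.X) else adata.X
        )
        bcs = list(adata.obs_names)
        genes = list(adata.var_names)
    elif mtx_dirs:
        counts, bcs, genes = _read_mtx_triplet(mtx_dirs[0])
    else:
        raise FileNotFoundError(
            f"no count matrix (feature_bc_matrix.h5 or matrix.mtx triplet) found under {root}"
        )

    pos_path = _find_first(root, ["tissue_positions_list.csv", "tissue_positions.csv"])
    if pos_path is None:
        raise FileNotFoundError(f"no tissue positions table found under {root}")
    pos = _read_positions(pos_path)
    pos = pos[pos["in_tissue"] == 1]

    bc_index = {b: i for i, b in enumerate(bcs)}
    unmatched = [b for b in pos["barcode"] if b not in bc_index]
    if unmatched:
        raise ValueError(
            f"{len(unmatched)} in-tissue barcodes in {pos_path.name} are absent from the "
            f"count matrix (e.g. {unmatched[:3]})"
        )
    # keep matrix order restricted to in-tissue spots
    in_tissue = set(pos["barcode"])
    keep = [i for i, b in enumerate(bcs) if b in in_tissue]
    spot_ids = [bcs[i] for i in keep]
    pos = pos.set_index("barcode").loc[spot_ids]
    coords = pos[["pxl_col", "pxl_row"]].to_numpy(dtype=np.float64)

    image = None
    img_path = _find_first(
        root, ["tissue_hires_image.png", "tissue_lowres_image.png", "image.png", "image.tiff"]
    )
    if img_path is not None:
        from PIL import Image

        image = np.asarray(Image.open(img_path).convert("RGB"))

    scalefactors = None
    sf_path = _find_first(root, ["scalefactors_json.json"])
    if sf_path is not None:
        with open(sf_path) as fh:
            scalefactors = json.load(fh)

    return SRTDataset(
        spot_ids=spot_ids,
        raw_counts=counts[keep],
        coords=coords,
        gene_ids=genes,
        image=image,
        scalefactors=scalefactors,
    )


def load_tabular(counts_path, coords_path, image_features_path=None) -> "SRTDataset":
    """Load a generic tabular dataset (counts + coordinates [+ features]).

    ``counts_path`` is a CSV with spot identifiers in the first column and
    gene identifiers as header, or a ``.mtx`` file with sidecars
    ``<stem>_spots.txt`` and ``<stem>_genes.txt``.  The coordinates CSV (and
    optional per-spot feature CSV) must carry the same identifiers in their
    first column; their rows are reindexed to the counts order.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        m = scipy.io.mmread(counts_path).tocsr()
        stem = counts_path.with_suffix("")
        spot_ids = Path(f"{stem}_spots.txt").read_text().split()
        gene_ids = Path(f"{stem}_genes.txt").read_text().split()
        counts = np.asarray(m.todense())
    else:
        df = pd.read_csv(counts_path, index_col=0)
        spot_ids = [str(s) for s in df.index]
        gene_ids = [str(g) for g in df.columns]
        counts = df.to_numpy()

    coords_df = pd.read_csv(coords_path, index_col=0)
    coords_df.index = coords_df.index.astype(str)
    missing = [s for s in spot_ids if s not in coords_df.index]
    extra = [s for s in coords_df.index if s not in set(spot_ids)]
    if missing or extra:
        raise ValueError(
            f"spot identifiers disagree between counts and coordinates: "
            f"{len(missing)} missing from coords (e.g. {missing[:3]}), "
            f"{len(extra)} extra in coords (e.g. {extra[:3]})"
        )
    coords = coords_df.loc[spot_ids].iloc[:, :2].to_numpy(dtype=np.float64)

    image_features = None
    if image_features_path is not None:
        feat_df = pd.read_csv(image_features_path, index_col=0)
        feat_df.index = feat_df.index.astype(str)
        missing = [s for s in spot_ids if s not in feat_df.index]
        if missing:
            raise ValueError(
                f"{len(missing)} spots have no image features (e.g. {missing[:3]})"
            )
        image_features = feat_df.loc[spot_ids].to_numpy(dtype=np.float64)

    return SRTDataset(
        spot_ids=spot_ids,
        raw_counts=counts,
        coords=coords,
        gene_ids=gene_ids,
        image_features=image_features,
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess(ds: SRTDataset, n_hvg: int = 3000, target_sum: float = 1e4) -> SRTDataset:
    """Normalize counts and select highly variable genes.

    Every spot is scaled so its total count equals ``target_sum``, then
    ``log1p`` is applied.  Genes are ranked by dispersion (variance/mean of
    the scaled, pre-log expression) and the top ``n_hvg`` with nonzero
    variance are kept; ``P = min(n_hvg, #genes with nonzero variance)``.
    Spots with zero total counts are dropped with a warning.
    """
    if n_hvg < 1 or target_sum <= 0:
        raise ValueError("n_hvg and target_sum must be positive")
    counts = np.asarray(ds.raw_counts, dtype=np.float64)
    lib = counts.sum(axis=1)
    keep = lib > 0
    if not keep.all():
        logger.warning("dropping %d spot(s) with zero total counts", int((~keep).sum()))
        ds = replace(
            ds,
            spot_ids=[s for s, k in zip(ds.spot_ids, keep) if k],
            raw_counts=ds.raw_counts[keep],
            coords=ds.coords[keep],
            image_features=None if ds.image_features is None else ds.image_features[keep],
            ground_truth=None if ds.ground_truth is None else ds.ground_truth[keep],
        )
        counts = counts[keep]
        lib = lib[keep]

    scaled = counts * (target_sum / lib)[:, None]
    mean = scaled.mean(axis=0)
    var = scaled.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    eligible = var > 0
    p = min(n_hvg, int(eligible.sum()))
    if p == 0:
        raise ValueError("no gene has nonzero variance; cannot select HVGs")
    ranked = np.argsort(-np.where(eligible, dispersion, -np.inf), kind="stable")
    hvg_idx = np.sort(ranked[:p])  # keep original gene order within the subset

    return replace(
        ds,
        norm_expr=np.log1p(scaled[:, hvg_idx]),
        hvg_gene_ids=[ds.gene_ids[i] for i in hvg_idx],
        hvg_raw_counts=np.asarray(ds.raw_counts)[:, hvg_idx],
        library_sizes=lib,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_result(res: DomainResult, out_dir) -> None:
    """Write ``labels.csv`` (spot_id, domain) and ``embedding.csv``.

    Output is deterministic for fixed inputs (fixed float formatting, fixed
    row order).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        spot_ids = res.spot_ids or [f"spot_{i}" for i in range(len(res.labels))]
        with open(out / "labels.csv", "w") as fh:
            fh.write("spot_id,domain\n")
            for s, l in zip(spot_ids, res.labels):
                fh.write(f"{s},{int(l)}\n")
        emb = np.asarray(res.embedding, dtype=np.float64)
        header = "spot_id," + ",".join(f"dim_{j}" for j in range(emb.shape[1]))
        with open(out / "embedding.csv", "w") as fh:
            fh.write(header + "\n")
            for s, row in zip(spot_ids, emb):
                fh.write(s + "," + ",".join(f"{v:.10g}" for v in row) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write results under {out}: {exc}") from exc


def write_result_h5(res: DomainResult, path) -> None:
    """Write the full result (labels, embedding, spot ids, K) as one HDF5 file."""
    import h5py

    spot_ids = res.spot_ids or [f"spot_{i}" for i in range(len(res.labels))]
    with h5py.File(path, "w") as fh:
        fh.create_dataset("labels", data=np.asarray(res.labels, dtype=np.int64))
        fh.create_dataset("embedding", data=np.asarray(res.embedding, dtype=np.float64))
        fh.create_dataset("spot_ids", data=np.array(spot_ids, dtype="S"))
        fh.attrs["n_domains"] = int(res.n_domains)


def write_tabular(ds: SRTDataset, out_dir, prefix: str = "data") -> dict:
    """Write a dataset in the tabular layout read by :func:`load_tabular`.

    Returns the paths written (keys: counts, coords, optionally features,
    truth).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    counts_df = pd.DataFrame(ds.raw_counts, index=ds.spot_ids, columns=ds.gene_ids)
    paths["counts"] = out / f"{prefix}_counts.csv"
    counts_df.to_csv(paths["counts"])
    coords_df = pd.DataFrame(ds.coords, index=ds.spot_ids, columns=["x", "y"])
    paths["coords"] = out / f"{prefix}_coords.csv"
    coords_df.to_csv(paths["coords"])
    if ds.image_features is not None:
        feat_df = pd.DataFrame(
            ds.image_features,
            index=ds.spot_ids,
            columns=[f"f_{j}" for j in range(ds.image_features.shape[1])],
        )
        paths["features"] = out / f"{prefix}_image_features.csv"
        feat_df.to_csv(paths["features"])
    if ds.ground_truth is not None:
        truth_df = pd.DataFrame({"domain": ds.ground_truth}, index=ds.spot_ids)
        paths["truth"] = out / f"{prefix}_truth.csv"
        truth_df.to_csv(paths["truth"])
    return paths
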