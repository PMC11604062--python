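"""Loaders, preprocessing (normalization + HVG selection) and writers."""

import logging

import numpy as np
import pandas as pd
import pytest

import stmmr
from stmmr.data import DomainResult, load_tabular, load_visium, preprocess, write_result, write_tabular


@pytest.fixture
def toy_ds():
    counts = np.array(
        [
            [10, 0, 5, 1, 0],
            [0, 2, 50, 3, 0],
            [4, 1, 0, 2, 0],
        ]
    )
    return stmmr.SRTDataset(
        spot_ids=["s1", "s2", "s3"],
        raw_counts=counts,
        coords=np.array([[0.0, 0], [1, 0], [0, 1]]),
        gene_ids=[f"g{i}" for i in range(5)],
    )


# -- tabular round trip ------------------------------------------------------


def test_tabular_round_trip_exact(tmp_path):
    ds, _, _ = stmmr.generate(stmmr.SynthConfig(n_spots=24, grid_shape=(4, 6), n_genes=30, n_marker_per_domain=4, seed=3))
    paths = write_tabular(ds, tmp_path)
    back = load_tabular(paths["counts"], paths["coords"], paths["features"])
    np.testing.assert_array_equal(back.raw_counts, ds.raw_counts)
    np.testing.assert_array_equal(back.coords, ds.coords)
    np.testing.assert_allclose(back.image_features, ds.image_features)
    assert back.spot_ids == ds.spot_ids


def test_tabular_shuffled_coords_reindexed(tmp_path):
    ds, _, _ = stmmr.generate(stmmr.SynthConfig(n_spots=12, grid_shape=(3, 4), n_genes=10, n_marker_per_domain=2, seed=1))
    paths = write_tabular(ds, tmp_path)
    coords_df = pd.read_csv(paths["coords"], index_col=0)
    shuffled = coords_df.sample(frac=1.0, random_state=0)
    shuffled.to_csv(tmp_path / "shuffled.csv")
    back = load_tabular(paths["counts"], tmp_path / "shuffled.csv")
    np.testing.assert_array_equal(back.coords, ds.coords)  # row i matches counts row i


def test_tabular_id_mismatch_reports_offenders(tmp_path):
    pd.DataFrame({"g0": [1, 2]}, index=["a", "b"]).to_csv(tmp_path / "counts.csv")
    pd.DataFrame({"x": [0, 1], "y": [0, 0]}, index=["a", "c"]).to_csv(tmp_path / "coords.csv")
    with pytest.raises(ValueError, match="b"):
        load_tabular(tmp_path / "counts.csv", tmp_path / "coords.csv")


def test_tabular_without_features_runs_expression_only(tmp_path):
    pd.DataFrame({"g0": [1, 2], "g1": [0, 3]}, index=["a", "b"]).to_csv(tmp_path / "counts.csv")
    pd.DataFrame({"x": [0, 1], "y": [0, 0]}, index=["a", "b"]).to_csv(tmp_path / "coords.csv")
    ds = load_tabular(tmp_path / "counts.csv", tmp_path / "coords.csv")
    assert ds.image_features is None and ds.n_spots == 2


# -- Visium loader -----------------------------------------------------------


def _write_visium_dir(tmp_path, n_positions_extra=0, barcodes=("AAA", "BBB", "CCC")):
    """Tiny matrix-market Visium layout: 5 genes × 3 barcodes, 3 in tissue."""
    mtx_dir = tmp_path / "filtered_feature_bc_matrix"
    mtx_dir.mkdir()
    # genes × spots triplets, 1-based; includes (gene 2, spot 1, value 7)
    (mtx_dir / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate integer general\n"
        "5 3 4\n"
        "2 1 7\n"
        "1 2 3\n"
        "5 3 2\n"
        "3 1 1\n"
    )
    (mtx_dir / "barcodes.tsv").write_text("\n".join(barcodes) + "\n")
    (mtx_dir / "features.tsv").write_text("\n".join(f"G{i}\tG{i}\tGene Expression" for i in range(5)) + "\n")
    spatial = tmp_path / "spatial"
    spatial.mkdir()
    rows = [f"{b},1,{i},{i},{10 * i + 5},{20 * i + 3}" for i, b in enumerate(barcodes)]
    for j in range(n_positions_extra):
        rows.append(f"EXTRA{j},1,9,9,99,99")
    (spatial / "tissue_positions_list.csv").write_text("\n".join(rows) + "\n")
    return tmp_path


def test_visium_mtx_load_shapes_and_values(tmp_path):
    import scipy.io

    d = _write_visium_dir(tmp_path)
    ds = load_visium(d)
    assert ds.raw_counts.shape == (3, 5)
    # independent dense read of the same MTX (genes × spots, transposed)
    dense = np.asarray(scipy.io.mmread(d / "filtered_feature_bc_matrix" / "matrix.mtx").todense()).T
    np.testing.assert_array_equal(ds.raw_counts, dense)
    assert ds.raw_counts[0, 1] == 7  # triplet entry (gene 2, spot 1, value 7)
    # pixel coordinates are (pxl_col, pxl_row)
    np.testing.assert_array_equal(ds.coords[1], [23, 15])


def test_visium_barcode_mismatch_is_fatal(tmp_path):
    d = _write_visium_dir(tmp_path, n_positions_extra=1)
    with pytest.raises(ValueError, match="1 in-tissue barcodes"):
        load_visium(d)


def test_visium_missing_components_are_fatal(tmp_path):
    with pytest.raises(FileNotFoundError, match="count matrix"):
        load_visium(tmp_path)  # empty dir
    d = _write_visium_dir(tmp_path)
    (d / "spatial" / "tissue_positions_list.csv").unlink()
    with pytest.raises(FileNotFoundError, match="positions"):
        load_visium(d)


# -- preprocessing -----------------------------------------------------------


def test_normalization_scale_factor_one_gives_log1p(toy_ds):
    lib0 = toy_ds.raw_counts[0].sum()  # 16
    out = preprocess(toy_ds, n_hvg=5, target_sum=float(lib0))
    cols = [toy_ds.gene_ids.index(g) for g in out.hvg_gene_ids]
    np.testing.assert_allclose(out.norm_expr[0], np.log1p(toy_ds.raw_counts[0, cols]))


def test_normalized_spot_sums_match_target(toy_ds):
    out = preprocess(toy_ds, n_hvg=5, target_sum=1e4)
    # invert log1p, sum over *all retained genes* == target_sum (P = all here
    # minus the constant gene, which contributes 0 after scaling anyway)
    back = np.expm1(out.norm_expr)
    lib = toy_ds.raw_counts.sum(axis=1)
    full_scaled = toy_ds.raw_counts * (1e4 / lib)[:, None]
    np.testing.assert_allclose(full_scaled.sum(axis=1), 1e4, rtol=1e-9)
    cols = [toy_ds.gene_ids.index(g) for g in out.hvg_gene_ids]
    np.testing.assert_allclose(back, full_scaled[:, cols], rtol=1e-9)


def test_constant_gene_never_selected(toy_ds):
    out = preprocess(toy_ds, n_hvg=5)
    assert "g4" not in out.hvg_gene_ids  # all-zero gene
    # and a constant nonzero gene is excluded too
    ds2 = stmmr.SRTDataset(
        spot_ids=toy_ds.spot_ids,
        raw_counts=np.column_stack([toy_ds.raw_counts[:, :4], [16, 55, 7]]),
        coords=toy_ds.coords,
        gene_ids=toy_ds.gene_ids,
    )
    # gene 4 is exactly proportional to library size -> zero variance after scaling
    out2 = preprocess(ds2, n_hvg=5, target_sum=100.0)
    assert "g4" not in out2.hvg_gene_ids


def test_hvg_ranking_matches_bruteforce_dispersion(toy_ds):
    out = preprocess(toy_ds, n_hvg=2, target_sum=100.0)
    scaled = toy_ds.raw_counts * (100.0 / toy_ds.raw_counts.sum(axis=1))[:, None]
    disp = np.zeros(5)
    for j in range(5):
        m, v = scaled[:, j].mean(), scaled[:, j].var()
        disp[j] = v / m if m > 0 else 0.0
    expected = {toy_ds.gene_ids[j] for j in np.argsort(-disp)[:2]}
    assert set(out.hvg_gene_ids) == expected


def test_zero_count_spot_dropped_with_warning(caplog):
    ds = stmmr.SRTDataset(
        spot_ids=["a", "b", "c"],
        raw_counts=np.array([[1, 2], [0, 0], [3, 1]]),
        coords=np.zeros((3, 2)),
        gene_ids=["g0", "g1"],
    )
    with caplog.at_level(logging.WARNING):
        out = preprocess(ds, n_hvg=2)
    assert out.n_spots == 2 and out.spot_ids == ["a", "c"]
    assert "1 spot" in caplog.text


def test_hvg_selection_idempotent(toy_ds):
    first = preprocess(toy_ds, n_hvg=3, target_sum=100.0)
    sub = stmmr.SRTDataset(
        spot_ids=first.spot_ids,
        raw_counts=first.hvg_raw_counts,
        coords=first.coords,
        gene_ids=first.hvg_gene_ids,
    )
    again = preprocess(sub, n_hvg=3, target_sum=100.0)
    assert set(again.hvg_gene_ids) == set(first.hvg_gene_ids)


# -- writers -----------------------------------------------------------------


def test_write_result_layout_and_determinism(tmp_path):
    res = DomainResult(
        labels=np.array([0, 1, 0]),
        embedding=np.arange(24, dtype=float).reshape(3, 8) / 7.0,
        n_domains=2,
        spot_ids=["a", "b", "c"],
    )
    write_result(res, tmp_path / "r1")
    write_result(res, tmp_path / "r2")
    lab = (tmp_path / "r1" / "labels.csv").read_text()
    assert lab.splitlines()[0] == "spot_id,domain" and len(lab.splitlines()) == 4
    assert lab == (tmp_path / "r2" / "labels.csv").read_text()  # byte-identical
    emb_header = (tmp_path / "r1" / "embedding.csv").read_text().splitlines()[0]
    assert emb_header.count(",") == 8  # spot_id + 8 value columns
    assert (tmp_path / "r1" / "embedding.csv").read_bytes() == (
        tmp_path / "r2" / "embedding.csv"
    ).read_bytes()


def test_write_result_h5_round_trip(tmp_path):
    import h5py

    from stmmr.data import write_result_h5

    res = DomainResult(
        labels=np.array([0, 1, 1]),
        embedding=np.arange(12, dtype=float).reshape(3, 4),
        n_domains=2,
        spot_ids=["a", "b", "c"],
    )
    write_result_h5(res, tmp_path / "result.h5")
    with h5py.File(tmp_path / "result.h5") as fh:
        np.testing.assert_array_equal(fh["labels"][:], res.labels)
        np.testing.assert_allclose(fh["embedding"][:], res.embedding)
        assert [s.decode() for s in fh["spot_ids"][:]] == ["a", "b", "c"]
        assert fh.attrs["n_domains"] == 2
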