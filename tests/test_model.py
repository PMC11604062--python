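"""Network building blocks and loss terms against closed forms and dense oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import softmax as sp_softmax

import stmmr
from stmmr.model import EPS


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# -- GCN encoder -------------------------------------------------------------


def test_gcn_identity_graph_identity_weights_is_identity():
    x = np.array([[1.5, -2.0]])
    out = stmmr.gcn_encode(x, np.eye(1), np.eye(2), np.eye(2), activation="linear")
    np.testing.assert_allclose(out.data, x)


def test_gcn_matches_dense_two_step_oracle(rng):
    # 3-node path graph, hand-set 2x2 weights
    a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    g = stmmr.normalize_adjacency(stmmr.SpatialGraph(weights=a, bandwidth=1.0))
    x = rng.normal(size=(3, 2))
    w0 = np.array([[0.5, -1.0], [2.0, 0.25]])
    w1 = np.array([[1.0, 0.0], [-0.5, 2.0]])
    out = stmmr.gcn_encode(x, g.norm_adj, w0, w1)
    h = np.maximum(g.norm_adj @ x @ w0, 0.0)
    np.testing.assert_allclose(out.data, g.norm_adj @ h @ w1, atol=1e-10)


def test_gcn_zero_features_zero_output(rng):
    out = stmmr.gcn_encode(np.zeros((4, 3)), np.eye(4), rng.normal(size=(3, 5)), rng.normal(size=(5, 2)))
    np.testing.assert_array_equal(out.data, 0.0)


# -- attention ---------------------------------------------------------------


def test_attention_single_spot_is_identity():
    e = np.array([[2.0, -1.0, 0.5]])
    np.testing.assert_allclose(stmmr.self_attention(e).data, e)


def test_attention_matches_manual_softmax(rng):
    e = np.array([[1.0, 0.0], [0.5, -1.0]])
    s = sp_softmax(e @ e.T / np.sqrt(2), axis=1)
    np.testing.assert_allclose(stmmr.self_attention(e).data, s @ e, atol=1e-12)
    e2 = rng.normal(size=(7, 4))
    s2 = sp_softmax(e2 @ e2.T / 2.0, axis=1)
    np.testing.assert_allclose(stmmr.self_attention(e2).data, s2 @ e2, atol=1e-10)


def test_attention_output_in_convex_hull(rng):
    e = rng.normal(size=(6, 3))
    out = stmmr.self_attention(e).data
    assert (out <= e.max(axis=0) + 1e-9).all() and (out >= e.min(axis=0) - 1e-9).all()


# -- projection / fusion / combination ---------------------------------------


def test_project_identity_and_rectification(rng):
    e = np.abs(rng.normal(size=(3, 4)))
    np.testing.assert_allclose(stmmr.project(e, np.eye(4), np.zeros(4)).data, e)
    out = stmmr.project(-e - 1.0, np.eye(4), np.zeros(4))
    np.testing.assert_array_equal(out.data, 0.0)
    w, b = rng.normal(size=(4, 2)), rng.normal(size=2)
    np.testing.assert_allclose(
        stmmr.project(e, w, b).data, np.maximum(e @ w + b, 0.0), atol=1e-12
    )


def test_fuse_block_selection_and_oracle(rng):
    qg, qh = rng.uniform(size=(3, 2)), rng.uniform(size=(3, 2))
    w_sel = np.vstack([np.eye(2), np.zeros((2, 2))])  # selects the Q_G block
    np.testing.assert_allclose(stmmr.fuse(qg, qh, w_sel, np.zeros(2)).data, qg)
    b = np.array([3.0, -1.0])
    np.testing.assert_allclose(
        stmmr.fuse(qg, qh, np.zeros((4, 2)), b).data, np.tile(b, (3, 1))
    )
    w = rng.normal(size=(4, 5))
    bb = rng.normal(size=5)
    np.testing.assert_allclose(
        stmmr.fuse(qg, qh, w, bb).data, np.concatenate([qg, qh], axis=1) @ w + bb, atol=1e-12
    )


def test_combine_weighted_sum(rng):
    eq, eah, eag = (rng.normal(size=(3, 2)) for _ in range(3))
    np.testing.assert_allclose(stmmr.combine(eq, eah, eag, 1, 0, 0).data, eq)
    np.testing.assert_array_equal(stmmr.combine(eq, eah, eag, 0, 0, 0).data, 0.0)
    np.testing.assert_allclose(stmmr.combine(eq, eah, eag, 1, 1, 1).data, eq + eah + eag)


# -- contrastive loss --------------------------------------------------------


def test_contrastive_fixed_point_and_scale_invariance(rng):
    q = rng.uniform(0.1, 1.0, size=(5, 3))
    assert float(stmmr.contrastive_loss(q, q)) == 0.0
    assert float(stmmr.contrastive_loss(q, 3.7 * q)) < 1e-10


def test_contrastive_orthogonal_vs_identical_rows_equals_two():
    qg = np.array([[1.0, 0.0], [0.0, 1.0]])  # similarity = I
    qh = np.array([[1.0, 1.0], [2.0, 2.0]])  # similarity = all-ones
    assert float(stmmr.contrastive_loss(qg, qh)) == pytest.approx(2.0, abs=1e-9)


# -- ZINB --------------------------------------------------------------------


def test_zinb_matches_scipy_pmf_oracle(rng):
    y = rng.poisson(3, size=(3, 4)).astype(float)
    mu = rng.uniform(0.5, 5, (3, 4))
    th = rng.uniform(0.5, 4, (3, 4))
    pi = rng.uniform(0.05, 0.6, (3, 4))
    nb = stats.nbinom.pmf(y, th, th / (th + mu))
    oracle = -np.log(pi * (y == 0) + (1 - pi) * nb).mean()
    assert float(stmmr.zinb_nll(y, stmmr.ZINBParams(mu, th, pi))) == pytest.approx(oracle, abs=1e-8)


def test_zinb_with_zero_inflation_off_is_plain_nb(rng):
    y = rng.poisson(2, size=(4, 3)).astype(float)
    mu = rng.uniform(0.5, 5, (4, 3))
    th = rng.uniform(0.5, 4, (4, 3))
    oracle = -stats.nbinom.logpmf(y, th, th / (th + mu)).mean()
    got = float(stmmr.zinb_nll(y, stmmr.ZINBParams(mu, th, np.zeros_like(mu))))
    assert got == pytest.approx(oracle, abs=1e-8)


def test_zinb_poisson_limit(rng):
    y = rng.poisson(4, size=(5, 5)).astype(float)
    lam = rng.uniform(1, 6, (5, 5))
    theta = np.full_like(lam, 1e6)
    got = float(stmmr.zinb_nll(y, stmmr.ZINBParams(lam, theta, np.zeros_like(lam))))
    assert got == pytest.approx(-stats.poisson.logpmf(y, lam).mean(), abs=1e-3)


def test_zinb_zero_count_bounded_by_inflation():
    # P(0) >= pi, so the NLL of a zero entry is at most -log(pi)
    val = float(stmmr.zinb_nll(np.array([[0.0]]), stmmr.ZINBParams(
        np.array([[50.0]]), np.array([[1.0]]), np.array([[0.5]]))))
    assert val <= -np.log(0.5) + 1e-9


def test_zinb_rejects_negative_counts():
    with pytest.raises(ValueError):
        stmmr.zinb_nll(np.array([[-1.0]]), stmmr.ZINBParams(
            np.array([[1.0]]), np.array([[1.0]]), np.array([[0.1]])))


# -- adjacency reconstruction ------------------------------------------------


def test_reconstruct_adjacency_fixed_points(rng):
    z_same = np.tile(rng.normal(size=(1, 4)), (3, 1))
    np.testing.assert_allclose(
        stmmr.reconstruct_adjacency(z_same).data, _sigmoid(1.0), atol=1e-9
    )
    z = np.array([[1.0, 0.0], [0.0, 1.0]])
    a = stmmr.reconstruct_adjacency(z).data
    assert a[0, 1] == pytest.approx(0.5, abs=1e-9)
    z_anti = np.array([[1.0, 0.0], [-1.0, 0.0]])
    a = stmmr.reconstruct_adjacency(z_anti).data
    assert a[0, 1] == pytest.approx(_sigmoid(-1.0), abs=1e-9)
    zr = rng.normal(size=(5, 3))
    ar = stmmr.reconstruct_adjacency(zr).data
    np.testing.assert_allclose(ar, ar.T, atol=1e-12)
    assert (ar > _sigmoid(-1.0) - 1e-9).all() and (ar < _sigmoid(1.0) + 1e-9).all()


def test_adjacency_loss_values():
    a = np.random.default_rng(0).uniform(size=(4, 4))
    assert float(stmmr.adjacency_loss(a, a)) == 0.0
    v = float(stmmr.adjacency_loss(np.array([[1.0]]), np.array([[_sigmoid(1.0)]])))
    assert v == pytest.approx((1 - _sigmoid(1.0)) ** 2, abs=1e-9)
    # mean normalization: same per-entry error at doubled N leaves loss unchanged
    e = 0.3
    small = float(stmmr.adjacency_loss(np.zeros((2, 2)), np.full((2, 2), e)))
    big = float(stmmr.adjacency_loss(np.zeros((4, 4)), np.full((4, 4), e)))
    assert small == pytest.approx(big, abs=1e-12)
    with pytest.raises(ValueError):
        stmmr.adjacency_loss(np.zeros((2, 2)), np.zeros((3, 3)))


def test_total_loss_weighted_sum_and_ablation_switches():
    assert float(stmmr.total_loss(1.0, 2.0, 3.0, 1, 1, 1)) == 6.0
    assert float(stmmr.total_loss(1.0, 2.0, 3.0, 0, 1, 1)) == 5.0  # no contrastive
    assert float(stmmr.total_loss(1.0, 2.0, 3.0, 1, 1, 0)) == 3.0  # no adjacency term


def test_losses_nonnegative_on_random_inputs(rng):
    for _ in range(5):
        q1, q2 = rng.uniform(0.1, 1, (4, 3)), rng.uniform(0.1, 1, (4, 3))
        assert float(stmmr.contrastive_loss(q1, q2)) >= 0.0
        a1, a2 = rng.uniform(size=(4, 4)), rng.uniform(size=(4, 4))
        assert float(stmmr.adjacency_loss(a1, a2)) >= 0.0
        y = rng.poisson(2, (3, 3)).astype(float)
        nll = float(stmmr.zinb_nll(y, stmmr.ZINBParams(
            rng.uniform(0.5, 3, (3, 3)), rng.uniform(0.5, 3, (3, 3)), rng.uniform(0.1, 0.9, (3, 3)))))
        assert nll >= 0.0
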