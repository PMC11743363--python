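"""Unit and property tests for the proxy-attention operator."""

import math

import numpy as np
import pytest

from proxyvit.attention import (AgentSet, AgentSource, AttentionConfig,
                                BiasTerm, PoolKind, ProjectionWeights,
                                TokenMatrix, agent_aggregate, agent_broadcast,
                                attention_cost, dense_oracle, downsample,
                                local_path, multi_head, proxy_attention,
                                proxy_attention_t, project_qkv,
                                scaled_attention, softmax_rows)
from proxyvit.autodiff import Tensor


def random_tokens(rng, n, d, grid=None):
    return TokenMatrix(rng.normal(size=(n, d)), grid)


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

def test_project_qkv_zero_and_identity(rng):
    W = ProjectionWeights(np.eye(2), np.eye(2), np.eye(2))
    X = TokenMatrix(np.zeros((3, 2)))
    q, k, v = project_qkv(X, W)
    assert not q.values.any() and not k.values.any() and not v.values.any()
    X2 = TokenMatrix(np.eye(2))
    q2, _, _ = project_qkv(X2, W)
    np.testing.assert_array_equal(q2.values, np.eye(2))


def test_project_qkv_matches_matrix_product(rng):
    X = random_tokens(rng, 4, 8)
    mats = [rng.normal(size=(8, 8)) for _ in range(3)]
    q, k, v = project_qkv(X, ProjectionWeights(*mats))
    for out, m in zip((q, k, v), mats):
        np.testing.assert_allclose(out.values, X.values @ m)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def test_downsample_max_of_all():
    T = TokenMatrix(np.array([[1.0], [2.0], [3.0], [4.0]]), (2, 2))
    a = downsample(T, (1, 1), "max")
    assert a.values.item() == 4.0


def test_downsample_identity_grid():
    rng = np.random.default_rng(0)
    T = random_tokens(rng, 9, 4, (3, 3))
    a = downsample(T, (3, 3), "max")
    np.testing.assert_array_equal(a.values, T.values)


@pytest.mark.parametrize("kind", ["max", "mean"])
def test_downsample_matches_window_scan(kind, rng):
    T = random_tokens(rng, 16, 5, (4, 4))
    a = downsample(T, (2, 2), kind)
    grid = T.values.reshape(4, 4, 5)
    for i in range(2):
        for j in range(2):
            win = grid[2 * i:2 * i + 2, 2 * j:2 * j + 2].reshape(4, 5)
            exp = win.max(axis=0) if kind == "max" else win.mean(axis=0)
            np.testing.assert_allclose(a.values[2 * i + j], exp)


def test_downsample_rejects_oversized_target(rng):
    T = random_tokens(rng, 4, 2, (2, 2))
    with pytest.raises(ValueError):
        downsample(T, (3, 3))


# ---------------------------------------------------------------------------
# softmax and the attention primitive
# ---------------------------------------------------------------------------

def test_softmax_rows_closed_forms():
    np.testing.assert_allclose(softmax_rows(np.zeros((1, 3))).weights,
                               np.full((1, 3), 1 / 3))
    assert softmax_rows(np.array([[7.0]])).weights.item() == 1.0
    w = softmax_rows(np.array([[1.0, 0.0]])).weights[0]
    e = math.e
    np.testing.assert_allclose(w, [e / (e + 1), 1 / (e + 1)], rtol=1e-12)


def test_softmax_rows_rejects_nonfinite():
    with pytest.raises(ValueError):
        softmax_rows(np.array([[np.inf, 0.0]]))


def test_scaled_attention_single_key_returns_value(rng):
    q = rng.normal(size=(3, 4))
    k = rng.normal(size=(1, 4))
    v = rng.normal(size=(1, 4))
    out = scaled_attention(q, k, v)
    np.testing.assert_allclose(out, np.repeat(v, 3, axis=0))


def test_scaled_attention_zero_query_gives_column_mean(rng):
    k = rng.normal(size=(5, 4))
    v = rng.normal(size=(5, 4))
    out = scaled_attention(np.zeros((2, 4)), k, v)
    np.testing.assert_allclose(out, np.repeat(v.mean(axis=0, keepdims=True),
                                              2, axis=0))


def test_scaled_attention_hand_computed_instance():
    q = np.array([[1.0, 0.0]])
    k = np.array([[1.0, 0.0], [0.0, 1.0]])
    v = np.array([[10.0, 0.0], [0.0, 10.0]])
    s = 1 / math.sqrt(2)
    w0 = math.exp(s) / (math.exp(s) + 1)
    expected = np.array([[10 * w0, 10 * (1 - w0)]])
    np.testing.assert_allclose(scaled_attention(q, k, v), expected, rtol=1e-12)


def test_scaled_attention_dimension_errors(rng):
    with pytest.raises(ValueError):
        scaled_attention(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)),
                         rng.normal(size=(2, 4)))
    with pytest.raises(ValueError):
        scaled_attention(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)),
                         rng.normal(size=(3, 3)))


# ---------------------------------------------------------------------------
# aggregation / broadcast / local path
# ---------------------------------------------------------------------------

def test_aggregate_single_pair_and_zero_values(rng):
    a1 = AgentSet(rng.normal(size=(1, 4)), AgentSource.QUERY_DERIVED, (1, 1))
    K = random_tokens(rng, 1, 4)
    V = TokenMatrix(rng.normal(size=(1, 4)))
    np.testing.assert_allclose(agent_aggregate(a1, K, V).values, V.values)
    Vz = TokenMatrix(np.zeros((6, 4)))
    Kz = random_tokens(rng, 6, 4)
    a6 = AgentSet(rng.normal(size=(2, 4)), AgentSource.QUERY_DERIVED, (1, 2))
    assert not agent_aggregate(a6, Kz, Vz).values.any()


def test_aggregate_matches_double_loop(rng):
    a1 = AgentSet(rng.normal(size=(4, 6)), AgentSource.QUERY_DERIVED, (2, 2))
    K = random_tokens(rng, 16, 6)
    V = random_tokens(rng, 16, 6)
    got = agent_aggregate(a1, K, V).values
    scale = 1 / math.sqrt(6)
    for i in range(4):
        logits = np.array([a1.values[i] @ K.values[j] * scale
                           for j in range(16)])
        w = np.exp(logits - logits.max())
        w /= w.sum()
        np.testing.assert_allclose(got[i], w @ V.values, rtol=1e-10)


def test_broadcast_trivial_and_loop(rng):
    # single agent: every output row equals the aggregated row
    a1 = AgentSet(rng.normal(size=(1, 4)), AgentSource.QUERY_DERIVED, (1, 1))
    va = TokenMatrix(rng.normal(size=(1, 4)))
    Q = random_tokens(rng, 5, 4)
    out = agent_broadcast(Q, a1, va)
    np.testing.assert_allclose(out.values, np.repeat(va.values, 5, axis=0))
    # zero queries: uniform weights -> column mean
    a3 = AgentSet(rng.normal(size=(3, 4)), AgentSource.QUERY_DERIVED, (1, 3))
    va3 = TokenMatrix(rng.normal(size=(3, 4)))
    out3 = agent_broadcast(TokenMatrix(np.zeros((2, 4))), a3, va3)
    np.testing.assert_allclose(out3.values,
                               np.repeat(va3.values.mean(0, keepdims=True),
                                         2, axis=0))


def test_local_path_identity_pooling_reduces_to_dense(rng):
    # agent grid == token grid: A2 = K and pooled V = V
    K = random_tokens(rng, 4, 3, (2, 2))
    V = random_tokens(rng, 4, 3, (2, 2))
    Q = random_tokens(rng, 4, 3, (2, 2))
    a2 = downsample(K, (2, 2), "max", AgentSource.KEY_DERIVED)
    out = local_path(Q, a2, V, "max")
    np.testing.assert_allclose(out.values,
                               scaled_attention(Q.values, K.values, V.values))


def test_local_path_single_agent_returns_pooled_value(rng):
    K = random_tokens(rng, 9, 3, (3, 3))
    V = random_tokens(rng, 9, 3, (3, 3))
    Q = random_tokens(rng, 9, 3, (3, 3))
    a2 = downsample(K, (1, 1), "max", AgentSource.KEY_DERIVED)
    out = local_path(Q, a2, V, "max")
    pooled = V.values.max(axis=0)
    np.testing.assert_allclose(out.values, np.repeat(pooled[None], 9, axis=0))


# ---------------------------------------------------------------------------
# full operator vs dense oracle
# ---------------------------------------------------------------------------

def test_proxy_attention_single_token_doubles_value(rng):
    cfg = AttentionConfig(d_model=3, n_agents=1)
    Q = random_tokens(rng, 1, 3, (1, 1))
    K = random_tokens(rng, 1, 3, (1, 1))
    V = random_tokens(rng, 1, 3, (1, 1))
    out = proxy_attention(Q, K, V, cfg)
    np.testing.assert_allclose(out.values, 2 * V.values, rtol=1e-12)


def test_proxy_attention_zero_values_gives_zero(rng):
    cfg = AttentionConfig(d_model=4, n_agents=4)
    Q = random_tokens(rng, 16, 4, (4, 4))
    K = random_tokens(rng, 16, 4, (4, 4))
    V = TokenMatrix(np.zeros((16, 4)), (4, 4))
    assert not proxy_attention(Q, K, V, cfg).values.any()


@pytest.mark.parametrize("n,d,n_a", [
    (4, 2, 1), (4, 2, 4), (4, 8, 1), (4, 32, 4),
    (16, 2, 4), (16, 8, 1), (16, 8, 4), (16, 8, 16), (16, 32, 4),
    (64, 2, 1), (64, 8, 4), (64, 32, 16), (64, 32, 64),
])
@pytest.mark.parametrize("with_bias", [False, True])
def test_proxy_attention_matches_dense_oracle(n, d, n_a, with_bias):
    rng = np.random.default_rng(1000 * n + 10 * d + n_a + int(with_bias))
    g = math.isqrt(n)
    cfg = AttentionConfig(d_model=d, n_agents=n_a,
                          agent_grid=None if math.isqrt(n_a) ** 2 == n_a
                          else (1, n_a))
    Q = random_tokens(rng, n, d, (g, g))
    K = random_tokens(rng, n, d, (g, g))
    V = random_tokens(rng, n, d, (g, g))
    bias = BiasTerm(agg_bias=rng.normal(size=(n_a, n)),
                    bcast_bias=rng.normal(size=(n, n_a))) if with_bias \
        else BiasTerm.none()
    fast = proxy_attention(Q, K, V, cfg, bias).values
    slow = dense_oracle(Q, K, V, cfg, bias).values
    assert np.abs(fast - slow).max() < 1e-5


def test_proxy_attention_rejects_too_many_agents(rng):
    cfg = AttentionConfig(d_model=2, n_agents=9)
    T = random_tokens(rng, 4, 2, (2, 2))
    with pytest.raises(ValueError):
        proxy_attention(T, T, T, cfg)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

def test_attention_maps_row_stochastic_many_instances():
    rng = np.random.default_rng(7)
    for _ in range(100):
        m, n = rng.integers(1, 12, size=2)
        w = softmax_rows(rng.normal(scale=5.0, size=(m, n))).weights
        assert (w >= 0).all()
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)


def test_output_rows_in_value_convex_hull():
    rng = np.random.default_rng(8)
    for _ in range(25):
        n, d = int(rng.integers(2, 10)), int(rng.integers(1, 6))
        q = rng.normal(size=(n, d))
        k = rng.normal(size=(n, d))
        v = rng.normal(size=(n, d))
        out = scaled_attention(q, k, v)
        assert (out >= v.min(axis=0) - 1e-6).all()
        assert (out <= v.max(axis=0) + 1e-6).all()


def test_value_column_permutation_equivariance(rng):
    # mean pooling, no bias: the value path is linear and columnwise
    cfg = AttentionConfig(d_model=6, n_agents=4, pool_kind=PoolKind.MEAN)
    Q = random_tokens(rng, 16, 6, (4, 4))
    K = random_tokens(rng, 16, 6, (4, 4))
    V = random_tokens(rng, 16, 6, (4, 4))
    perm = np.random.default_rng(3).permutation(6)
    base = proxy_attention(Q, K, V, cfg).values
    permuted = proxy_attention(
        Q, K, TokenMatrix(V.values[:, perm], (4, 4)), cfg).values
    np.testing.assert_allclose(permuted, base[:, perm], rtol=1e-10)


def test_gradient_check_through_proxy_attention(rng):
    q0 = rng.normal(size=(4, 3))
    k0 = rng.normal(size=(4, 3))
    v0 = rng.normal(size=(4, 3))
    w = rng.normal(size=(4, 3))

    def loss_of(qd, kd, vd):
        out = proxy_attention_t(Tensor(qd), Tensor(kd), Tensor(vd),
                                (2, 2), (1, 1), "max", 0.5)
        return float((out.data * w).sum())

    tensors = [Tensor(a, requires_grad=True) for a in (q0, k0, v0)]
    out = proxy_attention_t(*tensors, (2, 2), (1, 1), "max", 0.5)
    (out * Tensor(w)).sum().backward()
    eps = 1e-6
    for ti, arr in enumerate((q0, k0, v0)):
        num = np.zeros_like(arr)
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                args_p = [a.copy() for a in (q0, k0, v0)]
                args_m = [a.copy() for a in (q0, k0, v0)]
                args_p[ti][i, j] += eps
                args_m[ti][i, j] -= eps
                num[i, j] = (loss_of(*args_p) - loss_of(*args_m)) / (2 * eps)
        rel = np.abs(num - tensors[ti].grad).max() / max(np.abs(num).max(),
                                                         1e-12)
        assert rel < 1e-3


# ---------------------------------------------------------------------------
# multi-head and cost
# ---------------------------------------------------------------------------

def test_multi_head_single_head_equals_plain(rng):
    d = 8
    X = random_tokens(rng, 16, d, (4, 4))
    mats = [rng.normal(size=(d, d)) for _ in range(4)]
    W = ProjectionWeights(*mats)
    cfg = AttentionConfig(d_model=d, n_heads=1, n_agents=4)
    got = multi_head(X, W, cfg).values
    Q, K, V = project_qkv(X, W)
    exp = proxy_attention(Q, K, V, cfg).values @ mats[3]
    np.testing.assert_allclose(got, exp, rtol=1e-10)


def test_multi_head_duplicated_halves_match(rng):
    # both head slices carry identical projections -> identical head outputs
    d, dh = 8, 4
    X = random_tokens(rng, 16, d, (4, 4))
    blk = rng.normal(size=(d, dh))
    wq = np.concatenate([blk, blk], axis=1)
    W = ProjectionWeights(wq, wq.copy(), wq.copy(), np.eye(d))
    cfg = AttentionConfig(d_model=d, n_heads=2, n_agents=4)
    out = multi_head(X, W, cfg).values
    np.testing.assert_allclose(out[:, :dh], out[:, dh:], rtol=1e-10)


def test_multi_head_matches_per_head_manual(rng):
    d, h = 8, 2
    X = random_tokens(rng, 16, d, (4, 4))
    mats = [rng.normal(size=(d, d)) for _ in range(3)]
    wo = rng.normal(size=(d, d))
    W = ProjectionWeights(*mats, wo)
    cfg = AttentionConfig(d_model=d, n_heads=h, n_agents=4)
    got = multi_head(X, W, cfg).values
    Q, K, V = project_qkv(X, W)
    parts = []
    for i in range(h):
        cols = slice(i * 4, (i + 1) * 4)
        sub = AttentionConfig(d_model=4, n_heads=1, n_agents=4)
        parts.append(proxy_attention(
            TokenMatrix(Q.values[:, cols], (4, 4)),
            TokenMatrix(K.values[:, cols], (4, 4)),
            TokenMatrix(V.values[:, cols], (4, 4)), sub).values)
    np.testing.assert_allclose(got, np.concatenate(parts, axis=1) @ wo,
                               rtol=1e-10)


def test_attention_cost_formula_and_scaling():
    assert attention_cost(64, 32, 16) == (6 * 64 * 16 * 32, 2 * 64 * 64 * 32)
    for n in (4, 10, 64, 100):
        p1, s1 = attention_cost(n, 8, 4)
        p2, s2 = attention_cost(2 * n, 8, 4)
        assert p2 == 2 * p1
        assert s2 == 4 * s1
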