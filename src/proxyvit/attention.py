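"""Proxy attention: two-step agent attention with a key-derived local path.

Plain softmax attention couples every query with every key, which is
quadratic in the token count N. Agent (proxy) attention routes that
interaction through a small set of n_a pooled tokens instead:

1. *aggregation* — agents pooled from the queries attend over all
   keys/values, ``V_A = softmax(A1 K^T / sqrt(d)) V``;
2. *broadcast* — the original queries attend over the agents,
   ``O = softmax(Q A1^T / sqrt(d)) V_A``.

A second agent set pooled from the *keys* adds a local path,
``O += softmax(Q A2^T / sqrt(d)) V_pool``, where the values are pooled
with the same operator and grid as A2 so the product is well defined.
Both paths cost O(N * n_a * d), linear in N for fixed n_a.

Everything here is deterministic and in-memory; callers own all
randomness. The public API works on NumPy arrays wrapped in small
domain types; the differentiable path used by the transformer lives in
the tensor-level functions (`proxy_attention_t`), which the public API
calls with gradients disabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "AgentSource", "PoolKind", "TokenMatrix", "AgentSet", "AttentionMap",
    "ProjectionWeights", "BiasTerm", "AttentionConfig",
    "project_qkv", "downsample", "softmax_rows", "scaled_attention",
    "agent_aggregate", "agent_broadcast", "local_path", "proxy_attention",
    "dense_oracle", "multi_head", "attention_cost", "proxy_attention_t",
]


class AgentSource(str, Enum):
    QUERY_DERIVED = "query_derived"
    KEY_DERIVED = "key_derived"


class PoolKind(str, Enum):
    MAX = "max"
    MEAN = "mean"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TokenMatrix:
    """N x d token embeddings, optionally laid out on a 2-D patch grid."""

    values: np.ndarray
    grid_shape: Optional[tuple[int, int]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("TokenMatrix requires a 2-D array")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError("TokenMatrix requires N >= 1 and d >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TokenMatrix entries must be finite")
        if self.grid_shape is not None:
            r, c = self.grid_shape
            if r * c != n:
                raise ValueError(f"grid_shape {self.grid_shape} incompatible with N={n}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class AgentSet:
    """n_a x d pooled proxy tokens with their provenance and grid."""

    values: np.ndarray
    source: AgentSource
    origin_grid: tuple[int, int]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        r, c = self.origin_grid
        if r * c != self.values.shape[0]:
            raise ValueError("origin_grid inconsistent with agent count")

    @property
    def n_a(self) -> int:
        return self.values.shape[0]


@dataclass
class AttentionMap:
    """Row-stochastic attention weights (m queries x n keys)."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if np.any(w < 0):
            raise ValueError("attention weights must be nonnegative")
        if not np.allclose(w.sum(axis=-1), 1.0, atol=1e-6):
            raise ValueError("attention rows must sum to 1")
        self.weights = w


@dataclass
class ProjectionWeights:
    """Query/key/value (and optional output) projection matrices."""

    W_Q: np.ndarray
    W_K: np.ndarray
    W_V: np.ndarray
    W_O: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in ("W_Q", "W_K", "W_V"):
            m = np.asarray(getattr(self, name), dtype=np.float64)
            if not np.all(np.isfinite(m)):
                raise ValueError(f"{name} has non-finite entries")
            setattr(self, name, m)
        if self.W_Q.shape != self.W_K.shape or self.W_Q.shape != self.W_V.shape:
            raise ValueError("W_Q, W_K, W_V must share shape")
        if self.W_O is not None:
            self.W_O = np.asarray(self.W_O, dtype=np.float64)
            if self.W_O.shape[0] != self.W_Q.shape[1]:
                raise ValueError("W_O rows must match projection output dim")


@dataclass
class BiasTerm:
    """Additive pre-softmax logit biases for the two global-path steps.

    `agg_bias` is added to the aggregation logits (n_a x N); `bcast_bias`
    to the broadcast logits (N x n_a). Disabled => contributes zero.
    """

    agg_bias: Optional[np.ndarray] = None
    bcast_bias: Optional[np.ndarray] = None
    enabled: bool = True

    @classmethod
    def none(cls) -> "BiasTerm":
        return cls(enabled=False)

    def agg(self):
        return self.agg_bias if (self.enabled and self.agg_bias is not None) else None

    def bcast(self):
        return self.bcast_bias if (self.enabled and self.bcast_bias is not None) else None


@dataclass
class AttentionConfig:
    """Shape/behaviour knobs for the proxy-attention operator.

    n_agents must factor into the agent grid; by default a square grid
    (so n_agents must be a perfect square unless agent_grid is given).
    """

    d_model: int
    n_heads: int = 1
    n_agents: int = 49
    agent_grid: Optional[tuple[int, int]] = None
    pool_kind: PoolKind = PoolKind.MAX
    scale: Optional[float] = None  # default 1/sqrt(d_head)

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.agent_grid is None:
            s = math.isqrt(self.n_agents)
            if s * s != self.n_agents:
                raise ValueError(
                    "n_agents must be a perfect square unless agent_grid is given")
            self.agent_grid = (s, s)
        r, c = self.agent_grid
        if r * c != self.n_agents:
            raise ValueError("agent_grid must multiply to n_agents")
        self.pool_kind = PoolKind(self.pool_kind)

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads

    def effective_scale(self) -> float:
        return self.scale if self.scale is not None else 1.0 / math.sqrt(self.d_head)


# ---------------------------------------------------------------------------
# tensor-level core (differentiable; supports leading batch dims)
# ---------------------------------------------------------------------------

def _swap_last(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return t.transpose(*axes)


def scaled_attention_t(q: Tensor, k: Tensor, v: Tensor, scale: float,
                       bias: Tensor | np.ndarray | None = None) -> Tensor:
    """softmax(q k^T * scale + bias) v on the last two axes."""
    logits = (q @ _swap_last(k)) * scale
    if bias is not None:
        logits = logits + (bias if isinstance(bias, Tensor) else Tensor(bias))
    return logits.softmax(-1) @ v


def proxy_attention_t(q: Tensor, k: Tensor, v: Tensor, grid: tuple[int, int],
                      agent_grid: tuple[int, int], pool_kind: str, scale: float,
                      agg_bias=None, bcast_bias=None, n_prefix: int = 0) -> Tensor:
    """Differentiable proxy attention on (..., n_prefix + rows*cols, d) tokens.

    The first `n_prefix` rows (e.g. a class token) are excluded from
    pooling; their key/value rows are appended unchanged to the pooled
    key/value set of the local path and participate naturally in the
    aggregation step, which attends over the full key/value matrices.
    """
    sl = (Ellipsis, slice(n_prefix, None), slice(None))
    q_sp, k_sp, v_sp = q[sl], k[sl], v[sl]

    a1 = q_sp.pool_grid(grid, agent_grid, pool_kind)   # global agents
    a2 = k_sp.pool_grid(grid, agent_grid, pool_kind)   # local agents
    v_pool = v_sp.pool_grid(grid, agent_grid, pool_kind)

    # global path: aggregate over all keys/values, broadcast back to queries
    v_a = scaled_attention_t(a1, k, v, scale, agg_bias)
    out = scaled_attention_t(q, a1, v_a, scale, bcast_bias)

    # local path: queries over key-derived agents and equivalently pooled values
    if n_prefix:
        pre = (Ellipsis, slice(0, n_prefix), slice(None))
        k_loc = concat([k[pre], a2], axis=-2)
        v_loc = concat([v[pre], v_pool], axis=-2)
    else:
        k_loc, v_loc = a2, v_pool
    out = out + scaled_attention_t(q, k_loc, v_loc, scale, None)
    return out


# ---------------------------------------------------------------------------
# public (NumPy) operations
# ---------------------------------------------------------------------------

def project_qkv(X: TokenMatrix, W: ProjectionWeights
                ) -> tuple[TokenMatrix, TokenMatrix, TokenMatrix]:
    """Linear projections producing the query, key and value tokens."""
    if X.d != W.W_Q.shape[0]:
        raise ValueError(f"token dim {X.d} incompatible with W ({W.W_Q.shape[0]})")
    return (TokenMatrix(X.values @ W.W_Q, X.grid_shape),
            TokenMatrix(X.values @ W.W_K, X.grid_shape),
            TokenMatrix(X.values @ W.W_V, X.grid_shape))


def downsample(T: TokenMatrix, target_grid: tuple[int, int],
               pool_kind: PoolKind | str = PoolKind.MAX,
               source: AgentSource = AgentSource.QUERY_DERIVED) -> AgentSet:
    """Pool grid-shaped tokens down to an agent grid (per-dimension max/mean)."""
    if T.grid_shape is None:
        raise ValueError("downsample requires a TokenMatrix with grid_shape")
    kind = PoolKind(pool_kind).value
    pooled = Tensor(T.values).pool_grid(T.grid_shape, tuple(target_grid), kind)
    return AgentSet(pooled.data, AgentSource(source), tuple(target_grid))


def softmax_rows(logits: np.ndarray) -> AttentionMap:
    """Rowwise stable softmax; raises on non-finite logits."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("softmax_rows requires finite logits")
    return AttentionMap(Tensor(logits).softmax(-1).data)


def scaled_attention(Qr: np.ndarray, Kr: np.ndarray, Vr: np.ndarray,
                     scale: Optional[float] = None,
                     bias: Optional[np.ndarray] = None) -> np.ndarray:
    """softmax(Qr Kr^T / sqrt(d) + bias) Vr — the shared attention primitive."""
    Qr, Kr, Vr = (np.asarray(a, dtype=np.float64) for a in (Qr, Kr, Vr))
    if Qr.shape[-1] != Kr.shape[-1]:
        raise ValueError("query/key dimension mismatch")
    if Kr.shape[-2] != Vr.shape[-2]:
        raise ValueError("key/value row-count mismatch")
    if scale is None:
        scale = 1.0 / math.sqrt(Qr.shape[-1])
    return scaled_attention_t(Tensor(Qr), Tensor(Kr), Tensor(Vr), scale, bias).data


def agent_aggregate(A1: AgentSet, K: TokenMatrix, V: TokenMatrix,
                    bias: BiasTerm = BiasTerm.none(),
                    scale: Optional[float] = None) -> TokenMatrix:
    """Agents attend over the keys/values, yielding the n_a x d summary V_A."""
    if A1.source is not AgentSource.QUERY_DERIVED:
        raise ValueError("aggregation agents must be query-derived")
    out = scaled_attention(A1.values, K.values, V.values, scale, bias.agg())
    return TokenMatrix(out, A1.origin_grid)


def agent_broadcast(Q: TokenMatrix, A1: AgentSet, V_A: TokenMatrix,
                    bias: BiasTerm = BiasTerm.none(),
                    scale: Optional[float] = None) -> TokenMatrix:
    """Queries attend over the agents, spreading V_A back to all N tokens."""
    if V_A.n != A1.n_a:
        raise ValueError("V_A rows must match agent count")
    out = scaled_attention(Q.values, A1.values, V_A.values, scale, bias.bcast())
    return TokenMatrix(out, Q.grid_shape)


def local_path(Q: TokenMatrix, A2: AgentSet, V: TokenMatrix,
               pool_kind: PoolKind | str = PoolKind.MAX,
               scale: Optional[float] = None) -> TokenMatrix:
    """Local branch: V pooled with A2's operator/grid, then dense attention."""
    if A2.source is not AgentSource.KEY_DERIVED:
        raise ValueError("local-path agents must be key-derived")
    if V.grid_shape is None:
        raise ValueError("local_path requires grid-shaped values")
    v_pool = downsample(V, A2.origin_grid, pool_kind, AgentSource.KEY_DERIVED)
    out = scaled_attention(Q.values, A2.values, v_pool.values, scale)
    return TokenMatrix(out, Q.grid_shape)


def proxy_attention(Q: TokenMatrix, K: TokenMatrix, V: TokenMatrix,
                    cfg: AttentionConfig,
                    bias: BiasTerm = BiasTerm.none()) -> TokenMatrix:
    """Full proxy-attention operator (single head, spatial tokens only)."""
    if not (Q.n == K.n == V.n):
        raise ValueError("Q, K, V must share token count")
    if cfg.n_agents > Q.n:
        raise ValueError("n_agents may not exceed the token count")
    if Q.grid_shape is None:
        raise ValueError("proxy attention requires grid-shaped tokens")
    out = proxy_attention_t(
        Tensor(Q.values), Tensor(K.values), Tensor(V.values),
        Q.grid_shape, cfg.agent_grid, cfg.pool_kind.value,
        cfg.effective_scale(), bias.agg(), bias.bcast())
    return TokenMatrix(out.data, Q.grid_shape)


# ---------------------------------------------------------------------------
# dense reference oracle (explicit loops, for testing only)
# ---------------------------------------------------------------------------

def _loop_pool(x: np.ndarray, grid, target, kind: str) -> np.ndarray:
    r, c = grid
    tr, tc = target
    d = x.shape[1]
    xg = x.reshape(r, c, d)
    out = np.zeros((tr * tc, d))
    for i in range(tr):
        for j in range(tc):
            r0, r1 = (i * r) // tr, ((i + 1) * r) // tr
            c0, c1 = (j * c) // tc, ((j + 1) * c) // tc
            for dd in range(d):
                vals = []
                for rr in range(r0, r1):
                    for cc in range(c0, c1):
                        vals.append(xg[rr, cc, dd])
                if kind == "max":
                    best = vals[0]
                    for v in vals[1:]:
                        if v > best:
                            best = v
                    out[i * tc + j, dd] = best
                else:
                    out[i * tc + j, dd] = sum(vals) / len(vals)
    return out


def _loop_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray, scale: float,
                    bias: Optional[np.ndarray]) -> np.ndarray:
    m, d = q.shape
    n = k.shape[0]
    out = np.zeros((m, v.shape[1]))
    for i in range(m):
        logits = []
        for j in range(n):
            s = 0.0
            for dd in range(d):
                s += q[i, dd] * k[j, dd]
            s *= scale
            if bias is not None:
                s += bias[i, j]
            logits.append(s)
        mx = logits[0]
        for l in logits[1:]:
            if l > mx:
                mx = l
        exps = [math.exp(l - mx) for l in logits]
        z = sum(exps)
        for dd in range(v.shape[1]):
            acc = 0.0
            for j in range(n):
                acc += (exps[j] / z) * v[j, dd]
            out[i, dd] = acc
    return out


def dense_oracle(Q: TokenMatrix, K: TokenMatrix, V: TokenMatrix,
                 cfg: AttentionConfig,
                 bias: BiasTerm = BiasTerm.none()) -> TokenMatrix:
    """Loop-based reference for proxy_attention; small instances only."""
    if Q.n > 256:
        raise ValueError("dense_oracle is restricted to N <= 256")
    scale = cfg.effective_scale()
    kind = cfg.pool_kind.value
    a1 = _loop_pool(Q.values, Q.grid_shape, cfg.agent_grid, kind)
    a2 = _loop_pool(K.values, K.grid_shape, cfg.agent_grid, kind)
    v_pool = _loop_pool(V.values, V.grid_shape, cfg.agent_grid, kind)
    v_a = _loop_attention(a1, K.values, V.values, scale, bias.agg())
    out = _loop_attention(Q.values, a1, v_a, scale, bias.bcast())
    out = out + _loop_attention(Q.values, a2, v_pool, scale, None)
    return TokenMatrix(out, Q.grid_shape)


# ---------------------------------------------------------------------------
# multi-head wrapper and cost model
# ---------------------------------------------------------------------------

def multi_head(X: TokenMatrix, W: ProjectionWeights, cfg: AttentionConfig,
               bias: BiasTerm = BiasTerm.none()) -> TokenMatrix:
    """Split d_model into H head slices, run proxy attention per head,
    concatenate and apply the output projection."""
    if W.W_Q.shape[1] != cfg.d_model:
        raise ValueError("projection output dim must equal cfg.d_model")
    Q, K, V = project_qkv(X, W)
    dh = cfg.d_head
    heads = []
    for h in range(cfg.n_heads):
        cols = slice(h * dh, (h + 1) * dh)
        head_cfg = AttentionConfig(
            d_model=dh, n_heads=1, n_agents=cfg.n_agents,
            agent_grid=cfg.agent_grid, pool_kind=cfg.pool_kind, scale=cfg.scale)
        qh = TokenMatrix(Q.values[:, cols], Q.grid_shape)
        kh = TokenMatrix(K.values[:, cols], K.grid_shape)
        vh = TokenMatrix(V.values[:, cols], V.grid_shape)
        heads.append(proxy_attention(qh, kh, vh, head_cfg, bias).values)
    out = np.concatenate(heads, axis=1)
    if W.W_O is not None:
        out = out @ W.W_O
    return TokenMatrix(out, X.grid_shape)


def attention_cost(N: int, d: int, n_a: int) -> tuple[int, int]:
    """Multiply counts: proxy attention vs full softmax attention.

    Proxy: 2*n_a*N*d (aggregation) + 2*N*n_a*d (broadcast) + 2*N*n_a*d
    (local path) = 6*N*n_a*d. Full softmax: 2*N^2*d. Pooling cost is
    excluded by convention (documented constant).
    """
    if min(N, d, n_a) < 1:
        raise ValueError("N, d, n_a must all be >= 1")
    return 6 * N * n_a * d, 2 * N * N * d
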