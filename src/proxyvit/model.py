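"""Vision transformer with multi-head proxy attention.

Architecture: non-overlapping patch embedding, a learnable class token,
learnable (interpolatable) position embeddings, a stack of pre-norm
encoder blocks (multi-head proxy attention + GELU MLP, both residual),
a final layer norm and a linear head on the class token, softmax over
the C ordinal grades.

Defaults mirror the reference configuration: 256x256 input, patch 16,
depth 12, Adam-trainable under the categorical cross-entropy objective.
The model runs entirely on the NumPy autodiff core, in float64.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from . import __version__
from .attention import proxy_attention_t
from .autodiff import Tensor, concat

__all__ = [
    "ModelConfig", "ProbVector", "LabelVector", "one_hot",
    "ProxyViT", "patchify_pixels", "interpolate_pos_embed", "cross_entropy",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``n_agents`` defaults to a square agent grid of side min(7, grid//2)
    (49 agents for the standard 16x16 patch grid), kept well below the
    token count so the proxy path stays cheap.
    """

    image_size: int = 256
    patch_size: int = 16
    d_model: int = 64
    depth: int = 12
    heads: int = 4
    n_agents: Optional[int] = None
    mlp_ratio: float = 4.0
    n_classes: int = 5
    dropout: float = 0.0
    pool_kind: str = "max"
    bias_enabled: bool = True
    mean_pool_head: bool = False  # optional patch-pooled head, default off

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ValueError("image_size must be divisible by patch_size")
        if self.depth < 1 or self.heads < 1 or self.n_classes < 2:
            raise ValueError("require depth >= 1, heads >= 1, n_classes >= 2")
        if self.d_model % self.heads != 0:
            raise ValueError("d_model must be divisible by heads")
        if self.n_agents is None:
            side = max(1, min(7, self.grid_side // 2))
            self.n_agents = side * side
        s = math.isqrt(self.n_agents)
        if s * s != self.n_agents:
            raise ValueError("n_agents must be a perfect square")
        if self.n_agents > self.n_patches:
            raise ValueError("n_agents may not exceed the patch count")

    @property
    def grid_side(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.grid_side ** 2

    @property
    def agent_grid(self) -> tuple[int, int]:
        s = math.isqrt(self.n_agents)
        return (s, s)

    @property
    def d_head(self) -> int:
        return self.d_model // self.heads


@dataclass
class ProbVector:
    """Length-C probability vector (softmax output)."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        self.probs = p


@dataclass
class LabelVector:
    """One-hot ground-truth vector."""

    onehot: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.onehot, dtype=np.float64)
        nz = np.flatnonzero(y)
        if len(nz) != 1 or y[nz[0]] != 1.0:
            raise ValueError("onehot must have exactly one entry equal to 1")
        self.onehot = y


def one_hot(label: int, n_classes: int) -> LabelVector:
    y = np.zeros(n_classes)
    y[label] = 1.0
    return LabelVector(y)


# ---------------------------------------------------------------------------
# stateless pieces
# ---------------------------------------------------------------------------

def patchify_pixels(images: np.ndarray, patch_size: int) -> np.ndarray:
    """(B, S, S, 3) pixels -> (B, N, patch_size^2 * 3) flattened patches."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    b, h, w, c = images.shape
    if h != w:
        raise ValueError("square images required")
    if h % patch_size != 0:
        raise ValueError(
            f"image size {h} not divisible by patch size {patch_size}; resize first")
    g = h // patch_size
    x = images.reshape(b, g, patch_size, g, patch_size, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)  # (B, g, g, p, p, c)
    return x.reshape(b, g * g, patch_size * patch_size * c)


def _bilinear_grid_resize(field_2d: np.ndarray, new_grid: tuple[int, int]
                          ) -> np.ndarray:
    """Bilinearly resample (r, c, d) -> (r', c', d), align-corners convention."""
    r, c, d = field_2d.shape
    nr, nc = new_grid
    rows = np.linspace(0, r - 1, nr) if nr > 1 else np.array([(r - 1) / 2.0])
    cols = np.linspace(0, c - 1, nc) if nc > 1 else np.array([(c - 1) / 2.0])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = np.empty((nr, nc, d))
    for k in range(d):
        out[..., k] = map_coordinates(field_2d[..., k], [rr, cc], order=1,
                                      mode="nearest")
    return out


def interpolate_pos_embed(pos_embed: np.ndarray, new_grid: tuple[int, int],
                          src_grid: Optional[tuple[int, int]] = None
                          ) -> np.ndarray:
    """Resample patch position embeddings to a new grid.

    The first row is the class-token embedding and passes through
    unchanged; the remaining rows are reshaped to the source grid,
    bilinearly resampled (align-corners), and flattened back.
    """
    pos_embed = np.asarray(pos_embed, dtype=np.float64)
    n_patch = pos_embed.shape[0] - 1
    if src_grid is None:
        s = math.isqrt(n_patch)
        if s * s != n_patch:
            raise ValueError("non-square source grid must be given explicitly")
        src_grid = (s, s)
    nr, nc = new_grid
    if nr < 1 or nc < 1:
        raise ValueError("degenerate target grid")
    if (nr, nc) == tuple(src_grid):
        return pos_embed.copy()
    field = pos_embed[1:].reshape(src_grid[0], src_grid[1], -1)
    resized = _bilinear_grid_resize(field, (nr, nc)).reshape(nr * nc, -1)
    return np.concatenate([pos_embed[:1], resized], axis=0)


def cross_entropy(y: LabelVector | np.ndarray, y_pred: ProbVector | np.ndarray,
                  eps: float = 1e-12) -> float:
    """Categorical negative log-likelihood -sum_i y_i log y'_i, y' clipped to [eps, 1]."""
    yv = y.onehot if isinstance(y, LabelVector) else np.asarray(y, dtype=np.float64)
    pv = y_pred.probs if isinstance(y_pred, ProbVector) else np.asarray(
        y_pred, dtype=np.float64)
    pv = np.clip(pv, eps, 1.0)
    return float(-(yv * np.log(pv)).sum())


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def _trunc_normal(rng: np.random.Generator, shape, std=0.02) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std)


class ProxyViT:
    """Proxy-attention vision transformer classifier."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d = cfg.d_model
        pdim = cfg.patch_size ** 2 * 3
        n_tok = cfg.n_patches + 1
        n_a = cfg.n_agents
        p: dict[str, Tensor] = {}
        p["patch_w"] = self._param(_trunc_normal(rng, (pdim, d)))
        p["patch_b"] = self._param(np.zeros(d))
        p["cls"] = self._param(_trunc_normal(rng, (1, d)))
        p["pos"] = self._param(_trunc_normal(rng, (n_tok, d)))
        for e in range(cfg.depth):
            pre = f"blk{e}_"
            p[pre + "ln1_g"] = self._param(np.ones(d))
            p[pre + "ln1_b"] = self._param(np.zeros(d))
            for nm in ("wq", "wk", "wv", "wo"):
                p[pre + nm] = self._param(_trunc_normal(rng, (d, d)))
            p[pre + "agg_bias"] = self._param(np.zeros((n_a, n_tok)))
            p[pre + "bcast_bias"] = self._param(np.zeros((n_tok, n_a)))
            p[pre + "ln2_g"] = self._param(np.ones(d))
            p[pre + "ln2_b"] = self._param(np.zeros(d))
            hidden = int(cfg.mlp_ratio * d)
            p[pre + "mlp_w1"] = self._param(_trunc_normal(rng, (d, hidden)))
            p[pre + "mlp_b1"] = self._param(np.zeros(hidden))
            p[pre + "mlp_w2"] = self._param(_trunc_normal(rng, (hidden, d)))
            p[pre + "mlp_b2"] = self._param(np.zeros(d))
        p["ln_f_g"] = self._param(np.ones(d))
        p["ln_f_b"] = self._param(np.zeros(d))
        p["head_w"] = self._param(_trunc_normal(rng, (d, cfg.n_classes)))
        p["head_b"] = self._param(np.zeros(cfg.n_classes))
        self.params = p
        # per-channel input standardization (set from the training split)
        self.input_mean = np.zeros(3)
        self.input_std = np.ones(3)
        self._recorded: list[Tensor] = []

    @staticmethod
    def _param(arr: np.ndarray) -> Tensor:
        return Tensor(arr, requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def set_input_stats(self, images: np.ndarray) -> None:
        """Fit the per-channel standardization to a set of training images."""
        images = np.asarray(images, dtype=np.float64)
        self.input_mean = images.mean(axis=tuple(range(images.ndim - 1)))
        std = images.std(axis=tuple(range(images.ndim - 1)))
        self.input_std = np.where(std < 1e-8, 1.0, std)

    # -- building blocks ------------------------------------------------
    @staticmethod
    def _layernorm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-6) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + eps).sqrt() * g + b

    def _attention(self, x: Tensor, e: int) -> Tensor:
        cfg = self.cfg
        p = self.params
        pre = f"blk{e}_"
        b, t, d = x.shape
        h, dh = cfg.heads, cfg.d_head
        q = x @ p[pre + "wq"]
        k = x @ p[pre + "wk"]
        v = x @ p[pre + "wv"]
        # (B, T, d) -> (B, H, T, dh)
        def split(z: Tensor) -> Tensor:
            return z.reshape(b, t, h, dh).transpose(0, 2, 1, 3)
        agg_bias = p[pre + "agg_bias"] if cfg.bias_enabled else None
        bcast_bias = p[pre + "bcast_bias"] if cfg.bias_enabled else None
        out = proxy_attention_t(
            split(q), split(k), split(v),
            grid=(cfg.grid_side, cfg.grid_side), agent_grid=cfg.agent_grid,
            pool_kind=cfg.pool_kind, scale=1.0 / math.sqrt(dh),
            agg_bias=agg_bias, bcast_bias=bcast_bias, n_prefix=1)
        out = out.transpose(0, 2, 1, 3).reshape(b, t, d)
        return out @ p[pre + "wo"]

    def _dropout(self, t: Tensor, drop_rng) -> Tensor:
        # inverted dropout; active only when a generator is supplied
        rate = self.cfg.dropout
        if drop_rng is None or rate <= 0.0:
            return t
        mask = (drop_rng.random(t.shape) >= rate) / (1.0 - rate)
        return t * Tensor(mask)

    def _block(self, x: Tensor, e: int, record: bool, drop_rng=None) -> Tensor:
        p = self.params
        pre = f"blk{e}_"
        attn = self._attention(self._layernorm(x, p[pre + "ln1_g"],
                                               p[pre + "ln1_b"]), e)
        if record:
            self._recorded.append(attn)
        x = x + self._dropout(attn, drop_rng)
        h = self._layernorm(x, p[pre + "ln2_g"], p[pre + "ln2_b"])
        h = (h @ p[pre + "mlp_w1"] + p[pre + "mlp_b1"]).gelu()
        h = h @ p[pre + "mlp_w2"] + p[pre + "mlp_b2"]
        return x + self._dropout(h, drop_rng)

    # -- forward ---------------------------------------------------------
    def forward_tensor(self, images: np.ndarray, record: bool = False,
                       drop_rng=None) -> Tensor:
        """(B, S, S, 3) pixels -> (B, C) probability Tensor.

        `drop_rng` enables dropout (training mode); inference passes None.
        """
        cfg = self.cfg
        self._recorded = []
        images = (np.asarray(images, dtype=np.float64) - self.input_mean) \
            / self.input_std
        patches = patchify_pixels(images, cfg.patch_size)
        b = patches.shape[0]
        x = Tensor(patches) @ self.params["patch_w"] + self.params["patch_b"]
        cls = self.params["cls"].reshape(1, 1, cfg.d_model)
        cls_rows = cls + Tensor(np.zeros((b, 1, cfg.d_model)))  # broadcast copy
        x = concat([cls_rows, x], axis=1)
        x = x + self.params["pos"]
        for e in range(cfg.depth):
            x = self._block(x, e, record, drop_rng)
        x = self._layernorm(x, self.params["ln_f_g"], self.params["ln_f_b"])
        if cfg.mean_pool_head:
            feat = x[:, 1:, :].mean(axis=1)
        else:
            feat = x[:, 0, :]
        logits = feat @ self.params["head_w"] + self.params["head_b"]
        return logits.softmax(-1)

    def forward(self, images: np.ndarray) -> np.ndarray:
        """Inference: (B, S, S, 3) or (S, S, 3) -> (B, C) probabilities."""
        return self.forward_tensor(images).data

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.forward(images)

    def recorded_attention(self) -> list[Tensor]:
        """Per-block attention outputs from the last recorded forward pass."""
        return self._recorded

    def batch_loss(self, images: np.ndarray, labels: np.ndarray,
                   record: bool = False, drop_rng=None) -> tuple[Tensor, Tensor]:
        """Mean cross-entropy over a batch; returns (loss, probs)."""
        probs = self.forward_tensor(images, record=record, drop_rng=drop_rng)
        y = np.zeros(probs.shape)
        y[np.arange(len(labels)), np.asarray(labels, dtype=int)] = 1.0
        loss = -((probs + 1e-12).log() * Tensor(y)).sum() * (1.0 / len(labels))
        return loss, probs

    # -- resolution change ----------------------------------------------
    def resize_tokens(self, new_image_size: int) -> None:
        """Adapt the model to a new input resolution.

        Position embeddings are bilinearly resampled to the new patch
        grid; the learnable attention-bias logit matrices are resampled
        along their token axis the same way (class row/column fixed).
        """
        cfg = self.cfg
        if new_image_size % cfg.patch_size != 0:
            raise ValueError("new size must be divisible by patch_size")
        old_side = cfg.grid_side
        new_side = new_image_size // cfg.patch_size
        if new_side == old_side:
            return
        new_grid = (new_side, new_side)
        self.params["pos"] = self._param(
            interpolate_pos_embed(self.params["pos"].data, new_grid,
                                  (old_side, old_side)))
        n_new = new_side ** 2
        for e in range(cfg.depth):
            pre = f"blk{e}_"
            ab = self.params[pre + "agg_bias"].data  # (n_a, 1 + N)
            cls_col, patch_cols = ab[:, :1], ab[:, 1:]
            fld = patch_cols.reshape(-1, old_side, old_side).transpose(1, 2, 0)
            rs = _bilinear_grid_resize(fld, new_grid)
            rs = rs.transpose(2, 0, 1).reshape(-1, n_new)
            self.params[pre + "agg_bias"] = self._param(
                np.concatenate([cls_col, rs], axis=1))
            bb = self.params[pre + "bcast_bias"].data  # (1 + N, n_a)
            cls_row, patch_rows = bb[:1], bb[1:]
            fld = patch_rows.reshape(old_side, old_side, -1)
            rs = _bilinear_grid_resize(fld, new_grid).reshape(n_new, -1)
            self.params[pre + "bcast_bias"] = self._param(
                np.concatenate([cls_row, rs], axis=0))
        cfg.image_size = new_image_size


# ---------------------------------------------------------------------------
# checkpoints: .npz weights + .json config sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(model: ProxyViT, path: str) -> None:
    path = str(path)
    if path.endswith(".npz"):
        path = path[:-4]
    np.savez(path + ".npz", _input_mean=model.input_mean,
             _input_std=model.input_std,
             **{k: v.data for k, v in model.params.items()})
    with open(path + ".json", "w") as fh:
        json.dump({"config": asdict(model.cfg), "version": __version__}, fh,
                  indent=2)


def load_checkpoint(path: str) -> ProxyViT:
    path = str(path)
    if path.endswith(".npz"):
        path = path[:-4]
    with open(path + ".json") as fh:
        meta = json.load(fh)
    cfg = ModelConfig(**meta["config"])
    model = ProxyViT(cfg, seed=0)
    with np.load(path + ".npz") as data:
        if "_input_mean" in data.files:
            model.input_mean = data["_input_mean"].astype(np.float64)
            model.input_std = data["_input_std"].astype(np.float64)
        for k, t in model.params.items():
            if k not in data.files:
                raise ValueError(f"checkpoint missing parameter {k!r}")
            if data[k].shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k!r}: "
                                 f"{data[k].shape} vs {t.data.shape}")
            t.data = data[k].astype(np.float64)
    return model
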