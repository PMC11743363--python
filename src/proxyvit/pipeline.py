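"""Training and evaluation orchestration.

Covers stratified k-fold splitting, augmentation with minority-class
emphasis, Adam training of the proxy-attention transformer under the
cross-entropy objective, the full metric report, cross-validation, and
Grad-CAM saliency maps. Every stochastic step draws from generators
derived from one user seed, so a rerun with the same config and seed is
bit-identical.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import rotate as nd_rotate, zoom as nd_zoom
from scipy.optimize import brentq
from sklearn.model_selection import KFold, StratifiedKFold

from .autodiff import Adam, Tensor
from .config import TrainConfig
from .data import Dataset
from .metrics import MetricsReport, report_from_predictions
from .model import ModelConfig, ProxyViT, _bilinear_grid_resize
from .synthetic import GradedImage, field_of_view_mask

__all__ = [
    "FoldSplit", "SaliencyMap", "TrainResult", "make_folds", "augment",
    "sample_batch", "train", "evaluate", "cross_validate", "gradcam",
]


@dataclass
class FoldSplit:
    fold_id: int
    train_ids: np.ndarray
    val_ids: np.ndarray

    def __post_init__(self):
        self.train_ids = np.asarray(self.train_ids, dtype=int)
        self.val_ids = np.asarray(self.val_ids, dtype=int)
        if np.intersect1d(self.train_ids, self.val_ids).size:
            raise ValueError("train and validation ids overlap")


@dataclass
class SaliencyMap:
    heat: np.ndarray
    source_layer: str


@dataclass
class TrainResult:
    model: ProxyViT
    log: list[dict]
    best_epoch: int
    best_val_acc: float


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def make_folds(labels: Sequence[int], k: int, seed: int) -> list[FoldSplit]:
    """Deterministic stratified partition into k folds.

    Falls back to a plain shuffled split (with a warning) when k exceeds
    the smallest class count, where stratification is impossible.
    """
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    min_class = np.bincount(y).min() if n else 0
    if min_class >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), y)
    else:
        warnings.warn("k exceeds the smallest class count; "
                      "falling back to unstratified folds", RuntimeWarning)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    return [FoldSplit(i, tr, va) for i, (tr, va) in enumerate(splits)]


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(img: GradedImage, cfg: TrainConfig,
            rng: np.random.Generator) -> GradedImage:
    """Random rotation / flips / central zoom; label unchanged.

    The result is re-masked to the circular field of view and clipped
    to [0, 1]. With all switches off this is the identity.
    """
    px = img.pixels
    size = px.shape[0]
    changed = False
    if cfg.rotate:
        angle = float(rng.uniform(-cfg.rotate_deg, cfg.rotate_deg))
        px = nd_rotate(px, angle, axes=(1, 0), reshape=False, order=1,
                       mode="constant", cval=0.0)
        changed = True
    if cfg.flip:
        if rng.random() < 0.5:
            px = px[:, ::-1]
        if rng.random() < 0.5:
            px = px[::-1, :]
        changed = True
    if cfg.zoom:
        z = float(rng.uniform(*cfg.zoom_range))
        zoomed = nd_zoom(px, (z, z, 1.0), order=1)
        out = np.zeros_like(px)
        zs = zoomed.shape[0]
        if zs >= size:
            off = (zs - size) // 2
            out = zoomed[off:off + size, off:off + size]
            out = out[:size, :size]
        else:
            off = (size - zs) // 2
            out[off:off + zs, off:off + zs] = zoomed
        px = out
        changed = True
    if changed:
        px = np.clip(np.ascontiguousarray(px), 0.0, 1.0)
        px[~field_of_view_mask(size)] = 0.0
    return GradedImage(px, img.grade, dict(img.meta))


# ---------------------------------------------------------------------------
# minority-boosted sampling
# ---------------------------------------------------------------------------

def _class_probs_alpha(freqs: np.ndarray, alpha: float) -> np.ndarray:
    w = freqs ** (1.0 - alpha)
    return w / w.sum()


def solve_alpha(freqs: np.ndarray, boost: float) -> float:
    """Exponent alpha of the inverse-frequency sampling weights.

    Instance weights are (1/f_c)^alpha, so class c is drawn with
    probability f_c^(1-alpha) (normalized). alpha is set so the
    minority class is oversampled by `boost` relative to its natural
    frequency; the attainable maximum is 1/f_min (all-minority), and a
    larger request is clamped with a warning.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    f_min = freqs.min()
    if boost <= 1.0 or np.all(freqs == freqs[0]):
        return 0.0
    max_boost = 1.0 / f_min
    if boost >= max_boost - 1e-9:
        warnings.warn(f"minority_boost {boost} exceeds attainable {max_boost:.3g};"
                      " clamping", RuntimeWarning)
        return 200.0
    k = int(np.argmin(freqs))

    def gap(alpha):
        return _class_probs_alpha(freqs, alpha)[k] / f_min - boost

    return float(brentq(gap, 0.0, 200.0))


def sample_batch(indices: np.ndarray, labels: np.ndarray, cfg: TrainConfig,
                 rng: np.random.Generator,
                 batch_size: Optional[int] = None) -> np.ndarray:
    """Draw a batch of instance indices with minority-boosted weights."""
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("empty training set")
    y = np.asarray(labels, dtype=int)[indices]
    classes, counts = np.unique(y, return_counts=True)
    freqs = counts / counts.sum()
    alpha = solve_alpha(freqs, cfg.minority_boost)
    class_w = {c: (1.0 / f) ** alpha for c, f in zip(classes, freqs)}
    w = np.array([class_w[c] for c in y])
    w /= w.sum()
    bs = batch_size or cfg.batch_size
    return rng.choice(indices, size=bs, replace=True, p=w)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _eval_probs(model: ProxyViT, images: np.ndarray,
                chunk: int = 32) -> np.ndarray:
    out = [model.forward(images[i:i + chunk])
           for i in range(0, len(images), chunk)]
    return np.concatenate(out, axis=0)


def train(dataset: Dataset, model_cfg: ModelConfig, train_cfg: TrainConfig,
          val_idx: Optional[np.ndarray] = None, fold_id: int = 0,
          verbose: bool = False) -> TrainResult:
    """Adam training with per-epoch train/val logging.

    If no validation indices are given, a stratified hold-out of
    `val_fraction` is carved from the dataset. The returned model
    carries the weights of the best-validation-accuracy epoch.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([train_cfg.seed, fold_id, 1]))
    all_idx = np.arange(len(dataset))
    if val_idx is None:
        k = max(2, int(round(1.0 / train_cfg.val_fraction)))
        folds = make_folds(dataset.labels, k, train_cfg.seed)
        val_idx = folds[0].val_ids
        train_idx = folds[0].train_ids
    else:
        val_idx = np.asarray(val_idx, dtype=int)
        train_idx = np.setdiff1d(all_idx, val_idx)

    model = ProxyViT(model_cfg, seed=int(
        np.random.SeedSequence([train_cfg.seed, fold_id, 2]).generate_state(1)[0]
        % (2 ** 31)))
    model.set_input_stats(dataset.images[train_idx])
    opt = Adam(model.parameters(), lr=train_cfg.lr, betas=train_cfg.adam_betas,
               weight_decay=train_cfg.weight_decay)
    augmenting = train_cfg.rotate or train_cfg.flip or train_cfg.zoom
    log: list[dict] = []
    best_acc, best_epoch = -1.0, -1
    best_params = {k_: v.data.copy() for k_, v in model.params.items()}

    steps = max(1, math.ceil(len(train_idx) / train_cfg.batch_size))
    for epoch in range(train_cfg.epochs):
        losses = []
        for _ in range(steps):
            batch_idx = sample_batch(train_idx, dataset.labels, train_cfg, rng)
            imgs = []
            for i in batch_idx:
                gi = GradedImage(dataset.images[i], int(dataset.labels[i]))
                if augmenting:
                    gi = augment(gi, train_cfg, rng)
                imgs.append(gi.pixels)
            batch = np.stack(imgs)
            loss, _ = model.batch_loss(
                batch, dataset.labels[batch_idx],
                drop_rng=rng if model_cfg.dropout > 0 else None)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_probs = _eval_probs(model, dataset.images[val_idx])
        val_pred = val_probs.argmax(axis=1)
        yv = dataset.labels[val_idx]
        val_loss = float(np.mean([-np.log(max(val_probs[i, yv[i]], 1e-12))
                                  for i in range(len(yv))]))
        val_acc = float((val_pred == yv).mean())
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "val_loss": val_loss, "val_acc": val_acc}
        log.append(row)
        if verbose:
            print(f"epoch {epoch}: train_loss={row['train_loss']:.4f} "
                  f"val_loss={val_loss:.4f} val_acc={val_acc:.4f}")
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_params = {k_: v.data.copy() for k_, v in model.params.items()}

    for k_, v in model.params.items():
        v.data = best_params[k_]
    return TrainResult(model, log, best_epoch, best_acc)


def evaluate(model: ProxyViT, dataset: Dataset,
             task: str = "grading") -> MetricsReport:
    """Run the model over a dataset and compute the full metric suite."""
    if task not in ("grading", "binary", "grading_5"):
        raise ValueError("task must be 'grading' or 'binary'")
    probs = _eval_probs(model, dataset.images)
    preds = probs.argmax(axis=1)
    scores = probs[:, 1] if dataset.n_classes == 2 else probs
    return report_from_predictions(dataset.labels, preds, scores,
                                   n_classes=dataset.n_classes)


def cross_validate(dataset: Dataset, model_cfg: ModelConfig,
                   train_cfg: TrainConfig, verbose: bool = False
                   ) -> tuple[list[MetricsReport], dict]:
    """k-fold cross-validation: one model per fold, aggregated metrics."""
    folds = make_folds(dataset.labels, train_cfg.folds, train_cfg.seed)
    reports = []
    for fold in folds:
        cfg = copy.deepcopy(train_cfg)
        result = train(dataset, model_cfg, cfg, val_idx=fold.val_ids,
                       fold_id=fold.fold_id, verbose=verbose)
        reports.append(evaluate(result.model, dataset.subset(fold.val_ids)))
    fields_ = ["auc", "acc", "sensitivity", "specificity", "precision", "f1",
               "g_mean_ps", "g_mean_ss", "wF1", "wKappa"]
    arr = np.array([[getattr(r, f) for f in fields_] for r in reports])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = {f: {"mean": float(np.nanmean(arr[:, j])),
                       "std": float(np.nanstd(arr[:, j]))}
                   for j, f in enumerate(fields_)}
    return reports, summary


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def gradcam(model: ProxyViT, image: np.ndarray,
            target_class: Optional[int] = None, layer: int = -1) -> SaliencyMap:
    """Gradient-weighted class activation map over an encoder block.

    Target activations are the block's multi-head attention output on
    the patch tokens (class token dropped), reshaped to the patch grid.
    Channel weights are the spatial mean of the gradient of the target
    class log-probability; the weighted sum is ReLU'd, bilinearly
    upsampled to the image size and min-max normalized. A constant map
    yields all zeros with a warning.
    """
    if image.ndim == 3:
        image = image[None]
    probs = model.forward_tensor(image, record=True)
    acts = model.recorded_attention()
    act = acts[layer]
    if target_class is None:
        target_class = int(np.argmax(probs.data[0]))
    score = (probs[0, target_class] + 1e-12).log()
    score.backward()
    g = act.grad[0, 1:, :]          # (N, d) gradients, class token dropped
    a = act.data[0, 1:, :]
    side = model.cfg.grid_side
    weights = g.mean(axis=0)        # (d,)
    cam = np.maximum((a * weights).sum(axis=1), 0.0).reshape(side, side)
    size = image.shape[1]
    heat = _bilinear_grid_resize(cam[..., None], (size, size))[..., 0]
    lo, hi = heat.min(), heat.max()
    if hi - lo < 1e-12:
        warnings.warn("constant Grad-CAM map; returning zeros", RuntimeWarning)
        heat = np.zeros_like(heat)
    else:
        heat = (heat - lo) / (hi - lo)
    n_layers = len(acts)
    return SaliencyMap(heat, source_layer=f"block_{layer % n_layers}")
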