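"""Evaluation metrics for ordinal grading and binary lesion screening.

Implements the standard confusion-count ratios (accuracy, sensitivity,
specificity, precision), the F1 harmonic mean, the geometric mean
(G-mean) of a chosen rate pair, rank-based AUC, class-frequency-weighted
F1 and distance-weighted kappa. Undefined quantities (zero denominators,
single-class inputs) are reported as NaN with a warning — never silently
zero.

Two G-mean conventions circulate for imbalanced screening reports:
sqrt(precision * sensitivity) and sqrt(sensitivity * specificity). Both
are exposed; `g_mean` takes the pair explicitly.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts", "MetricsReport", "confusion", "basic_metrics",
    "f1_score", "g_mean", "auc_score", "weighted_f1", "weighted_kappa",
    "report_from_predictions", "write_report_json", "write_fold_csv",
]


@dataclass
class ConfusionCounts:
    """C x C contingency table, rows = true class, cols = predicted."""

    table: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.table)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("confusion table must be square")
        if np.any(t < 0):
            raise ValueError("counts must be nonnegative")
        self.table = t.astype(np.int64)

    @property
    def n_classes(self) -> int:
        return self.table.shape[0]

    @property
    def n(self) -> int:
        return int(self.table.sum())

    def binary_view(self, positive: int = 1) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, TN, FP, FN) for the given positive class."""
        t = self.table
        tp = int(t[positive, positive])
        fn = int(t[positive].sum() - tp)
        fp = int(t[:, positive].sum() - tp)
        tn = int(t.sum() - tp - fn - fp)
        return tp, tn, fp, fn

    @classmethod
    def from_binary(cls, tp: int, tn: int, fp: int, fn: int) -> "ConfusionCounts":
        return cls(np.array([[tn, fp], [fn, tp]]))


def confusion(y_true: Sequence[int], y_pred: Sequence[int], n_classes: int
              ) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if yt.size == 0:
        raise ValueError("empty input")
    for arr, nm in ((yt, "y_true"), (yp, "y_pred")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{nm} contains labels outside 0..{n_classes - 1}")
    table = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(table, (yt, yp), 1)
    return ConfusionCounts(table)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def basic_metrics(c: ConfusionCounts, positive: int = 1
                  ) -> tuple[float, float, float, float]:
    """(accuracy, sensitivity, specificity, precision) from binary counts.

    Multi-class tables are reduced one-vs-rest for the given positive
    class; accuracy is always the overall diagonal fraction.
    """
    tp, tn, fp, fn = c.binary_view(positive)
    acc = _ratio(np.trace(c.table), c.n, "accuracy")
    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    prec = _ratio(tp, tp + fp, "precision")
    return acc, sens, spec, prec


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean 2PS/(P+S)."""
    if math.isnan(precision) or math.isnan(sensitivity) or \
            precision + sensitivity == 0:
        warnings.warn("F1 undefined; reporting NaN", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def g_mean(a: float, b: float) -> float:
    """Geometric mean sqrt(a*b) of two rate metrics in [0, 1]."""
    return math.sqrt(a * b)


def auc_score(y_true: Sequence[int], scores) -> float:
    """Area under the ROC curve.

    Binary: tie-corrected rank statistic (Mann-Whitney; ties count 1/2).
    Multi-class (scores with C columns): unweighted one-vs-rest mean
    over the classes present.
    """
    yt = np.asarray(y_true, dtype=int)
    sc = np.asarray(scores, dtype=np.float64)
    if sc.ndim == 2 and sc.shape[1] > 2:
        aucs = []
        for k in range(sc.shape[1]):
            yk = (yt == k).astype(int)
            if yk.min() == yk.max():
                continue
            aucs.append(auc_score(yk, sc[:, k]))
        if not aucs:
            warnings.warn("AUC undefined (single class)", RuntimeWarning,
                          stacklevel=2)
            return float("nan")
        return float(np.mean(aucs))
    if sc.ndim == 2:
        sc = sc[:, 1]
    pos = yt == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined (single class)", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    ranks = rankdata(sc)  # average ranks -> ties contribute 1/2
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def weighted_f1(c: ConfusionCounts) -> float:
    """Support-weighted mean of per-class one-vs-rest F1 scores."""
    if c.n == 0:
        raise ValueError("empty confusion table")
    total = 0.0
    for k in range(c.n_classes):
        n_k = int(c.table[k].sum())
        if n_k == 0:
            continue
        tp, tn, fp, fn = c.binary_view(k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prec = _ratio(tp, tp + fp, "precision")
            sens = _ratio(tp, tp + fn, "sensitivity")
            f1 = float("nan") if (math.isnan(prec) or math.isnan(sens)
                                  or prec + sens == 0) \
                else 2 * prec * sens / (prec + sens)
        if math.isnan(f1):
            warnings.warn(f"class {k} F1 undefined; contributes 0 to wF1",
                          RuntimeWarning, stacklevel=2)
            f1 = 0.0
        total += (n_k / c.n) * f1
    return total


def weighted_kappa(c: ConfusionCounts, weighting: str = "quadratic") -> float:
    """Chance-corrected agreement with distance-based disagreement weights.

    kappa_w = 1 - sum(w * O) / sum(w * E), with w_ij = ((i-j)/(C-1))^2
    (quadratic, the ordinal-grading default) or |i-j|/(C-1) (linear),
    O the observed table and E the product of its marginals.
    """
    if weighting not in ("quadratic", "linear"):
        raise ValueError("weighting must be 'quadratic' or 'linear'")
    t = c.table.astype(np.float64)
    n = t.sum()
    if n == 0:
        raise ValueError("empty confusion table")
    k = c.n_classes
    idx = np.arange(k)
    diff = np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    w = diff ** 2 if weighting == "quadratic" else diff
    o = t / n
    e = np.outer(t.sum(axis=1), t.sum(axis=0)) / n ** 2
    den = (w * e).sum()
    if den == 0:
        warnings.warn("weighted kappa undefined (degenerate marginals)",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(1.0 - (w * o).sum() / den)


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Flat summary of the full metric suite for one evaluation run."""

    auc: float
    acc: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    g_mean_ps: float        # sqrt(precision * sensitivity)
    g_mean_ss: float        # sqrt(sensitivity * specificity)
    wF1: float
    wKappa: float
    per_class: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return asdict(self)


def report_from_predictions(y_true: Sequence[int], y_pred: Sequence[int],
                            scores: Optional[np.ndarray] = None,
                            n_classes: Optional[int] = None) -> MetricsReport:
    """Compute the full suite from labels, predictions and (optionally) scores.

    Binary tasks report the positive-class rates; multi-class tasks
    report macro averages of the one-vs-rest rates plus wF1/wKappa.
    """
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if n_classes is None:
        n_classes = int(max(yt.max(), yp.max())) + 1
    c = confusion(yt, yp, n_classes)
    per_class = []
    for k in range(n_classes):
        acc_k, sens_k, spec_k, prec_k = basic_metrics(c, positive=k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1_k = f1_score(prec_k, sens_k)
        per_class.append({"class": k, "sensitivity": sens_k,
                          "specificity": spec_k, "precision": prec_k,
                          "f1": f1_k})
    if n_classes == 2:
        acc, sens, spec, prec = basic_metrics(c, positive=1)
    else:
        acc = _ratio(np.trace(c.table), c.n, "accuracy")
        sens = float(np.nanmean([m["sensitivity"] for m in per_class]))
        spec = float(np.nanmean([m["specificity"] for m in per_class]))
        prec = float(np.nanmean([m["precision"] for m in per_class]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = f1_score(prec, sens)
    auc = float("nan")
    if scores is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            auc = auc_score(yt if n_classes > 2 else (yt == 1).astype(int),
                            scores)
    return MetricsReport(
        auc=auc, acc=acc, sensitivity=sens, specificity=spec, precision=prec,
        f1=f1,
        g_mean_ps=g_mean(prec, sens) if not (math.isnan(prec) or
                                             math.isnan(sens)) else float("nan"),
        g_mean_ss=g_mean(sens, spec) if not (math.isnan(sens) or
                                             math.isnan(spec)) else float("nan"),
        wF1=weighted_f1(c), wKappa=weighted_kappa(c), per_class=per_class)


def round_percent(x: float, decimals: int = 1) -> float:
    """Half-up rounding of a proportion to percent, as tables print it."""
    if math.isnan(x):
        return float("nan")
    scale = 10 ** decimals
    return math.floor(x * 100 * scale + 0.5) / scale


def write_report_json(report: MetricsReport, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, default=float)


def write_fold_csv(reports: Sequence[MetricsReport], path: str) -> None:
    """One row per fold plus mean/std summary rows."""
    fields = ["auc", "acc", "sensitivity", "specificity", "precision", "f1",
              "g_mean_ps", "g_mean_ss", "wF1", "wKappa"]
    rows = [[getattr(r, f) for f in fields] for r in reports]
    arr = np.array(rows, dtype=float)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fold"] + fields)
        for i, row in enumerate(rows):
            w.writerow([i] + [f"{v:.6f}" for v in row])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w.writerow(["mean"] + [f"{v:.6f}" for v in np.nanmean(arr, axis=0)])
            w.writerow(["std"] + [f"{v:.6f}" for v in np.nanstd(arr, axis=0)])
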