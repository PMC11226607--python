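"""Metrics, evaluation protocols and explanation tooling.

Metrics follow the standard multi-class conventions: accuracy =
trace/total of the confusion matrix; per-class precision TP/(TP+FP),
recall TP/(TP+FN) and F1 = 2PR/(P+R) from one-vs-rest counts, with
zero-denominator cases defined as 0; aggregate values are unweighted
(macro) means. Two protocols are provided: a conventional hold-out run and
stratified five-fold cross-validation with a fixed test set, reported as
per-fold rows plus an average row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.manifold import TSNE

from .data import SplitPlan
from .nn import bilinear_matrix

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics_from_confusion",
    "topk_accuracy",
    "evaluate_predictions",
    "run_protocol",
    "gradcam",
    "tsne_export",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[t, p]: rows are true classes, columns predicted classes."""

    counts: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path, class_names=None) -> None:
        names = class_names or [str(i) for i in range(self.n_classes)]
        pd.DataFrame(self.counts, index=names, columns=names).to_csv(path)


@dataclass
class MetricsReport:
    top1: float
    top3: float | None
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        d = {
            "top1": self.top1,
            "top3": self.top3,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class_precision": self.precision.tolist(),
            "per_class_recall": self.recall.tolist(),
            "per_class_f1": self.f1.tolist(),
            "confusion": self.confusion.counts.tolist(),
        }
        return d


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays differ in length")
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts=counts)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    return MetricsReport(
        top1=float(tp.sum() / counts.sum()),
        top3=None,
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        confusion=cm,
    )


def topk_accuracy(probs: np.ndarray, y_true, k: int) -> float:
    """Fraction of samples whose true class is among the k most probable;
    probability ties resolve toward the lower class index."""
    probs = np.asarray(probs, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if k < 1:
        raise ValueError("k must be >= 1")
    n, Y = probs.shape
    if k > Y:
        raise ValueError(f"k={k} exceeds number of classes {Y}")
    # sort by (-prob, class index): lexsort's last key dominates
    order = np.lexsort((np.broadcast_to(np.arange(Y), probs.shape), -probs), axis=1)
    topk = order[:, :k]
    return float(np.mean((topk == y_true[:, None]).any(axis=1)))


def evaluate_predictions(probs: np.ndarray, y_true, n_classes: int) -> MetricsReport:
    y_pred = probs.argmax(axis=1)
    report = metrics_from_confusion(confusion(y_true, y_pred, n_classes))
    report.top3 = topk_accuracy(probs, y_true, min(3, n_classes))
    return report


def _fit_eval(estimator, X, y, train_ids, eval_sets):
    est = clone(estimator)
    est.fit(X[train_ids], y[train_ids])
    out = {}
    for name, ids in eval_sets.items():
        probs = est.predict_proba(X[ids])
        enc = np.searchsorted(est.classes_, y[ids])
        out[name] = evaluate_predictions(probs, enc, len(est.classes_))
    return est, out


def run_protocol(estimator, X: np.ndarray, y: np.ndarray, plan: SplitPlan,
                 mode: str = "holdout", out_dir: str | Path | None = None) -> dict:
    """Run the hold-out or k-fold protocol and return (optionally write)
    the report.

    ``holdout``: fit on the training pool, report test metrics. ``kfold``:
    per fold, fit on the fold's training part, report validation and
    shared-test metrics, plus an arithmetic-average row.
    """
    y = np.asarray(y)
    report: dict = {"mode": mode, "seed": plan.seed}
    if mode == "holdout":
        _, res = _fit_eval(estimator, X, y, np.asarray(plan.train_ids),
                           {"test": np.asarray(plan.test_ids)})
        report["test"] = res["test"].to_dict()
    elif mode == "kfold":
        if not plan.folds:
            raise ValueError("plan has no folds; call make_folds first")
        rows = []
        for f, (tr, va) in enumerate(plan.folds, start=1):
            _, res = _fit_eval(estimator, X, y, np.asarray(tr),
                               {"val": np.asarray(va), "test": np.asarray(plan.test_ids)})
            rows.append({
                "fold": f,
                "val_top1": res["val"].top1, "test_top1": res["test"].top1,
                "val_top3": res["val"].top3, "test_top3": res["test"].top3,
                "precision": res["test"].macro_precision,
                "recall": res["test"].macro_recall,
                "f1": res["test"].macro_f1,
            })
        avg = {k: float(np.mean([r[k] for r in rows]))
               for k in rows[0] if k != "fold"}
        report["folds"] = rows
        report["average"] = avg
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"report_{mode}.json").write_text(json.dumps(report, indent=1))
        if mode == "kfold":
            df = pd.DataFrame(report["folds"])
            df.loc[len(df)] = {"fold": "Avg", **report["average"]}
            df.to_csv(out_dir / "report_kfold.csv", index=False)
    return report


def gradcam(estimator_or_model, image: np.ndarray, target_class: int) -> np.ndarray:
    """Gradient-weighted class-activation heatmap at input resolution.

    The gradient of the target-class logit w.r.t. the backbone's final
    convolutional map is averaged per channel into weights; the
    channel-weighted map is ReLU-rectified, min-max normalized to [0, 1]
    (an all-constant map collapses to zeros) and bilinearly resized.
    """
    model = getattr(estimator_or_model, "model_", estimator_or_model)
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected one HxWx3 image, got shape {image.shape}")
    if hasattr(estimator_or_model, "_preprocess"):
        x = estimator_or_model._preprocess(image[None])
    else:
        x = image[None]
    logits = model.forward(x, train=False)
    Y = logits.shape[1]
    if not 0 <= target_class < Y:
        raise ValueError(f"target class {target_class} outside [0, {Y})")
    seed = np.zeros_like(logits)
    seed[0, target_class] = 1.0
    model.backward(seed, into_backbone=False)
    fmap = model.feature_map_[0]                   # h x w x C
    grad = model.feature_map_grad_[0]
    weights = grad.mean(axis=(0, 1))               # GAP of the gradients
    cam = np.maximum((fmap * weights).sum(axis=-1), 0.0)
    H, W = image.shape[:2]
    Rh, Rw = bilinear_matrix(H, cam.shape[0]), bilinear_matrix(W, cam.shape[1])
    cam = Rh @ cam @ Rw.T
    span = cam.max() - cam.min()
    if span <= 1e-12:
        return np.zeros_like(cam)
    return np.clip((cam - cam.min()) / span, 0.0, 1.0)


def tsne_export(estimator, X: np.ndarray, y: np.ndarray, seed: int = 0,
                out_path: str | Path | None = None,
                perplexity: float | None = None) -> pd.DataFrame:
    """2-D t-SNE embedding of the penultimate feature vectors as an
    (x, y, label) table; seed-controlled and PCA-initialized."""
    if len(X) < 10:
        raise ValueError("need at least 10 samples for a t-SNE export")
    feats = estimator.transform(X)
    if perplexity is None:
        perplexity = min(30.0, max(2.0, len(X) / 4))
    emb = TSNE(n_components=2, random_state=seed, init="pca",
               perplexity=perplexity).fit_transform(feats)
    df = pd.DataFrame({"x": emb[:, 0], "y": emb[:, 1], "label": np.asarray(y)})
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df
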