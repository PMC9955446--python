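"""Classification metrics, ROC/AUC, k-fold harness and abstention analysis.

Conventions: the positive class is malignant (label 1); metric rows are
percentages; report rows are rounded half-up to 2 decimals (raw values
are kept in the JSON export); undefined ratios (zero denominator) are
reported as NaN, never as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_counts",
    "confusion_metrics",
    "roc_auc",
    "aggregate_folds",
    "kfold_evaluate",
    "uncertainty_accuracy_analysis",
    "round_half_up",
]

METRIC_COLUMNS = ["sensitivity", "precision", "accuracy", "specificity", "f1"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    fold_rows: pd.DataFrame  # one row per fold, percent
    aggregate: dict[str, float]  # half-up 2-decimal column means
    roc_points: list[tuple[float, float]]
    auc: float
    uncertainty_accuracy: list[tuple[float, float, float]] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = self.fold_rows.copy()
        table.loc["Average"] = pd.Series(self.aggregate)
        table.to_csv(out / "metrics.csv", index_label="fold")
        pd.DataFrame(self.roc_points, columns=["fpr", "tpr"]).to_csv(
            out / "roc_points.csv", index=False
        )
        payload = {
            "folds": self.fold_rows.to_dict(orient="index"),
            "aggregate": self.aggregate,
            "auc": self.auc,
            "uncertainty_accuracy": [
                {"threshold": t, "retained_fraction": r, "accuracy": a}
                for t, r, a in self.uncertainty_accuracy
            ],
        }
        (out / "report.json").write_text(json.dumps(payload, indent=1, allow_nan=True))


def round_half_up(x: float, ndigits: int = 2) -> float:
    if not math.isfinite(x):
        return x
    return float(Decimal(repr(x)).quantize(Decimal("1." + "0" * ndigits), rounding=ROUND_HALF_UP))


def confusion_counts(labels: np.ndarray, preds: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels).astype(int)
    preds = np.asarray(preds).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((preds == 1) & (labels == 1))),
        fp=int(np.sum((preds == 1) & (labels == 0))),
        tn=int(np.sum((preds == 0) & (labels == 0))),
        fn=int(np.sum((preds == 0) & (labels == 1))),
    )


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, precision, accuracy, specificity, F1 — all percent."""
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    prec = _ratio(counts.tp, counts.tp + counts.fp)
    acc = _ratio(counts.tp + counts.tn, counts.total)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    if math.isfinite(sens) and math.isfinite(prec) and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    else:
        f1 = float("nan")
    return {"sensitivity": sens, "precision": prec, "accuracy": acc, "specificity": spec, "f1": f1}


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[list[tuple[float, float]], float]:
    """ROC by threshold sweep over the unique scores (ties included
    simultaneously) and trapezoidal AUC."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def aggregate_folds(rows: pd.DataFrame | Sequence[dict[str, float]]) -> dict[str, float]:
    """Column-wise arithmetic mean, half-up rounded to 2 decimals."""
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError("need at least one fold row")
    if frame.isna().all().any():
        raise ValueError("ragged or empty metric columns")
    return {col: round_half_up(float(frame[col].mean())) for col in frame.columns}


def kfold_evaluate(
    train_fn: Callable[[np.ndarray, np.ndarray, int], object],
    images: np.ndarray,
    labels: np.ndarray,
    k: int = 9,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation.

    ``train_fn(train_images, train_labels, fold_seed)`` must return an
    object with a deterministic ``forward(batch) -> probs`` method (e.g.
    a trained :class:`~dropweak.model.ResidualClassifier`). Per-fold
    metric rows are aggregated with a half-up 2-decimal mean; ROC/AUC is
    computed over the pooled out-of-fold malignancy scores.
    """
    labels = np.asarray(labels).astype(int)
    if k < 2 or len(labels) < k:
        raise ValueError("need k >= 2 and at least k samples")
    if np.min(np.bincount(labels)) < k:
        raise ValueError("a class has fewer samples than folds (stratification error)")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    rows, pooled_scores, pooled_labels = [], [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(images, labels)):
        model = train_fn(images[train_idx], labels[train_idx], seed + fold)
        probs = model.forward(images[test_idx], stochastic=False)
        preds = probs.argmax(axis=1)
        rows.append(confusion_metrics(confusion_counts(labels[test_idx], preds)))
        pooled_scores.append(probs[:, 1])
        pooled_labels.append(labels[test_idx])
    frame = pd.DataFrame(rows, index=[f"fold_{i + 1}" for i in range(k)])
    points, auc = roc_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return EvalReport(frame, aggregate_folds(frame), points, auc)


def uncertainty_accuracy_analysis(
    pred_mean: np.ndarray,
    uncertainties: np.ndarray,
    labels: np.ndarray,
    thresholds: Sequence[float] = (0.3, 0.5),
    mode: str = "entropy",
) -> list[tuple[float, float, float]]:
    """Selective-prediction accuracy at uncertainty/confidence cutoffs.

    ``entropy`` mode retains samples with uncertainty <= threshold;
    ``ph`` mode retains samples whose probability-of-hit >= threshold.
    Returns (threshold, retained fraction, accuracy-of-retained) with
    NaN accuracy when nothing is retained.
    """
    if mode not in ("entropy", "ph"):
        raise ValueError("mode must be 'entropy' or 'ph'")
    preds = np.asarray(pred_mean).argmax(axis=1)
    labels = np.asarray(labels).astype(int)
    u = np.asarray(uncertainties, dtype=float)
    out = []
    for thr in thresholds:
        keep = u <= thr if mode == "entropy" else u >= thr
        frac = float(keep.mean())
        acc = float((preds[keep] == labels[keep]).mean()) if keep.any() else float("nan")
        out.append((float(thr), frac, acc))
    return out
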