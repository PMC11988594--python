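"""Splitting, leakage-free standardization, and classifier evaluation.

The evaluation protocol is fixed before any preprocessing: the labeled
cohort is split 7:3 with per-class stratification, then a z-score scaler is
fitted on training rows only and applied unchanged to the test rows.  The
report carries a confusion matrix, per-class and macro precision / recall /
F1, multiclass accuracy (trace of the confusion matrix over n), and
per-class one-vs-rest ROC curves with trapezoidal AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.preprocessing import StandardScaler

from .cohort import SampleMatrix

__all__ = ["SplitSpec", "ScalerParams", "EvaluationReport",
           "stratified_split", "fit_scaler", "apply_scaler", "evaluate"]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature standardization parameters fitted on training rows only.

    sigma is the population standard deviation (divide by n); zero-variance
    features transform to exactly 0.
    """

    mu: np.ndarray
    sigma: np.ndarray


def stratified_split(
    matrix: SampleMatrix, spec: SplitSpec | None = None
) -> tuple[SampleMatrix, SampleMatrix]:
    """Seeded stratified split into training and test cohorts.

    Each class contributes floor(n_c * train_fraction) training samples;
    remaining seats up to round(n_total * train_fraction) go to the classes
    with the largest fractional parts (ties to the lower class code), so a
    balanced 90-sample cohort at 0.7 yields exactly 63 train / 27 test
    (21 + 9 per origin).
    """
    spec = spec or SplitSpec()
    y = matrix.labels
    classes = np.unique(y)
    if classes.size < 1 or any((y == c).sum() < 2 for c in classes):
        raise ValueError("every class needs at least two samples")
    rng = np.random.default_rng(spec.seed)

    if spec.stratified:
        frac = {c: (y == c).sum() * spec.train_fraction for c in classes}
        base = {c: int(np.floor(frac[c])) for c in classes}
        target_total = int(round(matrix.n_samples * spec.train_fraction))
        deficit = target_total - sum(base.values())
        by_frac = sorted(classes, key=lambda c: (-(frac[c] - base[c]), c))
        for c in by_frac[:max(deficit, 0)]:
            base[c] += 1
        train_rows: list[int] = []
        for c in classes:
            rows = np.flatnonzero(y == c)
            rows = rng.permutation(rows)
            train_rows.extend(rows[: base[c]].tolist())
    else:
        n_train = int(round(matrix.n_samples * spec.train_fraction))
        train_rows = rng.permutation(matrix.n_samples)[:n_train].tolist()

    train_mask = np.zeros(matrix.n_samples, dtype=bool)
    train_mask[train_rows] = True
    return (matrix.subset_samples(np.flatnonzero(train_mask)),
            matrix.subset_samples(np.flatnonzero(~train_mask)))


def fit_scaler(train: SampleMatrix | np.ndarray) -> ScalerParams:
    """Fit z-score parameters on training rows only."""
    X = train.intensities if isinstance(train, SampleMatrix) else np.asarray(train)
    if X.shape[0] == 0:
        raise ValueError("cannot fit a scaler on an empty training set")
    sk = StandardScaler().fit(X)
    sigma = np.sqrt(sk.var_)
    if np.any(sigma == 0):
        warnings.warn(
            "constant training column(s); standardized values set to 0",
            stacklevel=2,
        )
    return ScalerParams(mu=sk.mean_.copy(), sigma=sigma)


def apply_scaler(params: ScalerParams,
                 matrix: SampleMatrix | np.ndarray) -> np.ndarray:
    """Standardize with frozen training parameters (never refits)."""
    X = matrix.intensities if isinstance(matrix, SampleMatrix) else np.asarray(matrix)
    safe = np.where(params.sigma == 0, 1.0, params.sigma)
    return (X - params.mu) / safe


@dataclass
class EvaluationReport:
    """Confusion matrix, classification metrics, and per-class ROC/AUC."""

    confusion: np.ndarray  # (C, C), rows true, columns predicted
    accuracy: float
    precision_per_class: np.ndarray
    recall_per_class: np.ndarray
    f1_per_class: np.ndarray
    precision_macro: float
    recall_macro: float
    f1_macro: float
    roc: list[dict[str, np.ndarray]] = field(default_factory=list)
    auc: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_test(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision_per_class": self.precision_per_class.tolist(),
            "recall_per_class": self.recall_per_class.tolist(),
            "f1_per_class": self.f1_per_class.tolist(),
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "roc": [{k: np.asarray(v).tolist() for k, v in r.items()}
                    for r in self.roc],
            "auc": self.auc.tolist(),
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def evaluate(y_true: np.ndarray, proba: np.ndarray) -> EvaluationReport:
    """Score class-probability predictions.

    The predicted label is the argmax of the probability row (ties break to
    the lowest class index).  Per-class precision/recall/F1 come from the
    one-vs-rest reading of the confusion matrix; accuracy is its trace over
    n.  ROC curves sweep thresholds over each class's probability column
    (one-vs-rest) and AUC is the trapezoidal area.
    """
    y_true = np.asarray(y_true)
    proba = np.asarray(proba, dtype=float)
    if proba.ndim != 2 or len(y_true) != proba.shape[0]:
        raise ValueError("y_true and proba shapes do not match")
    n_classes = proba.shape[1]
    y_pred = proba.argmax(axis=1)
    labels = np.arange(n_classes)
    cm = _sk_confusion(y_true, y_pred, labels=labels)

    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)

    roc, aucs = [], []
    for c in labels:
        fpr, tpr, thr = _sk_roc_curve(
            (y_true == c).astype(int), proba[:, c], drop_intermediate=False
        )
        roc.append({"fpr": fpr, "tpr": tpr, "thresholds": thr})
        aucs.append(_trapezoid_auc(fpr, tpr))

    return EvaluationReport(
        confusion=cm,
        accuracy=float(np.trace(cm) / cm.sum()),
        precision_per_class=precision,
        recall_per_class=recall,
        f1_per_class=f1,
        precision_macro=float(precision.mean()),
        recall_macro=float(recall.mean()),
        f1_macro=float(f1.mean()),
        roc=roc,
        auc=np.array(aucs),
    )
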