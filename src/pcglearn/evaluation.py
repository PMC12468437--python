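"""Confusion-matrix metrics, cross-validation and the repeated balanced protocol.

The positive class is **abnormal** (the patient): TP counts patients
correctly identified, TN healthy subjects correctly cleared.  Four
headline metrics are derived from the confusion counts:

    Acc  = (TP + TN) / (TP + FP + TN + FN)
    Se   = TP / (TP + FN)          (sensitivity)
    Sp   = TN / (FP + TN)          (specificity)
    MAcc = (Sp + Se) / 2           (modified accuracy)

Zero-denominator cases yield ``None`` (an explicit undefined marker,
never NaN) and are excluded from fold averages, with the exclusion
counted.

The evaluation protocol: stratified ten-fold cross-validation on a
balanced draw of n recordings per class, repeated over independent
draws, reporting grand mean +/- sd across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .dataio import balanced_indices
from .models import ModelSpec, count_parameters
from .nn import TrainingHistory

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "CVReport",
    "CostReport",
    "confusion",
    "compute_metrics",
    "modified_accuracy",
    "precision_f1",
    "round_half_up",
    "kfold_cv",
    "repeated_protocol",
    "compare_extractors",
    "cost_report",
]

POSITIVE_CLASS = "abnormal"
NEGATIVE_CLASS = "normal"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = abnormal."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class Metrics:
    """Headline metrics; ``None`` marks an undefined (0/0) value."""

    acc: float | None
    se: float | None
    sp: float | None
    macc: float | None
    precision: dict = field(default_factory=dict)
    f1: dict = field(default_factory=dict)

    def rounded(self, ndigits: int = 4) -> dict:
        out = {}
        for k in ("acc", "se", "sp", "macc"):
            v = getattr(self, k)
            out[k] = None if v is None else round(v, ndigits)
        return out


def round_half_up(value: float, ndigits: int = 4) -> float:
    """Decimal rounding with halves away from zero (table convention).

    Python's ``round`` is float-based banker's rounding, which turns
    0.91665 into 0.9166; published tables round half up to 0.9167.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def confusion(labels: Sequence, predictions: Sequence) -> ConfusionMatrix:
    """Count TP/FN/FP/TN from paired labels and predictions."""
    labels = list(labels)
    predictions = list(predictions)
    if len(labels) == 0:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    if len(labels) != len(predictions):
        raise ValueError(f"length mismatch: {len(labels)} labels vs {len(predictions)} predictions")
    valid = {POSITIVE_CLASS, NEGATIVE_CLASS}
    unknown = (set(labels) | set(predictions)) - valid
    if unknown:
        raise ValueError(f"unknown class tokens {sorted(unknown)}; expected {sorted(valid)}")
    tp = sum(1 for y, p in zip(labels, predictions) if y == POSITIVE_CLASS and p == POSITIVE_CLASS)
    fn = sum(1 for y, p in zip(labels, predictions) if y == POSITIVE_CLASS and p == NEGATIVE_CLASS)
    fp = sum(1 for y, p in zip(labels, predictions) if y == NEGATIVE_CLASS and p == POSITIVE_CLASS)
    tn = sum(1 for y, p in zip(labels, predictions) if y == NEGATIVE_CLASS and p == NEGATIVE_CLASS)
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def modified_accuracy(se: float | None, sp: float | None) -> float | None:
    """MAcc = (Sp + Se) / 2; undefined if either input is undefined."""
    if se is None or sp is None:
        return None
    return (sp + se) / 2.0


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Acc/Se/Sp/MAcc plus per-class precision and F1 from counts."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    acc = (cm.tp + cm.tn) / cm.total
    se = _ratio(cm.tp, cm.tp + cm.fn)
    sp = _ratio(cm.tn, cm.fp + cm.tn)
    precision = {
        "Ab": _ratio(cm.tp, cm.tp + cm.fp),
        "N": _ratio(cm.tn, cm.tn + cm.fn),
    }
    recall = {"Ab": se, "N": sp}
    f1 = {}
    for c in ("Ab", "N"):
        p, r = precision[c], recall[c]
        if p is None or r is None or (p + r) == 0:
            f1[c] = None
        else:
            f1[c] = 2 * p * r / (p + r)
    return Metrics(acc=acc, se=se, sp=sp, macc=modified_accuracy(se, sp),
                   precision=precision, f1=f1)


def precision_f1(labels: Sequence, predictions: Sequence) -> dict:
    """Per-class precision and F1, keyed 'Ab' (abnormal) and 'N' (normal)."""
    m = compute_metrics(confusion(labels, predictions))
    return {"precision": m.precision, "f1": m.f1}


@dataclass
class CVReport:
    """Cross-validation results: per-fold metrics and their summaries."""

    fold_metrics: list[Metrics]
    iteration_means: list[dict] = field(default_factory=list)
    seed: int = 0
    n_undefined: int = 0

    def mean(self) -> dict:
        return _mean_over([m.rounded(12) for m in self.fold_metrics])

    def grand_summary(self) -> dict:
        """Mean +/- sd of the per-iteration means."""
        rows = self.iteration_means or [self.mean()]
        out = {}
        for k in ("acc", "se", "sp", "macc"):
            vals = [r[k] for r in rows if r.get(k) is not None]
            out[k] = {
                "mean": float(np.mean(vals)) if vals else None,
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
        return out


def _mean_over(rows: list[dict]) -> dict:
    out = {}
    for k in ("acc", "se", "sp", "macc"):
        vals = [r[k] for r in rows if r.get(k) is not None]
        out[k] = float(np.mean(vals)) if vals else None
    return out


@dataclass
class CostReport:
    """Training-cost summary for one model."""

    model_name: str
    n_parameters: int
    epochs: int
    batch_size: int
    wall_time_s: float


def kfold_cv(
    x: np.ndarray,
    y: Sequence,
    model_builder: Callable[[], object],
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation of a classifier factory.

    ``model_builder`` returns a fresh sklearn-style estimator; every
    example is tested exactly once.  Folds whose metrics have a zero
    denominator contribute ``None`` entries, excluded from averages.
    """
    y = np.asarray(y)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; stratified {k}-fold needs >= k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: list[Metrics] = []
    n_undefined = 0
    for train_idx, test_idx in skf.split(np.zeros(n), y):
        est = model_builder()
        if hasattr(est, "get_params"):
            est = clone(est)
        est.fit(x[train_idx], y[train_idx])
        preds = est.predict(x[test_idx])
        m = compute_metrics(confusion(list(y[test_idx]), list(preds)))
        if m.se is None or m.sp is None:
            n_undefined += 1
        fold_metrics.append(m)
    return CVReport(fold_metrics=fold_metrics, seed=seed, n_undefined=n_undefined)


def repeated_protocol(
    x: np.ndarray,
    y: Sequence,
    model_builder: Callable[[], object],
    n_per_class: int = 218,
    iterations: int = 50,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """Repeated balanced-draw cross-validation.

    Each iteration draws ``n_per_class`` recordings per class from the
    pool (without replacement within the iteration), runs stratified
    ``k``-fold cross-validation, and records the fold-mean metrics; the
    grand summary is mean +/- sd over iterations.
    """
    y = np.asarray(y)
    all_folds: list[Metrics] = []
    iter_means: list[dict] = []
    n_undefined = 0
    for it, idx in enumerate(
        balanced_indices(y, n_per_class=n_per_class, iterations=iterations, seed=seed)
    ):
        report = kfold_cv(x[idx], y[idx], model_builder, k=k, seed=seed + it + 1)
        all_folds.extend(report.fold_metrics)
        n_undefined += report.n_undefined
        iter_means.append(report.mean())
    return CVReport(
        fold_metrics=all_folds,
        iteration_means=iter_means,
        seed=seed,
        n_undefined=n_undefined,
    )


def compare_extractors(
    waveforms: Sequence,
    y: Sequence,
    extractors: Sequence,
    head_builder: Callable[[], object],
    test_fraction: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired comparison of feature extractors under one model head.

    Every extractor sees the identical train/test split and an
    identically configured head, so rows differ only by the
    representation.  Returns one row per extractor with per-class
    precision/F1 and test accuracy.
    """
    from sklearn.model_selection import train_test_split

    if len(extractors) == 0:
        raise ValueError("need at least one extractor to compare")
    y = np.asarray(y)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    rows = []
    for name_or_transformer in extractors:
        if isinstance(name_or_transformer, str):
            from .features import SpectrogramImageExtractor

            name = name_or_transformer
            transformer = SpectrogramImageExtractor(extractor=name, image_size=(64, 64))
        else:
            transformer = name_or_transformer
            name = getattr(transformer, "extractor", type(transformer).__name__)
        feats = transformer.fit_transform(waveforms)
        est = head_builder()
        if hasattr(est, "get_params"):
            est = clone(est)
        est.fit(feats[train_idx], y[train_idx])
        preds = est.predict(feats[test_idx])
        m = compute_metrics(confusion(list(y[test_idx]), list(preds)))
        rows.append(
            {
                "extractor": name,
                "precision_Ab": m.precision["Ab"],
                "precision_N": m.precision["N"],
                "f1_Ab": m.f1["Ab"],
                "f1_N": m.f1["N"],
                "test_accuracy": m.acc,
            }
        )
    return pd.DataFrame(rows)


def cost_report(spec: ModelSpec, history: TrainingHistory) -> CostReport:
    """Training-cost summary: parameter count, epochs, wall time."""
    return CostReport(
        model_name=spec.name,
        n_parameters=count_parameters(spec),
        epochs=history.n_epochs,
        batch_size=spec.train_config.batch_size,
        wall_time_s=history.wall_time_s,
    )


def sort_cost_reports(reports: list[CostReport]) -> list[CostReport]:
    """Cost comparison table ordering: parameter count, descending."""
    return sorted(reports, key=lambda r: r.n_parameters, reverse=True)
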