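"""Confusion-matrix metrics, ROC/AUC and the stratified k-fold CV harness.

Metrics follow the standard confusion-count definitions:

    Acc  = (TP+TN) / (TP+FN+TN+FP)
    Sens = TP / (TP+FN)
    Spec = TN / (TN+FP)
    Prec = TP / (TP+FP)
    Mcc  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FN)(TN+FP))

Zero-denominator cases return 0.0 with a warning flag recorded on the
:class:`MetricSet`.  The ROC curve is a threshold sweep over the unique
scores with trapezoidal area; the headline cross-validation AUC is computed
on the *pooled* held-out scores of all folds, per-fold AUCs are also kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .encoding import batch_encode
from .io import LabeledDataset
from .network import ModelConfig, build_model, predict_proba, train

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    """Acc/Sens/Spec/Prec/Mcc (fractions in [0,1], Mcc in [-1,1]) plus AUC."""

    acc: float
    sens: float
    spec: float
    prec: float
    mcc: float
    auc: float | None = None
    threshold: float = 0.5
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = {"acc": self.acc, "sens": self.sens, "spec": self.spec,
             "prec": self.prec, "mcc": self.mcc}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


@dataclass
class FoldResult:
    fold_index: int
    metrics: MetricSet
    labels: np.ndarray
    scores: np.ndarray


@dataclass
class CrossValResult:
    folds: list[FoldResult]
    mean_metrics: MetricSet
    pooled_auc: float

    @property
    def k(self) -> int:
        return len(self.folds)


def confusion_counts(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/TN/FP/FN at a threshold; a score equal to the threshold is positive."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError(f"labels {labels.shape} and scores {scores.shape} differ in length")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def compute_metrics(c: ConfusionCounts, threshold: float = 0.5) -> MetricSet:
    """Evaluate the five confusion-based statistics; AUC is left unset."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (c.tp + c.tn) / c.total
    sens = ratio(c.tp, c.tp + c.fn, "sens")
    spec = ratio(c.tn, c.tn + c.fp, "spec")
    prec = ratio(c.tp, c.tp + c.fp, "prec")
    mcc_den = float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fn) * (c.tn + c.fp)
    mcc = ratio(c.tp * c.tn - c.fp * c.fn, np.sqrt(mcc_den), "mcc")
    if undefined:
        logger.warning("zero-denominator metrics set to 0.0: %s", undefined)
    return MetricSet(acc=acc, sens=sens, spec=spec, prec=prec, mcc=mcc,
                     threshold=threshold, undefined=tuple(undefined))


def roc_auc(labels, scores) -> tuple[np.ndarray, float]:
    """ROC points from a sweep over unique score thresholds + trapezoidal AUC.

    Ties move the curve point diagonally (all records at a threshold flip
    together).  Returns (points as (fpr, tpr) rows from (0,0) to (1,1), auc).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels != 1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = (labels[order] == 1).astype(float)
    cum_tp = np.cumsum(sorted_pos)
    cum_fp = np.cumsum(1.0 - sorted_pos)
    # keep only the last index of each tied score block
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, cum_tp[distinct] / n_pos]
    fpr = np.r_[0.0, cum_fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def stratified_kfold(dataset: LabeledDataset | np.ndarray, k: int, seed: int = 0) -> list[np.ndarray]:
    """Seeded stratified partition into k folds of record indices (fold order 1..k).

    Accepts a dataset or a bare label vector.  Each class must have at least k
    members; per-fold class proportions stay within one record of the global
    proportions.
    """
    labels = dataset.labels if isinstance(dataset, LabeledDataset) else np.asarray(dataset)
    if any(l is None for l in np.atleast_1d(labels)):
        raise ValueError("stratified folding requires labels on every record")
    labels = labels.astype(int)
    for cls in np.unique(labels):
        if np.sum(labels == cls) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(labels), labels)]


def evaluate_scores(labels, scores, threshold: float = 0.5) -> MetricSet:
    """Confusion metrics + AUC for one score vector."""
    m = compute_metrics(confusion_counts(labels, scores, threshold), threshold)
    try:
        _, m.auc = roc_auc(labels, scores)
    except ValueError:
        m.auc = None
    return m


def _mean_metrics(folds: list[FoldResult]) -> MetricSet:
    def mean(attr):
        return float(np.mean([getattr(f.metrics, attr) for f in folds]))

    return MetricSet(
        acc=mean("acc"), sens=mean("sens"), spec=mean("spec"),
        prec=mean("prec"), mcc=mean("mcc"),
        auc=float(np.mean([f.metrics.auc for f in folds if f.metrics.auc is not None])),
    )


def cross_validate(
    dataset: LabeledDataset,
    config: ModelConfig,
    k: int = 5,
    seed: int = 0,
    max_len: int | str = "auto",
) -> CrossValResult:
    """Stratified k-fold cross-validation of the classifier.

    For each fold the model is trained from scratch on the remaining k-1 folds
    (with its internal validation split for early stopping) and scored on the
    held-out fold.  Reported are per-fold metrics, their unweighted mean, and
    the AUC of the pooled held-out scores.
    """
    full_batch = batch_encode(dataset, max_len=max_len)
    L = full_batch.max_len
    folds = stratified_kfold(dataset, k, seed)
    all_idx = np.arange(len(dataset))
    results: list[FoldResult] = []
    for fold_i, test_idx in enumerate(folds, start=1):
        train_idx = np.setdiff1d(all_idx, test_idx)
        fold_cfg = ModelConfig.from_dict(config.to_dict())
        fold_cfg.seed = config.seed + fold_i
        try:
            model = build_model(fold_cfg, L, structure_available=full_batch.has_structure)
            fitted = train(model, full_batch.subset(train_idx), fold_cfg)
        except Exception as exc:  # annotate with fold index, then propagate
            raise type(exc)(f"fold {fold_i}: {exc}") from exc
        test_batch = full_batch.subset(test_idx)
        scores = predict_proba(fitted, test_batch)
        metrics = evaluate_scores(test_batch.labels, scores)
        results.append(FoldResult(fold_index=fold_i, metrics=metrics,
                                  labels=test_batch.labels.copy(), scores=scores))
    pooled_labels = np.concatenate([f.labels for f in results])
    pooled_scores = np.concatenate([f.scores for f in results])
    _, pooled = roc_auc(pooled_labels, pooled_scores)
    return CrossValResult(folds=results, mean_metrics=_mean_metrics(results), pooled_auc=pooled)
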