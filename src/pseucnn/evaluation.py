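"""Confusion-matrix metrics, AUC, and stratified k-fold cross-validation.

Five metrics summarize a binary Ψ-site predictor:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    MCC = (TP·TN - FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

plus the area under the ROC curve (probability that a random positive
scores above a random negative, ties counting one half). Any metric whose
denominator is zero is reported as 0 and flagged as degenerate, so that
hyperparameter screening survives pathological folds.

Cross-validation is stratified: folds preserve the class ratio, each
sample is validated exactly once, and a fresh model is trained per fold.
Per-fold metrics are computed on the validation fold only and averaged
(a pooled-AUC variant is available).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cnn_model import HyperParams, MappingMode, TrainedModel, build_model, train

METRIC_NAMES = ("acc", "sn", "sp", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from binary label vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        bad = set(np.unique(arr)) - {0, 1}
        if bad:
            raise ValueError(f"{name} contains non-binary labels {sorted(bad)}")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass(frozen=True)
class Metrics:
    acc: float
    sn: float
    sp: float
    mcc: float
    degenerate: tuple[str, ...] = ()


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """ACC, Sn, Sp and MCC from confusion counts.

    A zero denominator yields 0 for that metric, with its name recorded in
    ``degenerate`` rather than raising.
    """
    if c.total < 1:
        raise ValueError("no samples")
    degenerate: list[str] = []
    acc = (c.tp + c.tn) / c.total
    if c.tp + c.fn > 0:
        sn = c.tp / (c.tp + c.fn)
    else:
        sn = 0.0
        degenerate.append("sn")
    if c.tn + c.fp > 0:
        sp = c.tn / (c.tn + c.fp)
    else:
        sp = 0.0
        degenerate.append("sp")
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    else:
        mcc = 0.0
        degenerate.append("mcc")
    return Metrics(acc=acc, sn=sn, sp=sp, mcc=mcc, degenerate=tuple(degenerate))


def auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC requires both classes to be present")
    return float(roc_auc_score(y_true, scores))


@dataclass
class CvResult:
    """Per-fold and aggregate cross-validation metrics."""

    folds: pd.DataFrame  # columns: fold, n_val, acc, sn, sp, mcc, auc
    mean: dict[str, float]
    fold_assignment: np.ndarray
    k: int
    epochs: int
    seed: int

    def summary(self) -> str:
        """One line in the field's 4-decimal reporting style."""
        return "  ".join(
            f"{name.upper()}={self.mean[name]:.4f}" for name in METRIC_NAMES
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "k": self.k,
            "epochs": self.epochs,
            "seed": self.seed,
            "mean": {m: self.mean[m] for m in METRIC_NAMES},
            "folds": self.folds.to_dict(orient="records"),
            "fold_assignment": self.fold_assignment.tolist(),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def to_tsv(self, path: str | Path) -> None:
        self.folds.to_csv(path, sep="\t", index=False, float_format="%.6f")


def stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold index per sample; depends only on (labels, k, seed)."""
    y = np.asarray(y, dtype=int)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, val_idx) in enumerate(splitter.split(np.zeros((len(y), 1)), y)):
        assignment[val_idx] = fold
    return assignment


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    hp: HyperParams,
    k: int = 10,
    epochs: int = 30,
    seed: int = 0,
    filters: int = 16,
    mode: MappingMode = "dense_projection",
    lr: float = 1e-3,
    batch_size: int = 32,
    threshold: float = 0.5,
    pooled_auc: bool = False,
) -> CvResult:
    """Stratified k-fold cross-validation of the CNN on a feature matrix.

    A fresh model is trained on each training split (its seed derived from
    ``seed`` and the fold index) and scored on the held-out fold. With
    ``pooled_auc=True`` a single AUC over the pooled out-of-fold scores is
    reported instead of the per-fold average.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= k={k} members for stratification; got {counts.tolist()}"
        )
    assignment = stratified_folds(y, k, seed)
    spec = build_model(hp, input_dim=X.shape[1], filters=filters, mode=mode)
    rows = []
    oof_scores = np.empty(len(y))
    for fold in range(k):
        val = assignment == fold
        model = train(
            spec,
            X[~val],
            y[~val],
            epochs=epochs,
            seed=_fold_seed(seed, fold),
            lr=lr,
            batch_size=batch_size,
        )
        scores = model.predict_proba(X[val])[:, 1]
        oof_scores[val] = scores
        m = compute_metrics(confusion_counts(y[val], (scores >= threshold).astype(int)))
        try:
            fold_auc = auc(y[val], scores)
        except ValueError:  # single-class fold
            fold_auc = 0.0
        rows.append(
            {
                "fold": fold,
                "n_val": int(val.sum()),
                "acc": m.acc,
                "sn": m.sn,
                "sp": m.sp,
                "mcc": m.mcc,
                "auc": fold_auc,
            }
        )
    folds = pd.DataFrame(rows)
    mean = {name: float(folds[name].mean()) for name in METRIC_NAMES}
    if pooled_auc:
        mean["auc"] = auc(y, oof_scores)
    return CvResult(
        folds=folds,
        mean=mean,
        fold_assignment=assignment,
        k=k,
        epochs=epochs,
        seed=seed,
    )
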