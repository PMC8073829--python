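"""Evaluation: confusion counts, MAcc, and record-level cross-validation.

MAcc — the mean of sensitivity and specificity — is the headline metric for
binary heart-sound screening: it is insensitive to class imbalance and
penalizes both missed disease (low Se) and false alarms (low Sp) equally.

Cross-validation is stratified at the *record* level: no recording's
segments ever straddle the train/test boundary of a fold.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .core import DataError

__all__ = ["EvalResult", "confusion", "macc", "cross_validate"]


def _to_binary(values, positive_class) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "iubfc":
        return arr.astype(int)
    return (arr == positive_class).astype(int)


def confusion(labels, predictions, positive_class: str = "abnormal") -> tuple[int, int, int, int]:
    """(TP, FN, TN, FP) counts with ``positive_class`` as the positive label."""
    y = _to_binary(labels, positive_class)
    p = _to_binary(predictions, positive_class)
    if y.size == 0:
        raise DataError("empty input")
    if y.shape != p.shape:
        raise DataError(f"length mismatch: {y.shape} vs {p.shape}")
    tp = int(np.sum((y == 1) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    return tp, fn, tn, fp


def macc(counts: tuple[int, int, int, int]) -> tuple[float, float, float]:
    """(sensitivity, specificity, MAcc) from (TP, FN, TN, FP) counts.

    Se = TP/(TP+FN), Sp = TN/(TN+FP), MAcc = (Se+Sp)/2.
    """
    tp, fn, tn, fp = counts
    if tp + fn == 0:
        raise DataError("positive class absent: sensitivity undefined")
    if tn + fp == 0:
        raise DataError("negative class absent: specificity undefined")
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    return se, sp, (se + sp) / 2


@dataclass
class EvalResult:
    """Per-fold confusion metrics plus their mean and SD across folds."""

    folds: list = field(default_factory=list)  # dicts with tp/fn/tn/fp/se/sp/macc
    config_fingerprint: str = ""

    @property
    def fold_maccs(self) -> np.ndarray:
        return np.array([f["macc"] for f in self.folds])

    @property
    def mean_macc(self) -> float:
        return float(np.mean(self.fold_maccs))

    @property
    def sd_macc(self) -> float:
        return float(np.std(self.fold_maccs, ddof=1)) if len(self.folds) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "mean_macc": self.mean_macc,
            "sd_macc": self.sd_macc,
            "config_fingerprint": self.config_fingerprint,
        }


def fingerprint(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def cross_validate(dataset, fit_predict, k: int = 10, seed: int = 0,
                   config_obj=None) -> EvalResult:
    """Stratified record-level k-fold evaluation.

    ``dataset`` is a sequence of items each carrying a binary label (either
    ``item.label`` or ``item[0].label``); ``fit_predict(train_items,
    test_items)`` must train the configured pipeline from scratch and return
    binary predictions (0 = normal, 1 = positive class) for the test items.
    Fold assignment is deterministic under ``seed``.
    """

    def label_of(item):
        lab = item.label if hasattr(item, "label") else item[0].label
        return 1 if lab in (1, "abnormal", "af") else 0

    def id_of(item):
        return item.record_id if hasattr(item, "record_id") else item[0].record_id

    y = np.array([label_of(it) for it in dataset])
    if np.unique(y).size < 2:
        raise DataError("dataset must contain both classes")
    if min(np.bincount(y)) < k:
        raise DataError(f"cannot stratify {k} folds: a class has fewer than {k} records")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    result = EvalResult(config_fingerprint=fingerprint(config_obj) if config_obj else "")
    for tr_idx, te_idx in skf.split(np.zeros_like(y), y):
        train_items = [dataset[i] for i in tr_idx]
        test_items = [dataset[i] for i in te_idx]
        overlap = {id_of(i) for i in train_items} & {id_of(i) for i in test_items}
        if overlap:
            raise DataError(f"record ids straddle a fold boundary: {sorted(overlap)[:5]}")
        preds = np.asarray(fit_predict(train_items, test_items)).astype(int)
        tp, fn, tn, fp = confusion(y[te_idx], preds, positive_class=1)
        se, sp, m = macc((tp, fn, tn, fp))
        result.folds.append(
            {"tp": tp, "fn": fn, "tn": tn, "fp": fp,
             "sensitivity": se, "specificity": sp, "macc": m}
        )
    return result
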