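"""Cross-validation schemes, classification metrics and the ablation harness.

Two validation schemes are provided: stratified tenfold cross-validation
(folds of near-equal size, class balance preserved per fold) and LOOCV
(one sample held out per fold).  Splits are made at frame level; a
subject-grouped variant is available for leakage studies.

Metrics follow the 2 x 2 confusion-table conventions: accuracy, macro
recall, macro F1, Matthews correlation coefficient, and per-class
precision for the supine (+1) and lateral (-1) postures.  Tenfold summary
metrics are the unweighted mean over folds; LOOCV metrics are computed on
the pooled held-out predictions (per-singleton-fold macro metrics are
undefined), which makes LOOCV accuracy exactly the fraction of correctly
predicted held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
)
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .ensemble import BoostConfig, TrainingSet, predict, train

SCHEMES = ("tenfold", "loocv")

METRIC_NAMES = ("accuracy", "recall", "f1", "mcc",
                "precision_supine", "precision_lateral")


def make_splits(n: int, labels: np.ndarray | None, scheme: str, seed: int = 0,
                groups: np.ndarray | None = None) -> np.ndarray:
    """Assign each of ``n`` samples to a test fold.

    Returns an integer array ``folds`` of length n: sample i is tested in
    fold ``folds[i]``.  ``tenfold`` gives 10 stratified folds (sizes
    differing by at most 1); ``loocv`` gives n singleton folds.  Passing
    ``groups`` (e.g. subject ids) switches tenfold to grouped folds so no
    subject straddles a train/test boundary.
    """
    if scheme == "loocv":
        return np.arange(n)
    if scheme != "tenfold":
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if n < 10:
        raise ValueError(f"tenfold needs at least 10 samples, got {n}")
    if labels is None:
        raise ValueError("stratified tenfold needs class labels")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("stratified tenfold needs both classes present")
    folds = np.empty(n, dtype=int)
    if groups is not None:
        splitter = GroupKFold(n_splits=10)
        iterator = splitter.split(np.zeros(n), labels, groups=groups)
    else:
        splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
        iterator = splitter.split(np.zeros(n), labels)
    for k, (_, test_idx) in enumerate(iterator):
        folds[test_idx] = k
    return folds


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Confusion-table metrics for +/-1 labels.

    Macro recall / F1 average the two per-class values; per-class
    precision is reported for each posture.  Undefined ratios (an empty
    predicted class) are reported as 0.
    """
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.size == 0:
        raise ValueError("cannot score an empty prediction set")
    if y_true.size != y_pred.size:
        raise ValueError(f"length mismatch: {y_true.size} vs {y_pred.size}")
    if not (np.isin(y_true, (-1, 1)).all() and np.isin(y_pred, (-1, 1)).all()):
        raise ValueError("labels must be +1 or -1")
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "recall": float(recall_score(y_true, y_pred, average="macro", zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
        "mcc": float(matthews_corrcoef(y_true, y_pred)),
        "precision_supine": float(precision_score(y_true, y_pred, pos_label=1,
                                                  zero_division=0)),
        "precision_lateral": float(precision_score(y_true, y_pred, pos_label=-1,
                                                   zero_division=0)),
    }


FitPredict = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
"""Signature: (X_train, y_train, X_test) -> predicted labels."""


def boost_fit_predict(config: BoostConfig | None = None) -> FitPredict:
    """Fit-predict closure for the AdaBoost-SVM ensemble."""
    def _run(X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray) -> np.ndarray:
        model = train(TrainingSet(X_train, y_train), config)
        return predict(model, X_test)
    return _run


@dataclass
class CVResult:
    """Per-fold and summary metrics of one cross-validated evaluation."""

    scheme: str
    seed: int
    folds: np.ndarray
    per_fold: pd.DataFrame
    summary: dict[str, float]
    predictions: np.ndarray
    y_true: np.ndarray


def cross_validate(X: np.ndarray, y: np.ndarray, fit_predict: FitPredict,
                   scheme: str = "tenfold", seed: int = 0,
                   groups: np.ndarray | None = None,
                   folds: np.ndarray | None = None) -> CVResult:
    """Evaluate a fit-predict routine under a CV scheme.

    Precomputed ``folds`` may be passed so several feature representations
    are compared on identical splits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if folds is None:
        folds = make_splits(len(y), y, scheme, seed=seed, groups=groups)
    predictions = np.zeros_like(y)
    rows = []
    for k in np.unique(folds):
        test = folds == k
        y_hat = np.asarray(fit_predict(X[~test], y[~test], X[test]), dtype=int)
        predictions[test] = y_hat
        if scheme == "tenfold":
            rows.append({"fold": int(k), **compute_metrics(y[test], y_hat)})
        else:
            rows.append({"fold": int(k), "accuracy": float((y_hat == y[test]).mean())})
    per_fold = pd.DataFrame(rows)
    if scheme == "tenfold":
        summary = {m: float(per_fold[m].mean()) for m in METRIC_NAMES}
    else:
        summary = compute_metrics(y, predictions)
    return CVResult(scheme=scheme, seed=seed, folds=folds, per_fold=per_fold,
                    summary=summary, predictions=predictions, y_true=y)


def run_ablation(representations: Mapping[str, np.ndarray], y: np.ndarray,
                 fit_predict: FitPredict | None = None,
                 schemes: Sequence[str] = SCHEMES, seed: int = 0) -> pd.DataFrame:
    """Evaluate the classifier on several input representations.

    ``representations`` maps a name (e.g. raw / salient / sbwh / lmr / se)
    to an (n, d) feature matrix over the same n samples.  Every
    representation is scored on identical folds per scheme.  Returns a
    tidy table with one row per (representation, scheme) and metric
    columns, mirroring a feature-ablation report.
    """
    y = np.asarray(y, dtype=int).ravel()
    fit_predict = fit_predict or boost_fit_predict()
    rows = []
    for scheme in schemes:
        folds = make_splits(len(y), y, scheme, seed=seed)
        for name, X in representations.items():
            result = cross_validate(X, y, fit_predict, scheme=scheme, seed=seed,
                                    folds=folds)
            rows.append({"representation": name, "scheme": scheme, **result.summary})
    return pd.DataFrame(rows)


def learning_curve(X_train: np.ndarray, y_train: np.ndarray,
                   X_test: np.ndarray, y_test: np.ndarray,
                   config: BoostConfig | None = None) -> pd.DataFrame:
    """Train once and report 0-1 error of the partial ensemble per round.

    Columns: round, train_error, test_error — the loss-vs-iteration series
    of the boosted classifier on a held-out split.
    """
    model = train(TrainingSet(X_train, y_train), config)
    stages_train = model.staged_decision(X_train)
    stages_test = model.staged_decision(X_test)
    rows = []
    for t in range(len(model.learners)):
        pred_train = np.where(stages_train[t] >= 0, 1, -1)
        pred_test = np.where(stages_test[t] >= 0, 1, -1)
        rows.append({
            "round": t + 1,
            "train_error": float((pred_train != np.asarray(y_train)).mean()),
            "test_error": float((pred_test != np.asarray(y_test)).mean()),
        })
    return pd.DataFrame(rows)
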