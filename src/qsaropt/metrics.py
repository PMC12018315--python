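"""Regression and classification evaluation metrics.

The formulas are written out directly rather than delegated, because the
invariants the rest of the package relies on (rmse**2 == mse, F1 defined
as 0 when precision + recall == 0, ROC by explicit threshold sweep with
trapezoid AUC) are part of the package contract and are cross-checked
against scikit-learn in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RegressionEval:
    """MSE, RMSE, MAE, MAPE (percent) and R^2 for one prediction vector.

    ``mape`` is ``None`` when any true value is zero (relative error
    undefined); the other metrics are always computed.
    """

    mse: float
    rmse: float
    mae: float
    mape: float | None
    r2: float

    def as_dict(self) -> dict:
        return {"mse": self.mse, "rmse": self.rmse, "mae": self.mae,
                "mape": self.mape, "r2": self.r2}


def evaluate_regression(y_true, y_pred) -> RegressionEval:
    """Evaluate predictions with the five standard regression metrics.

    R^2 = 1 - SS_res / SS_tot with SS_tot about the mean of ``y_true``;
    MAPE is reported in percent.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D arrays of equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    err = y_true - y_pred
    mse = float(np.mean(err ** 2))
    rmse = math.sqrt(mse)
    mae = float(np.mean(np.abs(err)))
    if np.any(y_true == 0.0):
        mape: float | None = None
    else:
        mape = float(100.0 * np.mean(np.abs(err / y_true)))
    ss_res = float(np.sum(err ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    return RegressionEval(mse=mse, rmse=rmse, mae=mae, mape=mape, r2=r2)


@dataclass(frozen=True)
class ClassificationEval:
    """Confusion counts at a threshold, F1, and the ROC curve.

    ``auc`` is ``None`` when only one class is present.  ``roc_points``
    is the (fpr, tpr) polyline from the threshold sweep, starting at
    (0, 0) and ending at (1, 1).
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    auc: float | None
    roc_points: np.ndarray  # (k, 2) array of (fpr, tpr)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1, "auc": self.auc}


def evaluate_classifier(y_true, scores, threshold: float = 0.5) -> ClassificationEval:
    """Confusion counts, F1 and ROC/AUC for continuous scores.

    A sample is predicted positive when its score is >= ``threshold``
    (score exactly at the threshold maps to label 1).  F1 is the harmonic
    mean of precision and recall, defined as 0 when both are 0.  The ROC
    curve sweeps thresholds over the unique scores; AUC is the trapezoid
    integral, equal to the Mann-Whitney U statistic over n1*n0.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape or y_true.ndim != 1:
        raise ValueError("y_true and scores must be 1-D arrays of equal length")
    if not np.isin(y_true, (0, 1)).all():
        raise ValueError("y_true must be binary")
    y_true = y_true.astype(int)

    pred = scores >= threshold
    pos = y_true == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0

    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        roc = np.array([[0.0, 0.0], [1.0, 1.0]])
        auc: float | None = None
    else:
        order = np.argsort(-scores, kind="stable")
        sorted_y = y_true[order]
        sorted_s = scores[order]
        tps = np.cumsum(sorted_y)
        fps = np.cumsum(1 - sorted_y)
        # keep the last point of each tied-score run
        distinct = np.r_[sorted_s[1:] != sorted_s[:-1], True]
        tpr = np.r_[0.0, tps[distinct] / n_pos]
        fpr = np.r_[0.0, fps[distinct] / n_neg]
        roc = np.column_stack([fpr, tpr])
        auc = float(np.trapezoid(tpr, fpr))
    return ClassificationEval(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision,
                              recall=recall, f1=f1, auc=auc, roc_points=roc)
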