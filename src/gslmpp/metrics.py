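"""Evaluation metrics: task-averaged AUC-ROC, RMSE and MAE with label masks."""

from __future__ import annotations

import logging

import numpy as np
from sklearn.metrics import roc_auc_score

from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)


def masked_auc(y: np.ndarray, scores: np.ndarray, mask: np.ndarray) -> float:
    """Unweighted mean AUC over tasks, ignoring masked labels.

    Tasks whose observed labels are single-class are skipped with a
    warning; NaN is returned if no task is scoreable.
    """
    aucs = []
    for task in range(y.shape[1]):
        obs = mask[:, task]
        if obs.sum() == 0:
            continue
        yt = y[obs, task]
        if len(np.unique(yt)) < 2:
            logger.warning("task %d has single-class labels; skipped in AUC", task)
            continue
        aucs.append(roc_auc_score(yt, scores[obs, task]))
    return float(np.mean(aucs)) if aucs else float("nan")


def masked_rmse(y: np.ndarray, y_hat: np.ndarray, mask: np.ndarray) -> float:
    d = (y - y_hat)[mask]
    return float(np.sqrt(np.mean(d ** 2)))


def masked_mae(y: np.ndarray, y_hat: np.ndarray, mask: np.ndarray) -> float:
    return float(np.mean(np.abs((y - y_hat)[mask])))


def evaluate_predictions(y: np.ndarray, y_hat: np.ndarray, mask: np.ndarray,
                         task_type: str) -> dict[str, float]:
    """Metric bundle for one split; `y_hat` is probabilities or original units."""
    if task_type == "classification":
        return {"auc": masked_auc(y, y_hat, mask)}
    if task_type == "regression":
        return {"rmse": masked_rmse(y, y_hat, mask),
                "mae": masked_mae(y, y_hat, mask)}
    raise ConfigurationError(f"unknown task type {task_type!r}")
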