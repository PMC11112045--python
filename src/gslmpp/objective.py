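"""Prediction head and the composite loss L = Lpred + w * LGSL.

Lpred is a masked mean over observed labels: binary cross entropy on
logits for classification, mean squared error for regression (targets are
z-scored upstream for regression tasks).

LGSL scores the quality of the final fused adjacency Ã(T) on training
molecules only:

* classification — Ã should match the label-agreement matrix A*
  (A*_ij = 1 iff the labels agree): (Ã_ij − A*_ij)^2 accumulated over
  unordered train pairs.
* regression — property-discordant pairs (|y_i − y_j| > ε_y on the
  standardized scale) should not be connected: Ã_ij^2 accumulated over
  those pairs.

The pair accumulation is normalized by the number of qualifying unordered
pairs (i < j), so the graph loss lives on the same O(1) scale as the
prediction loss regardless of the training-set size; a single qualifying
pair therefore contributes its raw squared term. For multi-task data a
pair counts as label-agreeing only if every co-observed task agrees; pairs
with no co-observed task are skipped. Train sets beyond
`exact_pair_limit` switch to a seeded random subsample of pairs (logged).
"""

from __future__ import annotations

import logging

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import ConfigurationError, InputError, NumericalError

logger = logging.getLogger(__name__)

EXACT_PAIR_LIMIT = 3000


def _arr(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def predict(H_final, weight, bias=None):
    """Linear prediction head: logits (classification) or values (regression)."""
    out = ad.matmul(H_final, weight)
    return out if bias is None else ad.add(out, bias)


def prediction_loss(y_hat, y, mask, task_type: str):
    """Masked mean loss over observed labels (BCE-with-logits or MSE)."""
    mask = np.asarray(mask, dtype=np.float64)
    n_obs = mask.sum()
    if n_obs == 0:
        raise InputError("no observed labels for the prediction loss")
    y_obs = np.where(mask > 0, np.asarray(_arr(y), dtype=np.float64), 0.0)
    if task_type == "regression":
        diff = ad.sub(y_hat, y_obs)
        per_entry = ad.square(diff)
    elif task_type == "classification":
        # numerically stable BCE on logits z:
        # max(z,0) - z*y + log(1 + exp(-|z|))
        z = y_hat
        per_entry = ad.add(ad.sub(ad.relu(z), ad.mul(z, y_obs)),
                           ad.log(ad.add(1.0, ad.exp(ad.neg(ad.absolute(z))))))
    else:
        raise ConfigurationError(f"unknown task type {task_type!r}")
    return ad.div(ad.tsum(ad.mul(per_entry, mask)), float(n_obs))


def _pair_mask(n: int, rng: np.random.Generator | None = None,
               limit: int = EXACT_PAIR_LIMIT) -> np.ndarray:
    """Upper-triangle indicator of the train pairs entering the GSL loss."""
    triu = np.triu(np.ones((n, n)), k=1)
    if n > limit:
        rng = rng or np.random.default_rng(0)
        keep = rng.random((n, n)) < (limit * limit) / (n * n)
        triu = triu * keep
        logger.info("GSL loss pair sum subsampled (%d train molecules)", n)
    return triu


def agreement_matrix(labels: np.ndarray, label_mask: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """A* and the pair-validity mask for (possibly multi-task) class labels.

    A*_ij = 1 iff labels agree on every task observed for both molecules;
    the validity mask zeroes pairs with no co-observed task.
    """
    y = np.atleast_2d(np.asarray(labels, dtype=np.float64))
    if y.shape[0] == 1 and np.asarray(labels).ndim == 1:
        y = y.T
    mask = (np.ones_like(y, dtype=bool) if label_mask is None
            else np.atleast_2d(np.asarray(label_mask, dtype=bool)))
    if mask.shape != y.shape:
        mask = mask.T
    co = mask.astype(np.float64) @ mask.astype(np.float64).T  # co-observed counts
    diff_any = np.zeros((y.shape[0], y.shape[0]), dtype=bool)
    for task in range(y.shape[1]):
        obs = mask[:, task]
        both = np.outer(obs, obs)
        ne = y[:, task][:, None] != y[:, task][None, :]
        diff_any |= both & ne
    a_star = ((~diff_any) & (co > 0)).astype(np.float64)
    valid = (co > 0).astype(np.float64)
    return a_star, valid


def gsl_loss_classification(A_final, labels, train_idx,
                            label_mask=None, rng=None):
    """Mean over qualifying unordered train pairs of (Ã_ij − A*_ij)^2."""
    train_idx = np.asarray(train_idx, dtype=np.intp)
    n = train_idx.size
    if n < 2:
        logger.warning("fewer than 2 train molecules; GSL loss is 0")
        return ad.mul(0.0, ad.tsum(A_final)) if isinstance(A_final, Tensor) else 0.0
    a_tr = ad.take(ad.take(A_final, train_idx, axis=0), train_idx, axis=1)
    a_star, valid = agreement_matrix(np.asarray(labels)[train_idx],
                                     None if label_mask is None
                                     else np.asarray(label_mask)[train_idx])
    pairs = _pair_mask(n, rng) * valid
    n_pairs = max(pairs.sum(), 1.0)
    return ad.div(ad.tsum(ad.mul(ad.square(ad.sub(a_tr, a_star)), pairs)), n_pairs)


def gsl_loss_regression(A_final, y_train, train_idx, epsilon_y: float,
                        label_mask=None, rng=None):
    """Mean of Ã_ij^2 over train pairs whose targets differ by more than ε_y.

    For multi-task targets a pair qualifies if any co-observed task
    differs by more than ε_y.
    """
    if epsilon_y <= 0:
        raise ConfigurationError("epsilon_y must be > 0")
    train_idx = np.asarray(train_idx, dtype=np.intp)
    n = train_idx.size
    if n < 2:
        logger.warning("fewer than 2 train molecules; GSL loss is 0")
        return ad.mul(0.0, ad.tsum(A_final)) if isinstance(A_final, Tensor) else 0.0
    y = np.atleast_2d(np.asarray(y_train, dtype=np.float64))
    if y.shape[0] == 1 and np.asarray(y_train).ndim == 1:
        y = y.T
    y = y[train_idx]
    mask = (np.ones_like(y, dtype=bool) if label_mask is None
            else np.atleast_2d(np.asarray(label_mask, dtype=bool))[train_idx])
    discordant = np.zeros((n, n), dtype=bool)
    for task in range(y.shape[1]):
        obs = mask[:, task]
        both = np.outer(obs, obs)
        far = np.abs(y[:, task][:, None] - y[:, task][None, :]) > epsilon_y
        discordant |= both & far
    a_tr = ad.take(ad.take(A_final, train_idx, axis=0), train_idx, axis=1)
    pairs = _pair_mask(n, rng) * discordant
    n_pairs = max(pairs.sum(), 1.0)
    return ad.div(ad.tsum(ad.mul(ad.square(a_tr), pairs)), n_pairs)


def total_loss(l_pred, l_gsl, gsl_weight: float = 1.0):
    """L = Lpred + gsl_weight * LGSL (gsl_weight = 1 gives the plain sum)."""
    if gsl_weight < 0:
        raise ConfigurationError("gsl_weight must be >= 0")
    if not (np.isfinite(_arr(l_pred)).all() and np.isfinite(_arr(l_gsl)).all()):
        raise NumericalError("non-finite loss component")
    return ad.add(l_pred, ad.mul(gsl_weight, l_gsl))
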