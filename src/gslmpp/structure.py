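"""Metric-based graph structure learning on the molecule similarity graph.

Each refinement round t = 1..T:

1. learns a candidate adjacency A(t) from the current node embeddings with
   an m-perspective weighted cosine metric,
       s_ij = (1/m) * sum_p cos(w_p ⊙ v_i, w_p ⊙ v_j),
2. sparsifies it with an epsilon-neighborhood threshold (negatives and
   sub-threshold entries are dropped, the diagonal is zeroed),
3. fuses it with the fingerprint graph A(0) and the first learned graph
   A(1):  Ã(t) = λ A(0) + (1−λ)(η A(t) + (1−η) A(1)),
4. re-propagates the frozen initial embeddings X_r through an L-layer
   inter-molecule GNN,  H^(t,l) = ReLU(Ã(t) H^(t,l−1) W^(l)),  H^(t,0) = X_r.

By default Ã is lazy-walk normalized before propagation (half-weight
self-loop plus symmetrically degree-normalized neighbors; raw propagation
grows with the row sums and diverges on dense graphs, and unit self-loops
alone lose the node's own signal on heavy neighborhoods); a literal
unnormalized mode is kept for fidelity testing.

All functions accept plain ndarrays (returning ndarrays) or autodiff
Tensors (returning Tensors with gradients tracked), so the same formulas
serve training and oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import ConfigurationError, NumericalError

_EPS = 1e-12


def _arr(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


@dataclass
class GslState:
    """The evolving (embeddings, fused adjacency) pair across refinement rounds."""

    X_r: object                     # initial embedding matrix (frozen in a round)
    H_r: object                     # current node embeddings H_r(t)
    A0: object                      # fingerprint similarity adjacency
    A1: object | None = None        # adjacency learned from X_r at t = 1
    A_fused: object | None = None   # current fused adjacency Ã(t)
    t: int = 0
    trace: list = field(default_factory=list)


def center_embeddings(H):
    """Subtract the column mean: removes the shared embedding direction.

    Graph-level embeddings of similarly sized molecules share a dominant
    rank-one component that saturates raw cosine similarity near 1 for
    every pair; centering restores a discriminative metric.
    """
    return ad.sub(H, ad.tmean(H, axis=0, keepdims=True))


def weighted_cosine(H, perspective_weights):
    """Dense m-perspective weighted cosine similarity matrix.

    `perspective_weights` has shape (m, d). All-zero embedding rows get
    similarity 0 to everything (including themselves).
    """
    W = perspective_weights
    m = _arr(W).shape[0]
    if _arr(W).shape[1] != _arr(H).shape[1]:
        raise ConfigurationError("perspective weight width must match embeddings")
    acc = None
    for p in range(m):
        wp = ad.take(W, [p], axis=0) if isinstance(W, Tensor) else _arr(W)[p:p + 1]
        v = ad.mul(H, wp)
        norms = ad.sqrt(ad.add(ad.tsum(ad.square(v), axis=1, keepdims=True), _EPS))
        vn = ad.div(v, norms)
        s = ad.matmul(vn, ad.transpose(vn))
        acc = s if acc is None else ad.add(acc, s)
    return ad.div(acc, float(m))


def sparsify(S, epsilon_sparsify: float):
    """Epsilon-neighborhood sparsification: entries < eps (and the diagonal) -> 0."""
    if epsilon_sparsify < 0:
        raise ConfigurationError("epsilon_sparsify must be >= 0")
    s_arr = _arr(S)
    mask = (s_arr >= epsilon_sparsify).astype(np.float64)
    np.fill_diagonal(mask, 0.0)
    return ad.mul(S, mask) if isinstance(S, Tensor) else s_arr * mask


def fuse_adjacency(A0, A1, At, lam: float, eta: float):
    """Ã(t) = λ A(0) + (1−λ)(η A(t) + (1−η) A(1))."""
    if not (0.0 <= lam <= 1.0 and 0.0 <= eta <= 1.0):
        raise ConfigurationError("lambda and eta must lie in [0, 1]")
    if not (_arr(A0).shape == _arr(A1).shape == _arr(At).shape):
        raise ConfigurationError("adjacency shapes differ")
    learned = ad.add(ad.mul(eta, At), ad.mul(1.0 - eta, A1))
    return ad.add(ad.mul(lam, A0), ad.mul(1.0 - lam, learned))


def normalize_adjacency(A):
    """Lazy-walk normalization: 0.5 I + 0.5 D^-1/2 A D^-1/2.

    Symmetric degree normalization bounds the spectral radius so deep
    propagation cannot diverge; the explicit half-weight self-loop keeps
    every node's own signal from being drowned by large weighted
    neighborhoods (plain unit self-loops vanish against row sums of
    10+ on dense similarity graphs).
    """
    n = _arr(A).shape[0]
    deg = ad.tsum(A, axis=1, keepdims=True)
    dinv = ad.div(1.0, ad.sqrt(ad.add(deg, _EPS)))
    return ad.add(0.5 * np.eye(n), ad.mul(0.5, ad.mul(ad.mul(A, dinv),
                                                      ad.transpose(dinv))))


def propagate(X_r, A_fused, layer_weights: Sequence, normalize: bool = True,
              collect_layers: bool = False):
    """L applications of H <- ReLU(Ã H W_l), starting from H = X_r.

    With `collect_layers`, also returns the ndarray inputs seen by each
    layer (used to insert new nodes with one-directional message passing).
    """
    if len(layer_weights) == 0:
        raise ConfigurationError("at least one inter-molecule GNN layer is required")
    A_prop = normalize_adjacency(A_fused) if normalize else A_fused
    h = X_r
    layer_inputs = []
    for W in layer_weights:
        if collect_layers:
            layer_inputs.append(_arr(h).copy())
        h = ad.relu(ad.matmul(ad.matmul(A_prop, h), W))
    return (h, layer_inputs) if collect_layers else h


def gsl_iterate(X_r, A0, perspective_weights, epsilon_sparsify: float,
                lam: float, eta: float, layer_weights: Sequence, T: int,
                normalize: bool = True, center_metric: bool = False,
                record_trace: bool = False) -> GslState:
    """T rounds of alternating adjacency refinement and embedding propagation.

    Round t computes A(t) = sparsify(weighted_cosine(H(t−1))) with
    H(0) = X_r, caches A(1), fuses, and re-propagates from X_r. Returns the
    final state (H_r(T), Ã(T), A(1)); with `record_trace` the state carries
    the per-round (A(t), Ã(t), H(t)) values for inspection. With
    `center_metric` the embeddings are column-centered before the metric
    (see :func:`center_embeddings`); the plain metric is the default.
    """
    if T < 1:
        raise ConfigurationError("T must be >= 1")
    state = GslState(X_r=X_r, H_r=X_r, A0=A0)
    for t in range(1, T + 1):
        h_prev = state.H_r
        h_metric = center_embeddings(h_prev) if center_metric else h_prev
        s_mat = weighted_cosine(h_metric, perspective_weights)
        a_t = sparsify(s_mat, epsilon_sparsify)
        if t == 1:
            state.A1 = a_t
        a_fused = fuse_adjacency(A0, state.A1, a_t, lam, eta)
        if record_trace:
            h, layer_inputs = propagate(X_r, a_fused, layer_weights,
                                        normalize=normalize, collect_layers=True)
        else:
            h = propagate(X_r, a_fused, layer_weights, normalize=normalize)
        if not np.all(np.isfinite(_arr(h))):
            raise NumericalError(f"non-finite embeddings at GSL round {t}")
        state.H_r, state.A_fused, state.t = h, a_fused, t
        if record_trace:
            state.trace.append({
                "t": t,
                "H_prev": _arr(h_prev).copy(),
                "metric_mean": (_arr(h_prev).mean(axis=0, keepdims=True)
                                if center_metric else None),
                "A_t": _arr(a_t).copy(),
                "A_fused": _arr(a_fused).copy(),
                "degrees": _arr(a_fused).sum(axis=1),
                "layer_inputs": layer_inputs,
                "H": _arr(h).copy(),
            })
    return state
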