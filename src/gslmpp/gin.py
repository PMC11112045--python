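"""Graph isomorphism network (GIN) encoder for atom-level molecular graphs.

Node update per layer:

    h_v^(k) = MLP^(k)( (1 + eps^(k)) * h_v^(k-1) + sum_{u in N(v)} h_u^(k-1) )

with h_v^(0) the atom feature vector and eps^(k) a learnable scalar
initialized at 0. The readout pools node embeddings per layer (k = 0..K,
sum or mean), concatenates the pooled vectors and projects linearly to the
embedding width, giving the initial molecular embedding h_g.

The per-layer MLP is linear -> layer normalization -> ReLU -> linear; the
normalization is per-node, so encoding is independent of how molecules are
batched together.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Tensor
from .chem_io import MolecularGraph
from .exceptions import ConfigurationError, InputError


def neighbor_sum_matrix(graph: MolecularGraph) -> sp.csr_matrix:
    """Symmetric 0/1 adjacency whose product with H sums neighbor embeddings."""
    n = graph.n_v
    if graph.n_e == 0:
        return sp.csr_matrix((n, n))
    r = graph.edges[:, 0]
    c = graph.edges[:, 1]
    data = np.ones(2 * graph.n_e)
    return sp.csr_matrix((data, (np.r_[r, c], np.r_[c, r])), shape=(n, n))


def gin_layer(graph: MolecularGraph, h_prev, eps: float = 0.0,
              mlp: Callable | None = None):
    """One GIN update; `mlp=None` means the identity map.

    Accepts a plain ndarray or a Tensor for `h_prev`; isolated nodes
    aggregate only their own scaled embedding.
    """
    h_prev_arr = h_prev.data if isinstance(h_prev, Tensor) else np.asarray(h_prev)
    if h_prev_arr.shape[0] != graph.n_v:
        raise ConfigurationError("h_prev row count must equal n_v")
    agg = ad.spmm(neighbor_sum_matrix(graph), h_prev)
    out = ad.add(ad.mul(1.0 + eps, h_prev), agg)
    return mlp(out) if mlp is not None else out


def readout(per_layer_node_embeddings: Sequence, mode: str = "sum"):
    """Pool each layer's node embeddings over nodes and concatenate.

    Returns a single-row matrix of width sum of per-layer dims (the linear
    projection to the embedding width is applied by the encoder).
    """
    if not per_layer_node_embeddings:
        raise InputError("readout requires at least one layer of embeddings")
    if mode not in ("sum", "mean"):
        raise ConfigurationError(f"unknown readout mode {mode!r}")
    pooled = []
    for h in per_layer_node_embeddings:
        n = (h.data if isinstance(h, Tensor) else np.asarray(h)).shape[0]
        if n == 0:
            raise InputError("empty graph in readout")
        p = ad.tsum(h, axis=0, keepdims=True)
        if mode == "mean":
            p = ad.div(p, float(n))
        pooled.append(p)
    return ad.concat(pooled, axis=1)


class GinEncoder:
    """K-layer GIN with layer-concatenated readout and linear projection.

    Parameters
    ----------
    in_dim : width of the atom feature vectors.
    hidden_dim : embedding width of every hidden layer and of h_g.
    K : number of message-passing layers (>= 1).
    readout_mode : "sum" (default) or "mean" node pooling per layer.
    rng : seeded generator for weight initialization.
    """

    def __init__(self, in_dim: int, hidden_dim: int = 128, K: int = 3,
                 readout_mode: str = "sum",
                 rng: np.random.Generator | None = None):
        if K < 1:
            raise ConfigurationError("K must be >= 1")
        if readout_mode not in ("sum", "mean"):
            raise ConfigurationError(f"unknown readout mode {readout_mode!r}")
        rng = rng or np.random.default_rng(0)
        self.in_dim = in_dim
        self.hidden_dim = hidden_dim
        self.K = K
        self.readout_mode = readout_mode
        self.params: dict[str, Tensor] = {}
        d_prev = in_dim
        for k in range(K):
            p = self.params
            p[f"gin{k}_W1"] = ad.parameter((d_prev, hidden_dim), rng)
            p[f"gin{k}_b1"] = Tensor(np.zeros((1, hidden_dim)), requires_grad=True)
            p[f"gin{k}_gamma"] = Tensor(np.ones((1, hidden_dim)), requires_grad=True)
            p[f"gin{k}_beta"] = Tensor(np.zeros((1, hidden_dim)), requires_grad=True)
            p[f"gin{k}_W2"] = ad.parameter((hidden_dim, hidden_dim), rng)
            p[f"gin{k}_b2"] = Tensor(np.zeros((1, hidden_dim)), requires_grad=True)
            p[f"gin{k}_eps"] = Tensor(np.zeros((1, 1)), requires_grad=True)
            d_prev = hidden_dim
        concat_dim = in_dim + K * hidden_dim
        self.params["readout_W"] = ad.parameter((concat_dim, hidden_dim), rng)
        self.params["readout_b"] = Tensor(np.zeros((1, hidden_dim)), requires_grad=True)

    # -- internals ---------------------------------------------------------
    def _layernorm(self, x, k: int):
        mu = ad.tmean(x, axis=1, keepdims=True)
        xc = ad.sub(x, mu)
        var = ad.tmean(ad.square(xc), axis=1, keepdims=True)
        xn = ad.div(xc, ad.sqrt(ad.add(var, 1e-5)))
        return ad.add(ad.mul(xn, self.params[f"gin{k}_gamma"]),
                      self.params[f"gin{k}_beta"])

    def _mlp(self, x, k: int):
        p = self.params
        h = ad.add(ad.matmul(x, p[f"gin{k}_W1"]), p[f"gin{k}_b1"])
        h = ad.relu(self._layernorm(h, k))
        return ad.add(ad.matmul(h, p[f"gin{k}_W2"]), p[f"gin{k}_b2"])

    def _encode_block(self, graphs: Sequence[MolecularGraph]) -> Tensor:
        x0 = np.concatenate([g.node_features for g in graphs], axis=0)
        adj = sp.block_diag([neighbor_sum_matrix(g) for g in graphs], format="csr")
        sizes = [g.n_v for g in graphs]
        offs = np.cumsum([0] + sizes)
        # pooling matrix: molecule x atom, sum or mean over each molecule's atoms
        rows = np.repeat(np.arange(len(graphs)), sizes)
        cols = np.arange(offs[-1])
        vals = (np.ones(offs[-1]) if self.readout_mode == "sum"
                else 1.0 / np.repeat(np.asarray(sizes, dtype=np.float64), sizes))
        pool = sp.csr_matrix((vals, (rows, cols)), shape=(len(graphs), offs[-1]))

        h = Tensor(x0)
        pooled = [ad.spmm(pool, h)]
        for k in range(self.K):
            eps_k = self.params[f"gin{k}_eps"]
            agg = ad.spmm(adj, h)
            h = self._mlp(ad.add(ad.mul(ad.add(1.0, eps_k), h), agg), k)
            pooled.append(ad.spmm(pool, h))
        cat = ad.concat(pooled, axis=1)
        return ad.add(ad.matmul(cat, self.params["readout_W"]),
                      self.params["readout_b"])

    # -- public API ---------------------------------------------------------
    def encode(self, graphs: Sequence[MolecularGraph],
               batch_size: int | None = None) -> Tensor:
        """Embedding matrix: row i is h_g of graphs[i].

        Results are independent of the batch partition because all per-node
        operations (including the normalization) are batch-independent.
        """
        if not graphs:
            raise InputError("no graphs to encode")
        if batch_size is None or batch_size >= len(graphs):
            return self._encode_block(graphs)
        blocks = [self._encode_block(graphs[i:i + batch_size])
                  for i in range(0, len(graphs), batch_size)]
        return ad.concat(blocks, axis=0)

    def state_dict(self) -> dict[str, np.ndarray]:
        meta = {"__in_dim": np.array(self.in_dim), "__hidden_dim": np.array(self.hidden_dim),
                "__K": np.array(self.K),
                "__readout": np.array(1 if self.readout_mode == "mean" else 0)}
        return {**{k: v.data.copy() for k, v in self.params.items()}, **meta}

    @classmethod
    def from_state_dict(cls, state: dict[str, np.ndarray]) -> "GinEncoder":
        enc = cls(int(state["__in_dim"]), int(state["__hidden_dim"]), int(state["__K"]),
                  "mean" if int(state["__readout"]) else "sum")
        for k in enc.params:
            enc.params[k].data = np.asarray(state[k], dtype=np.float64).copy()
        return enc


def encode_molecules(graphs: Sequence[MolecularGraph], encoder: GinEncoder,
                     batch_size: int | None = None) -> np.ndarray:
    """Convenience wrapper returning the embedding matrix as an ndarray."""
    return encoder.encode(graphs, batch_size=batch_size).data
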