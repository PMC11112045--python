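"""The molecule similarity graph (MSG) built from fingerprint Tanimoto scores.

Nodes are molecules; an edge (i, j) carries the Tanimoto similarity of the
two fingerprints whenever it reaches the threshold ``epsilon_tc`` (the
comparison is inclusive: ties survive). The diagonal is excluded at
construction — self-connectivity is introduced only during propagation.

The pairwise computation is dense and O(n^2); a hard node-count guard
refuses inputs beyond ``max_nodes`` since no sub-quadratic (anchor-based)
approximation is implemented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .chem_io import Fingerprint
from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

DEFAULT_MAX_NODES = 20_000


@dataclass
class SimilarityGraph:
    """Sparse symmetric weighted molecule-level graph."""

    molecule_ids: list[str]
    adjacency: sp.csr_matrix
    epsilon_tc: float

    @property
    def n(self) -> int:
        return len(self.molecule_ids)

    def dense(self) -> np.ndarray:
        return self.adjacency.toarray()


def pairwise_tanimoto(fingerprints: list[Fingerprint]) -> np.ndarray:
    """Dense symmetric matrix of pairwise Tanimoto similarities."""
    first = fingerprints[0]
    for fp in fingerprints[1:]:
        if not fp.comparable_with(first):
            raise ConfigurationError("fingerprints not mutually comparable")
    bits = np.stack([fp.bits for fp in fingerprints]).astype(np.float64)
    inter = bits @ bits.T
    pop = bits.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1.0), 0.0)
    return sim


def build_initial_adjacency(fingerprints: list[Fingerprint],
                            epsilon_tc: float = 0.3,
                            molecule_ids: list[str] | None = None,
                            max_nodes: int = DEFAULT_MAX_NODES) -> SimilarityGraph:
    """Construct A(0): Tanimoto weights >= epsilon_tc, zero diagonal."""
    if not fingerprints:
        raise InputError("empty molecule list")
    if not 0.0 <= epsilon_tc <= 1.0:
        raise ConfigurationError("epsilon_tc must lie in [0, 1]")
    n = len(fingerprints)
    if n > max_nodes:
        raise ConfigurationError(
            f"{n} molecules exceeds the dense pairwise guard ({max_nodes}); "
            "an anchor-based similarity approximation is not implemented")
    sim = pairwise_tanimoto(fingerprints)
    np.fill_diagonal(sim, 0.0)
    sim[sim < epsilon_tc] = 0.0
    ids = molecule_ids if molecule_ids is not None else [f"mol{i}" for i in range(n)]
    if len(ids) != n:
        raise ConfigurationError("molecule_ids length mismatch")
    return SimilarityGraph(list(ids), sp.csr_matrix(sim), float(epsilon_tc))


def graph_stats(graph: SimilarityGraph) -> dict:
    """Node/edge counts, density, isolated nodes and weight quantiles."""
    n = graph.n
    coo = sp.triu(graph.adjacency, k=1).tocoo()
    n_edges = coo.nnz
    degrees = np.asarray((graph.adjacency != 0).sum(axis=1)).ravel()
    weights = coo.data
    quantiles = (np.quantile(weights, [0.0, 0.25, 0.5, 0.75, 1.0]).tolist()
                 if n_edges else [0.0] * 5)
    return {
        "n_nodes": n,
        "n_edges": int(n_edges),
        "density": 2.0 * n_edges / (n * (n - 1)) if n > 1 else 0.0,
        "n_isolated": int(np.count_nonzero(degrees == 0)),
        "weight_quantiles": quantiles,
    }


# ---------------------------------------------------------------------------
# text exchange formats

def write_edgelist(graph: SimilarityGraph, path) -> None:
    """Write `node_i node_j weight` (0-based, upper triangle) plus a header."""
    coo = sp.triu(graph.adjacency, k=1).tocoo()
    with open(path, "w") as fh:
        fh.write(f"# n={graph.n} epsilon_tc={graph.epsilon_tc}\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i} {j} {w:.10g}\n")


def read_edgelist(path, molecule_ids: list[str] | None = None) -> SimilarityGraph:
    n = None
    eps = 0.0
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    key, _, val = tok.partition("=")
                    if key == "n":
                        n = int(val)
                    elif key == "epsilon_tc":
                        eps = float(val)
                continue
            i, j, w = line.split()
            rows.append(int(i))
            cols.append(int(j))
            vals.append(float(w))
    if n is None:
        n = max(rows + cols) + 1 if rows else 0
    adj = sp.coo_matrix((vals + vals, (rows + cols, cols + rows)), shape=(n, n))
    ids = molecule_ids if molecule_ids is not None else [f"mol{i}" for i in range(n)]
    return SimilarityGraph(list(ids), adj.tocsr(), eps)


def write_mtx(graph: SimilarityGraph, path) -> None:
    mmwrite(str(path), graph.adjacency.tocoo(), symmetry="symmetric")


def read_mtx(path, epsilon_tc: float = 0.0,
             molecule_ids: list[str] | None = None) -> SimilarityGraph:
    adj = sp.csr_matrix(mmread(str(path)))
    n = adj.shape[0]
    ids = molecule_ids if molecule_ids is not None else [f"mol{i}" for i in range(n)]
    return SimilarityGraph(list(ids), adj, float(epsilon_tc))
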