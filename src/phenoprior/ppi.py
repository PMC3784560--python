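"""Protein-interaction feature via truncated network communicability.

Communicability between two nodes sums the number of walks connecting them,
down-weighting a walk of length k by 1/k!.  The series is truncated at walk
length 6 by default: G = sum_{k=1..L} A^k / k!.  The k = 0 identity term is
excluded because self-communicability carries no cross-node information.  A
gene's feature is its total communicability to the training-gene proteins,
excluding itself when it is a training gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CommunicabilityMatrix",
    "truncated_communicability",
    "training_communicability_score",
    "communicability_to_training",
]

DEFAULT_MAX_LEN = 6


@dataclass(frozen=True)
class CommunicabilityMatrix:
    """Dense truncated-communicability matrix with its node order."""

    nodes: tuple[str, ...]
    values: np.ndarray  # (n, n), symmetric, nonnegative

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("matrix shape does not match node count")

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def get(self, u: str, v: str) -> float:
        idx = self.index
        return float(self.values[idx[u], idx[v]])


def _check_graph(graph: nx.Graph) -> None:
    if any(u == v for u, v in graph.edges):
        raise ValueError("self-loops are not allowed in the interaction network")


def truncated_communicability(
    graph: nx.Graph, max_len: int = DEFAULT_MAX_LEN
) -> CommunicabilityMatrix:
    """Dense G = sum_{k=1..max_len} A^k / k! over the graph's nodes.

    Intended for small to medium graphs; use
    :func:`communicability_to_training` to score against a target set on
    large sparse networks without forming the full matrix.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    _check_graph(graph)
    nodes = tuple(graph.nodes)
    n = len(nodes)
    if n == 0:
        return CommunicabilityMatrix(nodes=(), values=np.zeros((0, 0)))
    a = nx.to_numpy_array(graph, nodelist=nodes, dtype=float)
    total = np.zeros_like(a)
    power = np.eye(n)
    for k in range(1, max_len + 1):
        power = power @ a
        total += power / factorial(k)
    return CommunicabilityMatrix(nodes=nodes, values=total)


def training_communicability_score(
    gene: str, comm: CommunicabilityMatrix, training: Iterable[str]
) -> float:
    """Sum of G[gene, t] over training genes t != gene present in the network.

    ``nan`` if the gene itself is not a network node.
    """
    idx = comm.index
    if gene not in idx:
        return float("nan")
    gi = idx[gene]
    return float(
        sum(comm.values[gi, idx[t]] for t in set(training) if t in idx and t != gene)
    )


def communicability_to_training(
    graph: nx.Graph,
    training: Iterable[str],
    max_len: int = DEFAULT_MAX_LEN,
    per_training: bool = False,
) -> pd.Series | pd.DataFrame:
    """Training-communicability scores for every node, without the full matrix.

    Computes the training columns of the truncated series by iterated sparse
    matrix-vector products, then sums them per node (excluding the node's own
    column when it is a training gene).

    Parameters
    ----------
    per_training
        If True, return the genes x training-genes column block instead of
        the per-gene sums (used by leave-one-out cross-validation, which
        drops one training column at a time).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    _check_graph(graph)
    nodes = list(graph.nodes)
    train = sorted(set(training) & set(nodes))
    if not nodes:
        empty = pd.Series(dtype=float, name="ppi")
        return empty.to_frame() if per_training else empty
    a = nx.to_scipy_sparse_array(graph, nodelist=nodes, dtype=float, format="csr")
    if not train:
        zero = np.zeros((len(nodes), 0))
        block = pd.DataFrame(zero, index=nodes, columns=train)
        if per_training:
            return block
        return pd.Series(0.0, index=nodes, name="ppi")
    node_pos = {n: i for i, n in enumerate(nodes)}
    cols = [node_pos[t] for t in train]
    seed = np.zeros((len(nodes), len(train)))
    seed[cols, range(len(train))] = 1.0
    acc = np.zeros_like(seed)
    cur = seed
    for k in range(1, max_len + 1):
        cur = a @ cur
        acc += cur / factorial(k)
    block = pd.DataFrame(acc, index=nodes, columns=train)
    if per_training:
        return block
    return sum_training_block(block)


def sum_training_block(block: pd.DataFrame) -> pd.Series:
    """Per-gene sums of a genes x training communicability block, excluding
    each training gene's own column from its sum."""
    totals = block.sum(axis=1)
    for t in block.columns:
        if t in totals.index:
            totals.loc[t] -= block.at[t, t]
    totals.name = "ppi"
    return totals
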