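"""Weighted drug network and its column-stochastic transition operator.

Nodes are drugs; two drugs are adjacent iff they share a chemical-chemical
interaction with a positive integrated evidence score, and the edge weight
is that score. The transition matrix divides each column by its sum, so a
walker at drug j moves to neighbour i with probability w(i,j)/deg_w(j);
columns of isolated drugs stay all-zero (no self-loop is injected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import scipy.sparse as sp

from .io import InteractionRecord

__all__ = ["DrugNetwork", "TransitionMatrix", "build_network", "column_normalize"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class DrugNetwork:
    """Symmetric weighted graph over a fixed, lexicographically ordered drug set."""

    nodes: tuple[str, ...]
    adjacency: sp.csr_matrix  # symmetric, zero diagonal, weights > 0 on edges
    dropped_records: int = 0
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {d: i for i, d in enumerate(self.nodes)})

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def __contains__(self, drug: str) -> bool:
        return drug in self._index

    def node_position(self, drug: str) -> int:
        try:
            return self._index[drug]
        except KeyError:
            raise KeyError(f"drug {drug!r} is not a network node") from None

    def weight(self, drug_a: str, drug_b: str) -> float:
        if drug_a == drug_b:
            return 0.0
        return float(self.adjacency[self.node_position(drug_a), self.node_position(drug_b)])

    def degrees(self) -> np.ndarray:
        """Number of neighbours per node, in node order."""
        return np.diff(self.adjacency.indptr)

    def neighbors(self, drug: str) -> tuple[str, ...]:
        row = self.adjacency.getrow(self.node_position(drug))
        return tuple(self.nodes[j] for j in row.indices)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Each undirected edge once, endpoints in node order."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            yield self.nodes[i], self.nodes[j], float(w)


@dataclass(frozen=True, eq=False)
class TransitionMatrix:
    """Columnwise-normalized adjacency: entry (i, j) = w(i,j) / sum_k w(k,j).

    Every column of a non-isolated node sums to one; isolated columns are
    all-zero, so the operator is sub-stochastic on networks with isolated
    drugs.
    """

    nodes: tuple[str, ...]
    matrix: sp.csr_matrix

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def build_network(
    records: Iterable[InteractionRecord], drug_universe: Iterable[str]
) -> DrugNetwork:
    """Assemble the drug network over ``drug_universe``.

    Records mentioning a drug outside the universe are dropped (real
    interaction dumps contain many extra chemicals); the count of dropped
    records is logged and kept on the returned network. Drugs with no
    surviving record become isolated nodes.
    """
    nodes = tuple(sorted({str(d) for d in drug_universe}))
    if not nodes:
        raise ValueError("drug universe is empty")
    index = {d: i for i, d in enumerate(nodes)}

    # readers collapse duplicates already; collapse again (max) defensively
    best: dict[tuple[int, int], float] = {}
    dropped = 0
    for rec in records:
        ia = index.get(rec.drug_a)
        ib = index.get(rec.drug_b)
        if ia is None or ib is None:
            dropped += 1
            continue
        key = (ia, ib) if ia < ib else (ib, ia)
        w = float(rec.score)
        if w > best.get(key, 0.0):
            best[key] = w
    if dropped:
        logger.info("build_network: dropped %d record(s) outside the drug universe", dropped)

    n = len(nodes)
    rows = [i for i, _ in best] + [j for _, j in best]
    cols = [j for _, j in best] + [i for i, _ in best]
    data = list(best.values()) * 2
    adjacency = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return DrugNetwork(nodes=nodes, adjacency=adjacency, dropped_records=dropped)


def column_normalize(network: DrugNetwork) -> TransitionMatrix:
    """Divide each adjacency column by its weighted degree (zero-safe)."""
    adjacency = network.adjacency.tocsc()
    colsums = np.asarray(adjacency.sum(axis=0)).ravel()
    inv = np.divide(1.0, colsums, out=np.zeros_like(colsums, dtype=float), where=colsums > 0)
    matrix = (adjacency @ sp.diags(inv)).tocsr()
    return TransitionMatrix(nodes=network.nodes, matrix=matrix)
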