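"""Shared fixtures: tiny hand-checkable networks and random instances."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from negsel.io import InteractionRecord, PositivePairTable, SideEffectIndex, build_index
from negsel.network import DrugNetwork, build_network

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def path_network() -> DrugNetwork:
    """Three-node path a-b-c with equal weights."""
    records = [InteractionRecord("a", "b", 999), InteractionRecord("b", "c", 999)]
    return build_network(records, {"a", "b", "c"})


@pytest.fixture
def star_network() -> DrugNetwork:
    """Hub h with three equally weighted leaves."""
    records = [InteractionRecord("h", f"l{i}", 500) for i in range(3)]
    return build_network(records, {"h", "l0", "l1", "l2"})


def random_instance(
    seed: int,
    n_drugs: int = 30,
    n_side_effects: int = 4,
    edge_prob: float = 0.08,
) -> tuple[DrugNetwork, SideEffectIndex, PositivePairTable]:
    """A random sparse weighted graph plus a random side-effect index."""
    rng = np.random.default_rng(seed)
    drugs = [f"d{i:02d}" for i in range(n_drugs)]
    records = []
    for i in range(n_drugs):
        for j in range(i + 1, n_drugs):
            if rng.random() < edge_prob:
                records.append(
                    InteractionRecord(drugs[i], drugs[j], int(rng.integers(1, 1000)))
                )
    pairs: set[tuple[str, str]] = set()
    for k in range(n_side_effects):
        n_owners = int(rng.integers(2, 6))
        owners = rng.choice(n_drugs, size=n_owners, replace=False)
        pairs.update((drugs[int(i)], f"s{k}") for i in owners)
    positives = PositivePairTable.from_iterable(pairs)
    network = build_network(records, drugs)
    return network, build_index(positives), positives


def bfs_reachable(network: DrugNetwork, seeds: set[str]) -> set[str]:
    """Independent reachability oracle via breadth-first search."""
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(network.nodes)
    graph.add_weighted_edges_from(network.edges())
    reachable: set[str] = set()
    for seed in seeds:
        reachable |= set(nx.bfs_tree(graph, seed))
    return reachable
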