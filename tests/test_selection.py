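"""Candidate extraction, NDS assembly, partitioning and the score diagnostic."""

import numpy as np
import pytest

from negsel.io import InteractionRecord, PositivePairTable, SideEffectIndex, build_index
from negsel.network import build_network
from negsel.selection import (
    DEFAULT_EPSILON_GRID,
    build_nds,
    compute_probabilities,
    epsilon_grid_from_probabilities,
    partition_by_probability,
    score_distribution_diagnostic,
    select_candidates_for_side_effect,
)

from conftest import bfs_reachable, random_instance


def three_node_instance():
    """Edge a-b, c isolated; side effect s owned by {a}."""
    net = build_network([InteractionRecord("a", "b", 500)], {"a", "b", "c"})
    positives = PositivePairTable.from_iterable([("a", "s")])
    return net, build_index(positives), positives


class TestCandidateSelection:
    def test_zero_threshold_keeps_only_unreachable_non_positives(self):
        net, index, positives = three_node_instance()
        probs = compute_probabilities(net, index)["s"]
        assert select_candidates_for_side_effect("s", probs, 0.0, positives) == [
            ("c", "s", 0.0)
        ]

    def test_vacuous_threshold_selects_all_non_positive_drugs(self):
        net, index, positives = three_node_instance()
        probs = compute_probabilities(net, index)["s"]
        selected = select_candidates_for_side_effect("s", probs, 1.0, positives)
        assert {d for d, _, _ in selected} == {"b", "c"}

    def test_all_owners_world_selects_nothing(self):
        net = build_network([InteractionRecord("a", "b", 500)], {"a", "b"})
        positives = PositivePairTable.from_iterable([("a", "s"), ("b", "s")])
        probs = compute_probabilities(net, build_index(positives))["s"]
        assert select_candidates_for_side_effect("s", probs, 1.0, positives) == []

    def test_threshold_is_inclusive(self):
        net, index, positives = three_node_instance()
        probs = compute_probabilities(net, index)["s"]
        p_b = probs["b"]
        selected = select_candidates_for_side_effect("s", probs, p_b, positives)
        assert ("b", "s", pytest.approx(p_b)) in [
            (d, s, p) for d, s, p in selected
        ]


class TestBuildNds:
    def test_single_side_effect_zero_eps_equals_unreachable_set(self):
        net, index, _ = random_instance(2, edge_prob=0.05)
        nds = build_nds(net, index, 0.0)
        for se in index:
            reachable = bfs_reachable(net, set(index[se]))
            expected = {
                (d, se) for d in net.nodes if d not in reachable
            } - {(d, se) for d in index[se]}
            got = {(d, s) for d, s, _ in nds if s == se}
            assert got == expected

    def test_connected_network_zero_eps_empty(self):
        # a path through every node: everything reachable from any seed
        drugs = [f"d{i}" for i in range(6)]
        records = [
            InteractionRecord.canonical(drugs[i], drugs[i + 1], 100)
            for i in range(5)
        ]
        net = build_network(records, drugs)
        positives = PositivePairTable.from_iterable([("d0", "s"), ("d3", "s")])
        assert len(build_nds(net, build_index(positives), 0.0)) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_nds_size_nondecreasing_in_threshold(self, seed):
        net, index, _ = random_instance(seed)
        probs = compute_probabilities(net, index)
        sizes = [
            len(build_nds(net, index, eps, probabilities=probs))
            for eps in (0.0, 1e-4, 1e-3, 1e-2, 1.0)
        ]
        assert sizes == sorted(sizes)

    @pytest.mark.parametrize("seed", range(4))
    def test_nds_nested_under_growing_threshold(self, seed):
        net, index, _ = random_instance(seed)
        probs = compute_probabilities(net, index)
        small = build_nds(net, index, 1e-4, probabilities=probs).pairs()
        large = build_nds(net, index, 1e-2, probabilities=probs).pairs()
        assert small <= large

    def test_side_effect_without_network_seed_is_an_error(self):
        net = build_network([InteractionRecord("a", "b", 10)], {"a", "b"})
        index = SideEffectIndex({"s": frozenset({"zz"})})
        with pytest.raises(ValueError, match="'s'"):
            compute_probabilities(net, index)


class TestPartition:
    def test_printed_interval_brackets(self):
        grid = DEFAULT_EPSILON_GRID
        cases = {
            0.0: 1,        # closed first cell [0, 0]
            2e-7: 2,       # open cell (0, 5e-7)
            5e-7: 3,       # boundary belongs to the half-open cell above it
            3e-6: 3,
            5e-6: 4,
            5.5e-5: 9,
            6e-5: 9,       # final cell closed on the right
        }
        for p, expected in cases.items():
            assert partition_by_probability([("d", "s", p)], grid) == [expected]

    def test_probability_above_grid_is_an_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            partition_by_probability([("d", "s", 7e-5)], DEFAULT_EPSILON_GRID)

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        triples = [("d", "s", float(p)) for p in rng.uniform(0, 6e-5, size=200)]
        parts = partition_by_probability(triples, DEFAULT_EPSILON_GRID)
        assert len(parts) == 200
        assert set(parts) <= set(range(1, 10))

    def test_nondecreasing_with_probability(self):
        grid = (0.0, 0.1, 0.2, 0.4)
        ps = [0.0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4]
        parts = partition_by_probability([("d", "s", p) for p in ps], grid)
        assert parts == sorted(parts)


class TestScoreDiagnostic:
    def test_no_edges_to_owners_means_all_zero_bin(self):
        net, index, positives = three_node_instance()
        dist = score_distribution_diagnostic([("c", "s", 0.0)], net, index)
        assert dist.proportions.loc[1, "zero"] == pytest.approx(1.0)

    def test_hand_binning_of_two_scores(self):
        records = [
            InteractionRecord("d", "o1", 100),
            InteractionRecord("d", "o2", 950),
        ]
        net = build_network(records, {"d", "o1", "o2"})
        index = build_index(
            PositivePairTable.from_iterable([("o1", "s"), ("o2", "s")])
        )
        dist = score_distribution_diagnostic([("d", "s", 0.0)], net, index, n_bins=10)
        counts = dist.counts.loc[1]
        assert counts["(99.9, 199.8]"] == 1
        assert counts["(899.1, 999.0]"] == 1
        assert counts.sum() == 2

    def test_exclude_zeros_mode_flags_empty_parts(self):
        net, index, _ = three_node_instance()
        dist = score_distribution_diagnostic(
            [("c", "s", 0.0)], net, index, include_zeros=False
        )
        assert dist.empty_parts == (1,)


class TestQuantileGrid:
    def test_grid_strictly_increasing_and_top_covers_everything(self):
        net, index, positives = random_instance(7)
        probs = compute_probabilities(net, index)
        grid = epsilon_grid_from_probabilities(probs, positives)
        assert list(grid) == sorted(set(grid))
        nds_top = build_nds(net, index, grid[-1], probabilities=probs)
        n_non_positive = sum(
            1 for se in index for d in net.nodes if (d, se) not in positives
        )
        assert len(nds_top) == n_non_positive
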