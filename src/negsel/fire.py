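"""FIRE-style negative selection: reliability by absence of direct links.

The comparator strategy scores each non-positive (drug, side effect) pair
by the drug's direct interaction-score links to the drugs owning the side
effect — here the maximum direct edge weight, which is order-independent
and zero exactly when no direct edge exists. Pairs with score zero (drug
at graph distance > 1 from every carrier) are selected as negatives.

Unlike the walk-based strategy, this ignores longer paths: every pair
whose drug merely lacks a *direct* link is treated as equally reliable,
whereas the walk probability still distinguishes near-misses from drugs
many hops away. The zero-probability set is therefore always contained in
the zero-score set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .io import PositivePairTable, SideEffectIndex
from .network import DrugNetwork

__all__ = ["FireScore", "FirePartitionReport", "fire_score", "fire_select", "fire_partition_report"]


@dataclass(frozen=True)
class FireScore:
    drug: str
    side_effect: str
    score: float  # max direct edge weight to a carrier; 0 iff no direct edge

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("interaction scores are non-negative")


def fire_score(
    drug: str, side_effect: str, network: DrugNetwork, index: SideEffectIndex
) -> FireScore:
    """Maximum direct edge weight between ``drug`` and the other carriers."""
    if side_effect not in index:
        raise KeyError(f"unknown side effect {side_effect!r}")
    owners = index[side_effect] - {drug}
    best = 0.0
    for owner in owners:
        if owner in network and drug in network:
            w = network.weight(drug, owner)
            if w > best:
                best = w
    return FireScore(drug, side_effect, best)


def fire_select(
    network: DrugNetwork, index: SideEffectIndex, positives: PositivePairTable
) -> frozenset[tuple[str, str]]:
    """All non-positive pairs whose drug has no direct edge to any carrier."""
    selected: set[tuple[str, str]] = set()
    adjacency = {d: set(network.neighbors(d)) for d in network.nodes}
    for se in sorted(index):
        owners = index[se]
        for drug in network.nodes:
            if (drug, se) in positives:
                continue
            if not (adjacency[drug] & (owners - {drug})):
                selected.add((drug, se))
    return frozenset(selected)


@dataclass(frozen=True, eq=False)
class FirePartitionReport:
    """Overlap between a FIRE selection and walk-derived quality parts."""

    coverage: dict[int, float]  # per part: fraction of its members FIRE also selects
    distribution: dict[int, float]  # fraction of covered FIRE pairs per part
    n_fire: int
    n_fire_outside_parts: int  # FIRE pairs not present in the partitioned set


def fire_partition_report(
    fire_set: frozenset[tuple[str, str]],
    rwr_parts: Mapping[tuple[str, str], int],
) -> FirePartitionReport:
    """Cross-tabulate a FIRE selection against walk-probability parts."""
    part_sizes: dict[int, int] = {}
    hits: dict[int, int] = {}
    for pair, part in rwr_parts.items():
        part_sizes[part] = part_sizes.get(part, 0) + 1
        if pair in fire_set:
            hits[part] = hits.get(part, 0) + 1
    coverage = {part: hits.get(part, 0) / size for part, size in sorted(part_sizes.items())}
    covered = sum(hits.values())
    distribution = {
        part: (hits.get(part, 0) / covered if covered else 0.0)
        for part in sorted(part_sizes)
    }
    outside = sum(1 for pair in fire_set if pair not in rwr_parts)
    return FirePartitionReport(coverage, distribution, len(fire_set), outside)
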