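"""Refined negative-sample selection from random-walk probabilities.

For each side effect, the drugs owning it seed a random walk with restart
on the drug network; drugs whose stationary probability does not exceed a
threshold epsilon are paired with the side effect as candidate negatives.
The union over all side effects is the negative dataset (NDS). Small
thresholds keep only drugs essentially unrelated to every known carrier of
the side effect — at epsilon = 0, exactly the drugs with no path to any
seed.

The module also partitions a selected set into quality parts along a
threshold grid and computes the interaction-score distribution diagnostic
that makes the quality gradient visible: low-probability candidates have
no direct interactions with the side effect's carriers at all, while
high-probability ones increasingly do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PositivePairTable, SideEffectIndex
from .network import DrugNetwork, column_normalize
from .rwr import (
    DEFAULT_LAMBDA,
    DEFAULT_THETA,
    DENSE_CUTOFF,
    NodeProbabilities,
    _direct_solve_columns,
    make_restart_vector,
    rwr_iterate,
)

__all__ = [
    "DEFAULT_EPSILON_GRID",
    "NegativeSampleSet",
    "ScoreDistribution",
    "compute_probabilities",
    "select_candidates_for_side_effect",
    "build_nds",
    "partition_by_probability",
    "score_distribution_diagnostic",
    "epsilon_grid_from_probabilities",
]

#: Probability-threshold grid used for real-scale interaction networks.
DEFAULT_EPSILON_GRID: tuple[float, ...] = (
    0.0,
    5e-7,
    5e-6,
    1e-5,
    2e-5,
    3e-5,
    4e-5,
    5e-5,
    6e-5,
)


@dataclass(frozen=True, eq=False)
class NegativeSampleSet:
    """Selected (drug, side effect, probability) triples under one threshold."""

    triples: tuple[tuple[str, str, float], ...]
    threshold: float

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        return iter(self.triples)

    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((d, s) for d, s, _ in self.triples)


def _validate_grid(grid: Sequence[float]) -> tuple[float, ...]:
    grid = tuple(float(g) for g in grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError(f"threshold grid must be strictly increasing, got {grid}")
    if grid[0] < 0:
        raise ValueError("thresholds must be non-negative")
    return grid


def compute_probabilities(
    network: DrugNetwork,
    index: SideEffectIndex,
    lam: float = DEFAULT_LAMBDA,
    theta: float = DEFAULT_THETA,
    solver: str = "auto",
) -> dict[str, NodeProbabilities]:
    """Run one seeded walk per side effect; returns side effect -> probabilities.

    ``solver`` is ``"direct"``, ``"iterative"`` or ``"auto"`` (direct below
    the dense-factorization cutoff, iterative above). The direct path
    factorizes the stationary system once and reuses it for every side
    effect.
    """
    if solver not in ("auto", "direct", "iterative"):
        raise ValueError(f"unknown solver {solver!r}")
    node_set = set(network.nodes)
    side_effects = sorted(index)
    seed_sets: dict[str, frozenset[str]] = {}
    for se in side_effects:
        seeds = frozenset(index[se]) & node_set
        if not seeds:
            raise ValueError(f"side effect {se!r} has no owning drug in the network")
        seed_sets[se] = seeds

    M = column_normalize(network)
    if solver == "auto":
        solver = "direct" if network.n_nodes <= DENSE_CUTOFF else "iterative"

    out: dict[str, NodeProbabilities] = {}
    if solver == "direct" and lam < 1.0:
        p0s = np.column_stack(
            [make_restart_vector(seed_sets[se], network.nodes) for se in side_effects]
        )
        solution = _direct_solve_columns(M, p0s, lam)
        for k, se in enumerate(side_effects):
            out[se] = NodeProbabilities(network.nodes, solution[:, k], 0, True)
        return out
    for se in side_effects:
        p0 = make_restart_vector(seed_sets[se], network.nodes)
        if solver == "direct":  # lam == 1 degenerates to the restart vector
            out[se] = NodeProbabilities(network.nodes, p0, 0, True)
        else:
            out[se] = rwr_iterate(M, p0, lam=lam, theta=theta)
    return out


def select_candidates_for_side_effect(
    side_effect: str,
    probabilities: NodeProbabilities,
    eps: float,
    positives: PositivePairTable,
) -> list[tuple[str, str, float]]:
    """Drugs with walk probability <= eps, minus the known positive pairs.

    The threshold is inclusive: a probability exactly equal to eps selects
    the drug, so eps = 0 selects precisely the drugs unreachable from the
    seeds. Output is sorted by (probability, drug id) for determinism.
    """
    if eps < 0:
        raise ValueError("eps must be non-negative")
    selected = [
        (drug, side_effect, float(p))
        for drug, p in zip(probabilities.nodes, probabilities.probabilities)
        if p <= eps and (drug, side_effect) not in positives
    ]
    selected.sort(key=lambda t: (t[2], t[0]))
    return selected


def build_nds(
    network: DrugNetwork,
    index: SideEffectIndex,
    eps: float,
    lam: float = DEFAULT_LAMBDA,
    theta: float = DEFAULT_THETA,
    probabilities: Mapping[str, NodeProbabilities] | None = None,
) -> NegativeSampleSet:
    """Assemble the negative dataset: union of per-side-effect candidates.

    Precomputed per-side-effect probabilities (from
    :func:`compute_probabilities`) may be passed to amortize the walks
    across a threshold grid.
    """
    if probabilities is None:
        probabilities = compute_probabilities(network, index, lam=lam, theta=theta)
    positives = index.to_pairs()
    triples: list[tuple[str, str, float]] = []
    for se in sorted(index):
        triples.extend(select_candidates_for_side_effect(se, probabilities[se], eps, positives))
    triples.sort(key=lambda t: (t[1], t[2], t[0]))
    return NegativeSampleSet(tuple(triples), float(eps))


def partition_by_probability(
    triples: Sequence[tuple[str, str, float]], grid: Sequence[float]
) -> list[int]:
    """Assign each triple a quality-part index 1..k along the threshold grid.

    Part 1 is the closed cell [0, g1]; part 2 the open cell (g1, g2); parts
    i >= 3 the half-open cells [g_{i-1}, g_i) — so a probability exactly at
    a grid boundary g_i (i >= 2) falls in part i+1. The final cell is
    closed on the right so that the largest admissible probability (== g_k)
    has a part. Probabilities above the last grid value are an error.
    """
    grid = _validate_grid(grid)
    k = len(grid)
    parts: list[int] = []
    for drug, side_effect, p in triples:
        if p > grid[-1]:
            raise ValueError(
                f"probability {p:.6g} of pair ({drug!r}, {side_effect!r}) exceeds "
                f"the last grid value {grid[-1]:.6g}"
            )
        if p <= grid[0]:
            parts.append(1)
        elif k >= 2 and p < grid[1]:
            parts.append(2)
        else:
            for i in range(2, k):
                if p < grid[i]:
                    parts.append(i + 1)
                    break
            else:
                parts.append(k)
    return parts


@dataclass(frozen=True, eq=False)
class ScoreDistribution:
    """Per-part interaction-score histograms (proportions and raw counts)."""

    proportions: pd.DataFrame  # rows: part index; columns: bin labels
    counts: pd.DataFrame
    empty_parts: tuple[int, ...]  # parts with no scores to bin (flagged, not dropped)
    include_zeros: bool


def score_distribution_diagnostic(
    triples: Sequence[tuple[str, str, float]],
    network: DrugNetwork,
    index: SideEffectIndex,
    n_bins: int = 10,
    grid: Sequence[float] | None = None,
    include_zeros: bool = True,
) -> ScoreDistribution:
    """Distribution of interaction scores between candidates and carriers.

    For each selected triple (d, s, p), the network weight between d and
    every drug owning s is collected (0 when no edge exists). Scores are
    binned into ``n_bins`` equal-width intervals over (0, 999], with zero
    scores counted in a separate leading bin when ``include_zeros`` is
    true and dropped otherwise. When a grid is given, triples are first
    assigned quality parts and one histogram row is produced per part;
    otherwise all triples form a single part.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if grid is None:
        parts = [1] * len(triples)
        part_labels = [1]
    else:
        parts = partition_by_probability(triples, grid)
        part_labels = list(range(1, len(_validate_grid(grid)) + 1))

    edges = np.linspace(0.0, 999.0, n_bins + 1)
    bin_labels = [f"({edges[i]:.1f}, {edges[i + 1]:.1f}]" for i in range(n_bins)]
    columns = (["zero"] if include_zeros else []) + bin_labels

    counts = pd.DataFrame(0, index=part_labels, columns=columns, dtype=int)
    for (drug, side_effect, _), part in zip(triples, parts):
        owners = index[side_effect] - {drug}
        for owner in owners:
            w = network.weight(drug, owner) if owner in network else 0.0
            if w == 0.0:
                if include_zeros:
                    counts.loc[part, "zero"] += 1
                continue
            # right-closed bins over (0, 999]
            b = min(int(np.searchsorted(edges, w, side="left")), n_bins) - 1
            counts.loc[part, bin_labels[max(b, 0)]] += 1

    totals = counts.sum(axis=1)
    empty = tuple(int(p) for p in counts.index[totals == 0])
    proportions = counts.div(totals.replace(0, np.nan), axis=0)
    return ScoreDistribution(proportions, counts, empty, include_zeros)


def epsilon_grid_from_probabilities(
    probabilities: Mapping[str, NodeProbabilities],
    positives: PositivePairTable,
    quantiles: Sequence[float] = (0.1, 0.3, 0.5, 0.75, 1.0),
) -> tuple[float, ...]:
    """Data-driven threshold grid: quantiles of non-positive pair probabilities.

    Walk probabilities scale with network size and seed-set size, so a
    fixed grid only suits one data regime; quantiles of the pooled
    candidate probabilities give a grid that spans the observed range on
    any world. A final quantile of 1.0 makes the top threshold admit every
    non-positive pair.
    """
    pooled: list[float] = []
    for se, node_probs in probabilities.items():
        for drug, p in zip(node_probs.nodes, node_probs.probabilities):
            if (drug, se) not in positives:
                pooled.append(float(p))
    if not pooled:
        raise ValueError("no non-positive pairs to build a grid from")
    values = np.quantile(np.asarray(pooled), np.asarray(quantiles, dtype=float))
    grid: list[float] = []
    for v in values:
        v = float(v)
        if not grid or v > grid[-1]:
            grid.append(v)
    return _validate_grid(grid)
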