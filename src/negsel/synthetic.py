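"""Synthetic drug/side-effect worlds with planted ground truth.

The generator builds a community-structured world in which the premise of
network-based negative selection — interacting drugs tend to share
properties — holds by construction and can therefore be audited:

* drugs are split into communities; edges are sampled within a community
  with probability ``p_in`` and across communities with ``p_out``
  (``p_out < p_in``), with integer weights uniform on the interaction
  score scale;
* each side effect is carried by one or two communities, and each drug in
  a carrying community owns it with probability ``carriage_prob``;
* every similarity channel gives same-community pairs a high baseline
  (``similarity_signal`` plus noise) and cross-community pairs only noise
  (uniform on [0, ``similarity_noise``]).

Non-positive pairs get a ground-truth label: a pair whose drug sits in a
carrying community but was not emitted as a positive is a *latent
positive* — exactly the kind of unvalidated association that random
negative sampling would mislabel — and every other pair is a *true
negative*. With ``p_out = 0`` communities are mutually unreachable, so
the zero-probability candidates of the walk-based selection are purely
true negatives: the selection's central claim becomes a graph-theoretic
fact the tests can assert exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import CHANNELS, SimilarityMatrix
from .io import (
    InteractionRecord,
    PositivePairTable,
    SideEffectIndex,
    build_index,
    write_interaction_table,
    write_pair_table,
    write_similarity_matrix,
)
from .selection import NegativeSampleSet, partition_by_probability

__all__ = ["WorldConfig", "SyntheticWorld", "PurityReport", "generate_world", "world_truth_report", "write_world"]

TRUE_NEGATIVE, LATENT_POSITIVE = "true-negative", "latent-positive"


@dataclass(frozen=True)
class WorldConfig:
    """Desk-scale study conditions for one synthetic world.

    Defaults give a 300-drug, 40-side-effect world in six communities —
    every experiment on it runs in minutes on one CPU while preserving
    the qualitative structure of a real interaction network: dense
    clusters, sparse cross-talk, and side effects concentrated in
    clusters.
    """

    n_drugs: int = 300
    n_side_effects: int = 40
    n_communities: int = 6
    p_in: float = 0.25
    p_out: float = 0.01
    weight_low: int = 1
    weight_high: int = 999
    carriage_prob: float = 0.5
    similarity_signal: float = 0.6
    similarity_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if not 1 <= self.weight_low <= self.weight_high <= 999:
            raise ValueError("need 1 <= weight_low <= weight_high <= 999")
        for name in ("carriage_prob", "similarity_signal", "similarity_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_drugs, self.n_side_effects, self.n_communities) < 1:
            raise ValueError("counts must be positive")
        if self.n_communities > self.n_drugs:
            raise ValueError("more communities than drugs")


@dataclass(frozen=True, eq=False)
class SyntheticWorld:
    """One generated world plus its planted ground truth."""

    config: WorldConfig
    records: tuple[InteractionRecord, ...]
    positives: PositivePairTable
    channels: dict[str, SimilarityMatrix]
    truth: dict[tuple[str, str], str]  # non-positive pair -> true-negative | latent-positive
    communities: dict[str, int]
    carrying: dict[str, frozenset[int]]
    index: SideEffectIndex = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "index", build_index(self.positives))

    @property
    def drug_universe(self) -> frozenset[str]:
        return frozenset(self.communities)

    @property
    def side_effects(self) -> tuple[str, ...]:
        return tuple(sorted(self.carrying))


def _drug_names(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"D{i:0{width}d}" for i in range(n)]


def _side_effect_names(n: int) -> list[str]:
    width = max(2, len(str(n - 1)))
    return [f"SE{i:0{width}d}" for i in range(n)]


def generate_world(config: WorldConfig, max_retries: int = 100) -> SyntheticWorld:
    """Sample one world; fully reproducible from ``config.seed``.

    Side effects that end up with fewer than two owners are resampled up
    to ``max_retries`` times (two owners keep the per-pair similarity
    features well-posed for positives).
    """
    rng = np.random.default_rng(config.seed)
    drugs = _drug_names(config.n_drugs)
    side_effects = _side_effect_names(config.n_side_effects)
    community = np.repeat(
        np.arange(config.n_communities),
        -(-config.n_drugs // config.n_communities),  # ceil division
    )[: config.n_drugs]
    communities = {d: int(c) for d, c in zip(drugs, community)}

    # --- interaction edges -------------------------------------------------
    iu, ju = np.triu_indices(config.n_drugs, k=1)
    same = community[iu] == community[ju]
    p_edge = np.where(same, config.p_in, config.p_out)
    keep = rng.random(len(iu)) < p_edge
    weights = rng.integers(config.weight_low, config.weight_high + 1, size=len(iu))
    records = tuple(
        InteractionRecord(drugs[i], drugs[j], int(w))
        for i, j, w in zip(iu[keep], ju[keep], weights[keep])
    )

    # --- side-effect carriage and positive pairs ---------------------------
    carrying: dict[str, frozenset[int]] = {}
    pairs: set[tuple[str, str]] = set()
    members_of = {
        c: [d for d in drugs if communities[d] == c] for c in range(config.n_communities)
    }
    for se in side_effects:
        for attempt in range(max_retries + 1):
            n_carry = int(rng.integers(1, min(2, config.n_communities) + 1))
            carriers = rng.choice(config.n_communities, size=n_carry, replace=False)
            candidates = [d for c in sorted(carriers) for d in members_of[int(c)]]
            owned = [d for d in candidates if rng.random() < config.carriage_prob]
            if len(owned) >= 2:
                carrying[se] = frozenset(int(c) for c in carriers)
                pairs.update((d, se) for d in owned)
                break
        else:
            raise RuntimeError(
                f"side effect {se} kept fewer than 2 owners after {max_retries} resamples; "
                "raise carriage_prob or community size"
            )
    positives = PositivePairTable.from_iterable(pairs)

    # --- similarity channels ------------------------------------------------
    same_comm = community[:, None] == community[None, :]
    channels: dict[str, SimilarityMatrix] = {}
    for label in CHANNELS:
        noise = rng.uniform(0.0, config.similarity_noise, size=(config.n_drugs, config.n_drugs))
        noise = np.triu(noise, k=1)
        noise = noise + noise.T
        values = noise + np.where(same_comm, config.similarity_signal, 0.0)
        np.fill_diagonal(values, 1.0)
        channels[label] = SimilarityMatrix(label, tuple(drugs), np.clip(values, 0.0, 1.0))

    # --- ground truth for non-positive pairs --------------------------------
    truth: dict[tuple[str, str], str] = {}
    for se in side_effects:
        for d in drugs:
            if (d, se) in positives:
                continue
            truth[(d, se)] = (
                LATENT_POSITIVE if communities[d] in carrying[se] else TRUE_NEGATIVE
            )

    return SyntheticWorld(
        config=config,
        records=records,
        positives=positives,
        channels=channels,
        truth=truth,
        communities=communities,
        carrying=carrying,
    )


@dataclass(frozen=True, eq=False)
class PurityReport:
    """How much of a selected negative set is genuinely negative."""

    n_selected: int
    n_true_negative: int
    purity: float  # fraction of selected pairs that are planted true negatives
    base_rate: float  # true-negative fraction among all non-positive pairs
    per_part: dict[int, float] | None = None


def world_truth_report(
    world: SyntheticWorld,
    nds: NegativeSampleSet,
    grid: tuple[float, ...] | None = None,
) -> PurityReport:
    """Purity of a selected negative set against the planted truth.

    With a grid, purity is also broken down by probability part. An empty
    selection reports purity 0 over 0 pairs rather than erroring.
    """
    labels = [world.truth[(d, s)] for d, s, _ in nds]
    n_true = sum(1 for lab in labels if lab == TRUE_NEGATIVE)
    base_n = sum(1 for lab in world.truth.values() if lab == TRUE_NEGATIVE)
    base_rate = base_n / len(world.truth) if world.truth else 0.0
    per_part = None
    if grid is not None and len(nds):
        parts = partition_by_probability(list(nds), grid)
        totals: dict[int, int] = {}
        trues: dict[int, int] = {}
        for part, lab in zip(parts, labels):
            totals[part] = totals.get(part, 0) + 1
            if lab == TRUE_NEGATIVE:
                trues[part] = trues.get(part, 0) + 1
        per_part = {p: trues.get(p, 0) / n for p, n in sorted(totals.items())}
    purity = n_true / len(labels) if labels else 0.0
    return PurityReport(len(labels), n_true, purity, base_rate, per_part)


def write_world(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Write a world in the same dialects the real-data readers consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": directory / "interactions.tsv",
        "pairs": directory / "pairs.tsv",
        "truth": directory / "truth.tsv",
        "communities": directory / "communities.tsv",
    }
    write_interaction_table(world.records, paths["interactions"])
    write_pair_table(world.positives, paths["pairs"])
    truth_frame = pd.DataFrame(
        [(d, s, lab) for (d, s), lab in sorted(world.truth.items())],
        columns=["drug", "side_effect", "truth"],
    )
    truth_frame.to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame(
        sorted(world.communities.items()), columns=["drug", "community"]
    ).to_csv(paths["communities"], sep="\t", index=False)
    for label, matrix in world.channels.items():
        path = directory / f"similarity_{label}.tsv"
        write_similarity_matrix(matrix, path)
        paths[f"similarity_{label}"] = path
    return paths
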