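"""End-to-end pipeline: simulate/read -> network -> walks -> selection ->
features -> evaluation -> comparison, with one machine-readable report.

Every stage writes its intermediate artifact into the working directory
and contributes to the report, so each reported number can be recomputed
from the written intermediates. A single global seed fans out to
per-stage seeds by fixed offsets, which keeps runs reproducible without
reusing one stream across stages.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from . import evaluation, features, fire, io, selection, synthetic
from .network import build_network
from .rwr import DEFAULT_LAMBDA, DEFAULT_THETA

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

# fixed fan-out offsets from the global seed
_SEED_WORLD, _SEED_CV, _SEED_BALANCE, _SEED_BASELINE = 1, 2, 3, 4


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration of one pipeline run (defaults match the method's
    stated constants: restart probability 0.8, stop tolerance 1e-6,
    tenfold cross-validation)."""

    workdir: Path = Path("negsel-run")
    simulate: bool = True
    interactions: Path | None = None
    pairs: Path | None = None
    channel_paths: dict[str, Path] = field(default_factory=dict)
    lam: float = DEFAULT_LAMBDA
    theta: float = DEFAULT_THETA
    grid: tuple[float, ...] | None = None  # None: Table-style default or quantile grid
    eps_select: float | None = None  # threshold for the evaluated negative set
    model: str = "rf"
    folds: int = 10
    balance: str = "all"
    n_repeats: int = 5
    seed: int = 0
    compare_random: bool = True
    compare_fire: bool = True
    world: synthetic.WorldConfig | None = None
    min_score: int = 1


@contextmanager
def _stage(name: str, workdir: Path) -> Iterator[None]:
    try:
        yield
    except Exception as exc:
        (workdir / "STALE").write_text(
            f"pipeline failed in stage {name!r}: {exc}\n"
            "outputs written so far may be stale\n"
        )
        raise PipelineError(f"stage {name!r}: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the run report (also written
    to ``workdir/report.json``)."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    stale = workdir / "STALE"
    if stale.exists():
        stale.unlink()
    report: dict = {"seed": config.seed, "lam": config.lam, "theta": config.theta}

    world = None
    with _stage("simulate", workdir):
        if config.simulate:
            world_config = config.world or synthetic.WorldConfig()
            world_config = synthetic.WorldConfig(
                **{**world_config.__dict__, "seed": config.seed + _SEED_WORLD}
            )
            world = synthetic.generate_world(world_config)
            synthetic.write_world(world, workdir / "world")
            report["world"] = {
                "n_drugs": world_config.n_drugs,
                "n_side_effects": world_config.n_side_effects,
                "n_positive_pairs": len(world.positives),
            }
            interactions_path = workdir / "world" / "interactions.tsv"
            pairs_path = workdir / "world" / "pairs.tsv"
        else:
            if config.interactions is None or config.pairs is None:
                raise FileNotFoundError(
                    "interactions and pairs paths are required when simulate is off"
                )
            interactions_path = Path(config.interactions)
            pairs_path = Path(config.pairs)
            for path in (interactions_path, pairs_path):
                if not path.exists():
                    raise FileNotFoundError(f"input file {path} does not exist")

    with _stage("read-inputs", workdir):
        records = io.read_interaction_table(interactions_path, min_score=config.min_score)
        positives = io.read_pair_table(pairs_path)
        index = io.build_index(positives)
        universe = (
            world.drug_universe if world is not None else positives.drugs
        ) | {r.drug_a for r in records} | {r.drug_b for r in records}

    with _stage("build-network", workdir):
        network = build_network(records, universe)
        io.write_triples(
            ((a, b, w) for a, b, w in network.edges()),
            workdir / "edges.tsv",
            value_column="weight",
        )
        report["network"] = {
            "n_nodes": network.n_nodes,
            "n_edges": network.n_edges,
            "dropped_records": network.dropped_records,
        }

    with _stage("rwr", workdir):
        probabilities = selection.compute_probabilities(
            network, index, lam=config.lam, theta=config.theta
        )

    with _stage("select", workdir):
        if config.grid is not None:
            grid = tuple(config.grid)
        elif config.simulate:
            grid = selection.epsilon_grid_from_probabilities(probabilities, positives)
        else:
            grid = selection.DEFAULT_EPSILON_GRID
        report["grid"] = list(grid)
        nds_by_eps = {
            eps: selection.build_nds(network, index, eps, probabilities=probabilities)
            for eps in grid
        }
        report["nds_counts"] = {f"{eps:.6g}": len(nds) for eps, nds in nds_by_eps.items()}
        nds_max = nds_by_eps[grid[-1]]
        io.write_triples(list(nds_max), workdir / "nds_max.tsv")
        parts = selection.partition_by_probability(list(nds_max), grid)
        part_counts: dict[int, int] = {}
        for part in parts:
            part_counts[part] = part_counts.get(part, 0) + 1
        report["part_counts"] = {str(p): n for p, n in sorted(part_counts.items())}

    with _stage("fire", workdir):
        if config.compare_fire:
            fire_set = fire.fire_select(network, index, positives)
            io.write_triples(
                sorted((d, s, 0.0) for d, s in fire_set),
                workdir / "fire.tsv",
                value_column="score",
            )
            rwr_parts = {(d, s): part for (d, s, _), part in zip(nds_max, parts)}
            fire_report = fire.fire_partition_report(fire_set, rwr_parts)
            report["fire"] = {
                "n_selected": fire_report.n_fire,
                "coverage_per_part": {str(p): v for p, v in fire_report.coverage.items()},
                "distribution_per_part": {
                    str(p): v for p, v in fire_report.distribution.items()
                },
            }

    with _stage("featurize", workdir):
        if world is not None:
            channels = world.channels
        else:
            if set(config.channel_paths) != set(features.CHANNELS):
                raise FileNotFoundError(
                    f"need one similarity matrix per channel {features.CHANNELS}, "
                    f"got {sorted(config.channel_paths)}"
                )
            channels = {
                label: io.read_similarity_matrix(path, sorted(universe), label=label)
                for label, path in config.channel_paths.items()
            }
        if config.eps_select is not None:
            eps_select = config.eps_select
        else:
            # default: the smallest grid threshold that yields any negatives
            eps_select = next((eps for eps in grid if len(nds_by_eps[eps])), None)
            if eps_select is None:
                raise ValueError(
                    "no negative samples selected at any grid threshold; "
                    "pass a larger eps_select or a wider grid"
                )
        nds_selected = selection.build_nds(
            network, index, eps_select, probabilities=probabilities
        )
        report["eps_select"] = eps_select
        labeled = [(d, s, "positive") for d, s in sorted(positives)] + [
            (d, s, "negative") for d, s, _ in nds_selected
        ]
        vectors = features.featurize(labeled, channels, index)
        frame = features.feature_table(vectors)
        frame.to_csv(workdir / "features.tsv", sep="\t", index=False)
        if world is not None:
            purity = synthetic.world_truth_report(world, nds_selected)
            report["purity"] = {
                "n_selected": purity.n_selected,
                "purity": purity.purity,
                "base_rate": purity.base_rate,
            }

    with _stage("evaluate", workdir):
        spec = evaluation.ClassifierSpec(family=config.model, seed=config.seed + _SEED_CV)
        pos_frame = frame[frame["label"] == "positive"]
        neg_frame = frame[frame["label"] == "negative"]
        results = evaluation.balance_experiment(
            pos_frame,
            neg_frame,
            mode=config.balance,
            spec=spec,
            n_repeats=config.n_repeats,
            k=config.folds,
            seed=config.seed + _SEED_BALANCE,
        )
        report["evaluation"] = {
            "model": config.model,
            "folds": config.folds,
            "balance": config.balance,
            "repeats": [
                {**r.metrics.as_dict(), "AUROC": r.roc.area, "AUPR": r.pr.area}
                for r in results
            ],
        }

    with _stage("compare-random", workdir):
        if config.compare_random:
            rng = np.random.default_rng(config.seed + _SEED_BASELINE)
            non_positive = sorted(
                (d, s)
                for s in index
                for d in network.nodes
                if (d, s) not in positives
            )
            chosen = rng.choice(len(non_positive), size=min(len(positives), len(non_positive)), replace=False)
            random_neg = [
                (non_positive[i][0], non_positive[i][1], "negative") for i in np.sort(chosen)
            ]
            random_vectors = features.featurize(random_neg, channels, index)
            random_frame = features.feature_table(random_vectors)
            baseline = evaluation.balance_experiment(
                pos_frame,
                random_frame,
                mode="all",
                spec=spec,
                k=config.folds,
                seed=config.seed + _SEED_BALANCE,
            )[0]
            report["random_negative_baseline"] = {
                **baseline.metrics.as_dict(),
                "AUROC": baseline.roc.area,
                "AUPR": baseline.pr.area,
            }

    report_path = workdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("pipeline finished; report at %s", report_path)
    return report
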