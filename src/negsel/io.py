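"""Readers and writers for the tabular formats the pipeline consumes and emits.

Three input dialects are supported, all tab-separated with a header row:

* an interaction table in the STITCH ``chemical_chemical.links`` dialect
  (columns ``chemical1``, ``chemical2``, ``combined_score``; scores are
  integers between 1 and 999),
* a drug/side-effect positive-pair table (columns ``drug``, ``side_effect``),
* square drug-by-drug similarity matrices (first row and first column carry
  the drug identifiers).

Identifiers are opaque strings throughout: no compound-ID parsing is
attempted, so synthetic and real inputs go through identical code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "FormatError",
    "ParseError",
    "ConsistencyError",
    "EmptyInputError",
    "InteractionRecord",
    "PositivePairTable",
    "SideEffectIndex",
    "read_interaction_table",
    "write_interaction_table",
    "read_pair_table",
    "write_pair_table",
    "build_index",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "write_triples",
]


class FormatError(ValueError):
    """A file does not have the expected column layout."""


class ParseError(ValueError):
    """A cell could not be interpreted; the message names the offending line."""


class ConsistencyError(ValueError):
    """A file parses but violates a semantic constraint (e.g. asymmetry)."""


class EmptyInputError(ValueError):
    """A file contains a header but no data rows."""


@dataclass(frozen=True, order=True)
class InteractionRecord:
    """One scored chemical-chemical interaction.

    ``score`` is an integrated evidence score on the 1-999 scale used by
    STITCH's ``combined_score``. Endpoints are stored in canonical (sorted)
    order so that unordered duplicates compare equal.
    """

    drug_a: str
    drug_b: str
    score: int

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise ValueError(f"self-interaction not allowed: {self.drug_a!r}")
        if not 1 <= self.score <= 999:
            raise ValueError(f"score {self.score} outside the 1-999 scale")

    @classmethod
    def canonical(cls, drug_a: str, drug_b: str, score: int) -> "InteractionRecord":
        """Build a record with endpoints in sorted order."""
        a, b = sorted((drug_a, drug_b))
        return cls(a, b, score)


@dataclass(frozen=True)
class PositivePairTable:
    """A de-duplicated set of known (drug, side effect) associations."""

    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_iterable(cls, pairs: Iterable[tuple[str, str]]) -> "PositivePairTable":
        pairset = frozenset((str(d), str(s)) for d, s in pairs)
        for d, s in pairset:
            if not d or not s:
                raise ValueError("empty drug or side-effect identifier in pair table")
        return cls(pairset)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.pairs)

    @property
    def side_effects(self) -> frozenset[str]:
        return frozenset(s for _, s in self.pairs)


@dataclass(frozen=True)
class SideEffectIndex:
    """Inverse view of a pair table: side effect -> set of drugs owning it.

    The per-side-effect drug sets are the seed sets of the random walk and
    the owner sets over which per-pair similarity features take their max.
    """

    owners: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for se, drugs in self.owners.items():
            if not drugs:
                raise ValueError(f"side effect {se!r} has an empty drug set")

    def __getitem__(self, side_effect: str) -> frozenset[str]:
        return self.owners[side_effect]

    def __iter__(self) -> Iterator[str]:
        return iter(self.owners)

    def __len__(self) -> int:
        return len(self.owners)

    def __contains__(self, side_effect: str) -> bool:
        return side_effect in self.owners

    @property
    def side_effects(self) -> frozenset[str]:
        return frozenset(self.owners)

    @property
    def drugs(self) -> frozenset[str]:
        out: set[str] = set()
        for drugs in self.owners.values():
            out |= drugs
        return frozenset(out)

    def to_pairs(self) -> PositivePairTable:
        """Re-expand the index into the pair table it was built from."""
        return PositivePairTable.from_iterable(
            (d, s) for s, drugs in self.owners.items() for d in drugs
        )


def _require_columns(frame: pd.DataFrame, required: tuple[str, ...], path: Path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(frame.columns)}"
        )


def read_interaction_table(path: str | Path, min_score: int = 1) -> list[InteractionRecord]:
    """Read a STITCH-dialect interaction table.

    Rows with ``combined_score`` below ``min_score`` are dropped, self-pairs
    are dropped, and duplicate unordered pairs are collapsed keeping the
    maximum score. Extra columns are ignored.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(frame, ("chemical1", "chemical2", "combined_score"), path)

    best: dict[tuple[str, str], int] = {}
    for row_pos, (c1, c2, raw) in enumerate(
        zip(frame["chemical1"], frame["chemical2"], frame["combined_score"])
    ):
        line = row_pos + 2  # 1-based, after the header
        try:
            score = int(str(raw).strip())
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: line {line}: combined_score {raw!r} is not an integer"
            ) from None
        if not 1 <= score <= 999:
            raise ParseError(
                f"{path}: line {line}: combined_score {score} outside the 1-999 scale"
            )
        a, b = str(c1).strip(), str(c2).strip()
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if score > best.get(key, 0):
            best[key] = score

    return sorted(
        InteractionRecord(a, b, score)
        for (a, b), score in best.items()
        if score >= min_score
    )


def write_interaction_table(records: Iterable[InteractionRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.drug_a, r.drug_b, r.score) for r in sorted(records)],
        columns=["chemical1", "chemical2", "combined_score"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> PositivePairTable:
    """Read a two-column drug/side-effect pair table (de-duplicated)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(frame, ("drug", "side_effect"), path)
    if len(frame) == 0:
        raise EmptyInputError(f"{path}: no data rows after the header")
    for row_pos, (d, s) in enumerate(zip(frame["drug"], frame["side_effect"])):
        if pd.isna(d) or pd.isna(s) or not str(d).strip() or not str(s).strip():
            raise ParseError(f"{path}: line {row_pos + 2}: empty drug or side-effect id")
    return PositivePairTable.from_iterable(
        (str(d).strip(), str(s).strip())
        for d, s in zip(frame["drug"], frame["side_effect"])
    )


def write_pair_table(pairs: PositivePairTable, path: str | Path) -> None:
    frame = pd.DataFrame(sorted(pairs.pairs), columns=["drug", "side_effect"])
    frame.to_csv(path, sep="\t", index=False)


def build_index(pairs: PositivePairTable) -> SideEffectIndex:
    """Invert a pair table into a side-effect -> owning-drugs index."""
    if len(pairs) == 0:
        raise EmptyInputError("cannot index an empty pair table")
    owners: dict[str, set[str]] = {}
    for drug, side_effect in pairs:
        owners.setdefault(side_effect, set()).add(drug)
    return SideEffectIndex({s: frozenset(d) for s, d in owners.items()})


def read_similarity_matrix(
    path: str | Path,
    drug_universe: Iterable[str],
    label: str = "structure",
    tol: float = 1e-9,
):
    """Read a square drug-by-drug similarity matrix.

    The file's row and column identifier sets must coincide and the matrix
    must be symmetric within ``tol``. The result is restricted to
    ``drug_universe``; drugs absent from the file get all-zero rows and
    columns ("no evidence of association").
    """
    from .features import SimilarityMatrix  # deferred: features imports this module

    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    if set(frame.index) != set(frame.columns) or frame.shape[0] != frame.shape[1]:
        raise FormatError(f"{path}: row and column identifier sets differ (not square)")
    frame = frame.loc[frame.index, frame.index]  # align column order to row order
    values = frame.to_numpy(dtype=float)
    asym = abs(values - values.T).max() if values.size else 0.0
    if asym > tol:
        raise ConsistencyError(f"{path}: matrix asymmetric (max |W - W^T| = {asym:.3g})")

    universe = sorted(str(d) for d in drug_universe)
    full = frame.reindex(index=universe, columns=universe, fill_value=0.0).fillna(0.0)
    return SimilarityMatrix(label=label, nodes=tuple(universe), values=full.to_numpy(dtype=float))


def write_similarity_matrix(matrix, path: str | Path) -> None:
    frame = pd.DataFrame(matrix.values, index=matrix.nodes, columns=matrix.nodes)
    frame.to_csv(path, sep="\t")


def write_triples(
    triples: Iterable[tuple[str, str, float]],
    path: str | Path,
    value_column: str = "probability",
) -> None:
    """Write (drug, side_effect, value) triples, e.g. a selected negative set."""
    frame = pd.DataFrame(list(triples), columns=["drug", "side_effect", value_column])
    frame.to_csv(path, sep="\t", index=False)


def read_triples(path: str | Path, value_column: str = "probability") -> list[tuple[str, str, float]]:
    frame = pd.read_csv(path, sep="\t", dtype={"drug": str, "side_effect": str})
    _require_columns(frame, ("drug", "side_effect", value_column), Path(path))
    return [
        (str(d), str(s), float(v))
        for d, s, v in zip(frame["drug"], frame["side_effect"], frame[value_column])
    ]
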