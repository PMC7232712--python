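"""Five-channel drug-association similarities and per-pair feature vectors.

Each (drug, side effect) sample is encoded by five scalars, one per
association channel: for channel W the feature is

    Q(d, s) = max{ W(d, d') : d' owns s, d' != d }

i.e. the strongest association between the sample's drug and any *other*
drug known to carry the side effect. A drug highly similar to carriers of
a side effect is itself likely to carry it, so positives concentrate at
high Q and well-chosen negatives at low Q.

Two channels are computed natively here — Tanimoto similarity over hashed
substructure fingerprint bits and direction-cosine similarity over binary
target-protein profiles. The structure (maximum-common-subgraph), ATC-code
and literature co-occurrence channels come from external tools and are
consumed as precomputed square matrices (see :func:`negsel.io.read_similarity_matrix`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SideEffectIndex

__all__ = [
    "CHANNELS",
    "SimilarityMatrix",
    "FeatureVector",
    "tanimoto",
    "target_cosine",
    "fingerprint_matrix",
    "target_profile_matrix",
    "fingerprints_from_smiles",
    "pair_feature",
    "featurize",
    "feature_table",
    "read_fingerprint_table",
    "read_target_profile_table",
]

logger = logging.getLogger(__name__)

#: Fixed channel order of the feature vector.
CHANNELS: tuple[str, ...] = ("fingerprint", "structure", "atc", "literature", "target")


@dataclass(frozen=True, eq=False)
class SimilarityMatrix:
    """One symmetric drug-by-drug association channel over a fixed universe."""

    label: str
    nodes: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError(
                f"channel {self.label!r}: matrix shape {v.shape} does not match "
                f"{len(self.nodes)} drugs"
            )
        if v.size and abs(v - v.T).max() > 1e-9:
            raise ValueError(f"channel {self.label!r}: matrix is not symmetric")
        if v.size and v.min() < 0:
            raise ValueError(f"channel {self.label!r}: negative similarity values")
        object.__setattr__(self, "values", v)

    def position(self, drug: str) -> int:
        try:
            return self.nodes.index(drug)
        except ValueError:
            raise KeyError(f"drug {drug!r} not in channel {self.label!r}") from None

    def value(self, drug_a: str, drug_b: str) -> float:
        return float(self.values[self.position(drug_a), self.position(drug_b)])

    @property
    def is_all_zero(self) -> bool:
        return bool(self.values.size == 0 or self.values.max() == 0.0)


@dataclass(frozen=True)
class FeatureVector:
    """The 5-channel representation of one labeled (drug, side effect) sample."""

    drug: str
    side_effect: str
    values: tuple[float, float, float, float, float]
    label: str  # "positive" or "negative"


def tanimoto(fp1: Iterable[int], fp2: Iterable[int]) -> float:
    """Tanimoto coefficient of two fingerprint bit sets (0 when both empty)."""
    a, b = set(fp1), set(fp2)
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def target_cosine(v1: Sequence[float], v2: Sequence[float]) -> float:
    """Direction cosine of two binary target profiles (0 if either is all-zero)."""
    x = np.asarray(v1, dtype=float)
    y = np.asarray(v2, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"profile length mismatch: {x.shape} vs {y.shape}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


def fingerprint_matrix(
    fingerprints: Mapping[str, Iterable[int]], drug_universe: Iterable[str]
) -> SimilarityMatrix:
    """All-pairs Tanimoto channel from per-drug fingerprint bit sets.

    Drugs without a fingerprint get zero similarity to everything; empty
    fingerprints are allowed but logged.
    """
    nodes = tuple(sorted(str(d) for d in drug_universe))
    sets = {d: frozenset(int(b) for b in bits) for d, bits in fingerprints.items()}
    for d, bits in sets.items():
        if any(b < 0 for b in bits):
            raise ValueError(f"drug {d!r}: negative fingerprint bit index")
        if not bits:
            logger.warning("drug %r has an empty fingerprint", d)
    values = np.zeros((len(nodes), len(nodes)))
    for i, di in enumerate(nodes):
        if di not in sets:
            continue
        values[i, i] = 1.0 if sets[di] else 0.0
        for j in range(i + 1, len(nodes)):
            dj = nodes[j]
            if dj in sets:
                values[i, j] = values[j, i] = tanimoto(sets[di], sets[dj])
    return SimilarityMatrix("fingerprint", nodes, values)


def target_profile_matrix(
    profiles: Mapping[str, Sequence[float]], drug_universe: Iterable[str]
) -> SimilarityMatrix:
    """All-pairs direction-cosine channel from binary target profiles."""
    nodes = tuple(sorted(str(d) for d in drug_universe))
    arrays = {d: np.asarray(v, dtype=float) for d, v in profiles.items()}
    lengths = {a.shape for a in arrays.values()}
    if len(lengths) > 1:
        raise ValueError(f"target profiles have inconsistent lengths: {lengths}")
    for d, a in arrays.items():
        if not np.isin(a, (0.0, 1.0)).all():
            raise ValueError(f"drug {d!r}: target profile is not 0/1")
        if a.sum() == 0:
            logger.warning("drug %r has an all-zero target profile", d)
    width = len(next(iter(arrays.values()))) if arrays else 0
    stacked = np.zeros((len(nodes), width))
    present = np.zeros(len(nodes), dtype=bool)
    for i, d in enumerate(nodes):
        if d in arrays:
            stacked[i] = arrays[d]
            present[i] = True
    norms = np.linalg.norm(stacked, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    values = (stacked / safe[:, None]) @ (stacked / safe[:, None]).T
    values[~present, :] = 0.0
    values[:, ~present] = 0.0
    values[norms == 0, :] = 0.0
    values[:, norms == 0] = 0.0
    np.fill_diagonal(values, np.where((norms > 0) & present, 1.0, 0.0))
    return SimilarityMatrix("target", nodes, np.clip(values, 0.0, None))


def fingerprints_from_smiles(
    smiles: Mapping[str, str], radius: int = 2, n_bits: int = 2048
) -> dict[str, frozenset[int]]:
    """Hashed circular (ECFP-style) fingerprints from SMILES strings.

    Requires the optional cheminformatics toolkit (``negsel[chem]``);
    radius 2 corresponds to ECFP_4. Unparseable SMILES raise.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "fingerprints_from_smiles requires rdkit; install the 'chem' extra "
            "or supply precomputed fingerprint bit sets instead"
        ) from exc
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out: dict[str, frozenset[int]] = {}
    for drug, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"drug {drug!r}: could not parse SMILES {smi!r}")
        out[drug] = frozenset(gen.GetFingerprint(mol).GetOnBits())
    return out


def pair_feature(
    drug: str, side_effect: str, W: SimilarityMatrix, index: SideEffectIndex
) -> float:
    """Max similarity between ``drug`` and the other owners of ``side_effect``.

    Returns 0 when the side effect has no owner besides the drug itself
    (the owner sets in curated data always have several drugs; the
    convention matters only for degenerate inputs).
    """
    if side_effect not in index:
        raise KeyError(f"unknown side effect {side_effect!r}")
    owners = index[side_effect] - {drug}
    if not owners:
        return 0.0
    i = W.position(drug)
    positions = [W.nodes.index(o) for o in owners if o in W.nodes]
    if not positions:
        return 0.0
    return float(W.values[i, positions].max())


def featurize(
    pairs: Iterable[tuple[str, str, str]],
    channels: Mapping[str, SimilarityMatrix],
    index: SideEffectIndex,
) -> list[FeatureVector]:
    """Encode labeled (drug, side_effect, label) pairs as 5-channel vectors.

    All five channels must be supplied (an all-zero channel is accepted
    and logged). Pairs are grouped by side effect so each owner-restricted
    max is one vectorized slice per channel.
    """
    missing = [c for c in CHANNELS if c not in channels]
    if missing:
        raise ValueError(f"missing similarity channel(s): {missing}")
    for label in CHANNELS:
        if channels[label].is_all_zero:
            logger.warning("similarity channel %r is all-zero", label)

    pair_list = [(str(d), str(s), str(lab)) for d, s, lab in pairs]
    by_se: dict[str, list[int]] = {}
    for k, (_, s, _) in enumerate(pair_list):
        by_se.setdefault(s, []).append(k)

    node_pos = {c: {d: i for i, d in enumerate(channels[c].nodes)} for c in CHANNELS}
    results: list[tuple[float, ...] | None] = [None] * len(pair_list)
    for se, members in by_se.items():
        if se not in index:
            raise KeyError(f"unknown side effect {se!r}")
        owners = sorted(index[se])
        per_channel: dict[str, np.ndarray] = {}
        owner_cols: dict[str, list[int]] = {}
        for c in CHANNELS:
            pos = node_pos[c]
            cols = [pos[o] for o in owners if o in pos]
            owner_cols[c] = cols
            per_channel[c] = (
                channels[c].values[:, cols] if cols else np.zeros((len(pos), 0))
            )
        for k in members:
            drug = pair_list[k][0]
            values = []
            for c in CHANNELS:
                pos = node_pos[c]
                if drug not in pos:
                    raise KeyError(
                        f"pair ({drug!r}, {se!r}) references a drug missing from "
                        f"channel {c!r}"
                    )
                row = per_channel[c][pos[drug]]
                if drug in index[se] and owner_cols[c]:
                    # exclude the drug's own column from its competitor set
                    keep = [
                        j
                        for j, o in enumerate(o for o in owners if o in pos)
                        if o != drug
                    ]
                    row = row[keep]
                values.append(float(row.max()) if row.size else 0.0)
            results[k] = tuple(values)

    return [
        FeatureVector(d, s, results[k], lab)  # type: ignore[arg-type]
        for k, (d, s, lab) in enumerate(pair_list)
    ]


def feature_table(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    """Flatten feature vectors into the on-disk frame layout."""
    rows = [
        {"drug": v.drug, "side_effect": v.side_effect, "label": v.label}
        | {f"q_{c}": val for c, val in zip(CHANNELS, v.values)}
        for v in vectors
    ]
    columns = ["drug", "side_effect"] + [f"q_{c}" for c in CHANNELS] + ["label"]
    return pd.DataFrame(rows, columns=columns)


def read_fingerprint_table(path) -> dict[str, frozenset[int]]:
    """Read a drug -> comma-separated-bit-indices table."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "drug" not in frame.columns or "bits" not in frame.columns:
        raise ValueError(f"{path}: expected columns 'drug' and 'bits'")
    out: dict[str, frozenset[int]] = {}
    for d, bits in zip(frame["drug"], frame["bits"]):
        raw = "" if pd.isna(bits) else str(bits).strip()
        out[str(d)] = frozenset(int(b) for b in raw.split(",") if b != "")
    return out


def read_target_profile_table(path) -> dict[str, np.ndarray]:
    """Read a drug-by-protein 0/1 incidence table (first column: drug ids)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return {str(d): frame.loc[d].to_numpy(dtype=float) for d in frame.index}
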