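"""Random walk with restart on the drug network.

The walker starts from the seed drugs (those owning a given side effect),
moves along the column-stochastic transition operator M, and restarts at
the seeds with probability ``lam`` each step:

    p_{t+1} = (1 - lam) * M @ p_t + lam * p_0

where p_0 is uniform over the seeds. Iteration stops when the L1 change
falls below ``theta``. The stationary point solves the linear system

    (I - (1 - lam) * M) p = lam * p_0

which ``rwr_direct_solve`` computes exactly; for lam > 0 and sub-stochastic
M the system matrix is strictly diagonally dominant in the relevant norm,
hence non-singular. The direct route doubles as an independent oracle for
the iterative one and as the preferred solver on small networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg

from .network import TransitionMatrix

__all__ = [
    "NodeProbabilities",
    "make_restart_vector",
    "rwr_iterate",
    "rwr_direct_solve",
    "DEFAULT_LAMBDA",
    "DEFAULT_THETA",
]

#: Restart probability; the conventional choice for this class of network walks.
DEFAULT_LAMBDA = 0.8
#: L1 convergence tolerance of the iterative solver.
DEFAULT_THETA = 1e-6
#: Node count below which the direct solver uses a dense factorization.
DENSE_CUTOFF = 2000


@dataclass(frozen=True, eq=False)
class NodeProbabilities:
    """Per-drug relevance probabilities produced by one walk."""

    nodes: tuple[str, ...]
    probabilities: np.ndarray
    iterations_used: int
    converged: bool

    def __getitem__(self, drug: str) -> float:
        try:
            return float(self.probabilities[self.nodes.index(drug)])
        except ValueError:
            raise KeyError(f"drug {drug!r} is not a network node") from None

    def as_dict(self) -> dict[str, float]:
        return {d: float(p) for d, p in zip(self.nodes, self.probabilities)}

    @property
    def total_mass(self) -> float:
        return float(self.probabilities.sum())


def make_restart_vector(seeds: Iterable[str], nodes: Sequence[str]) -> np.ndarray:
    """Uniform restart distribution over the seed drugs, in node order."""
    seedset = set(seeds)
    if not seedset:
        raise ValueError("no seeds")
    positions = {d: i for i, d in enumerate(nodes)}
    p0 = np.zeros(len(nodes))
    for drug in seedset:
        if drug not in positions:
            raise ValueError(f"seed drug {drug!r} is not a network node")
        p0[positions[drug]] = 1.0 / len(seedset)
    return p0


def _validate(lam: float, theta: float | None = None) -> None:
    if not 0.0 < lam <= 1.0:
        raise ValueError(f"restart probability lam must be in (0, 1], got {lam}")
    if theta is not None and not theta > 0.0:
        raise ValueError(f"convergence tolerance theta must be positive, got {theta}")


def rwr_iterate(
    M: TransitionMatrix,
    p0: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    theta: float = DEFAULT_THETA,
    max_iter: int = 10_000,
) -> NodeProbabilities:
    """Power-iterate the restart update until the L1 step drops below theta.

    Non-convergence within ``max_iter`` is never silent: the result carries
    ``converged=False`` and a ``RuntimeWarning`` is emitted.
    """
    _validate(lam, theta)
    p0 = np.asarray(p0, dtype=float)
    operator = M.matrix * (1.0 - lam)
    p = p0.copy()
    for iteration in range(1, max_iter + 1):
        p_next = operator @ p + lam * p0
        step = float(np.abs(p_next - p).sum())
        p = p_next
        if step < theta:
            return NodeProbabilities(M.nodes, p, iteration, True)
    warnings.warn(
        f"random walk did not converge within {max_iter} iterations "
        f"(last L1 step {step:.3g} >= theta {theta:.3g})",
        RuntimeWarning,
        stacklevel=2,
    )
    return NodeProbabilities(M.nodes, p, max_iter, False)


def rwr_direct_solve(
    M: TransitionMatrix,
    p0: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    dense_cutoff: int = DENSE_CUTOFF,
) -> NodeProbabilities:
    """Solve the stationary restart equation exactly by a linear solve."""
    _validate(lam)
    p0 = np.asarray(p0, dtype=float)
    if lam == 1.0:
        return NodeProbabilities(M.nodes, p0.copy(), 0, True)
    p = _direct_solve_columns(M, p0[:, None], lam, dense_cutoff)[:, 0]
    return NodeProbabilities(M.nodes, p, 0, True)


def _direct_solve_columns(
    M: TransitionMatrix,
    p0_columns: np.ndarray,
    lam: float,
    dense_cutoff: int = DENSE_CUTOFF,
) -> np.ndarray:
    """Solve the stationary system for several restart vectors at once.

    One factorization serves every column, which makes per-side-effect
    walks over the same network essentially free after the first.
    """
    n = M.n_nodes
    rhs = lam * p0_columns
    if n <= dense_cutoff:
        system = np.eye(n) - (1.0 - lam) * M.matrix.toarray()
        try:
            return scipy.linalg.solve(system, rhs)
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stationary system unexpectedly singular: {exc}") from exc
    system = sp.eye(n, format="csc") - (1.0 - lam) * M.matrix.tocsc()
    solver = scipy.sparse.linalg.factorized(system)
    return np.column_stack([solver(rhs[:, k]) for k in range(rhs.shape[1])])
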