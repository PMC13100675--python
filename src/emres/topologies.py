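"""Reservoir base connectivity matrices.

A reservoir's recurrent weights start from a symmetric, nonnegative,
zero-diagonal base network.  Supported origins:

- ``random``: uniform [0, 1] weights on every undirected edge (the control
  condition for connectome-informed reservoirs);
- ``consensus``: a group-level connectome aggregated from subject-level
  matrices (mean streamline count, with edges zero in a strict majority of
  subjects removed);
- ``surrogate``: a synthetic connectome-like network with block-modular
  structure and heavy-tailed (log-normal) weights — a stand-in for empirical
  structural connectomes, not a claim about any of them;
- ``file``: any user-supplied square symmetric matrix (CSV or NPZ).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BaseNetwork",
    "random_symmetric_network",
    "consensus_connectome",
    "surrogate_connectome",
    "load_weight_matrix",
    "write_weight_matrix",
]

_SYMMETRY_TOL = 1e-8


@dataclass(frozen=True)
class BaseNetwork:
    """Symmetric nonnegative connectivity matrix with zero diagonal."""

    weights: np.ndarray
    origin: str = "random"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if np.max(np.abs(w - w.T)) > _SYMMETRY_TOL:
            raise ValueError("weights must be symmetric")
        if np.any(np.diagonal(w) != 0):
            raise ValueError("diagonal must be zero (no self-connections)")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def random_symmetric_network(n: int, rng: np.random.Generator) -> BaseNetwork:
    """Fully connected symmetric network with uniform [0, 1] weights."""
    if n < 2:
        raise ValueError("n must be >= 2")
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    w[iu] = rng.uniform(0.0, 1.0, size=len(iu[0]))
    w = w + w.T
    return BaseNetwork(weights=w, origin="random")


def consensus_connectome(subject_matrices) -> BaseNetwork:
    """Aggregate subject-level connectomes into a group consensus.

    Weights are averaged entrywise across subjects; any edge that is zero in
    strictly more than half of the subjects is set to zero (an edge zero in
    exactly half survives).  The diagonal is zeroed.
    """
    stack = np.asarray(subject_matrices, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("expected a (K, N, N) stack of square matrices")
    k = stack.shape[0]
    mean = stack.mean(axis=0)
    n_zero = np.sum(stack == 0, axis=0)
    mean[n_zero > k / 2] = 0.0
    np.fill_diagonal(mean, 0.0)
    return BaseNetwork(weights=mean, origin="consensus")


def surrogate_connectome(
    n: int,
    n_modules: int = 5,
    rng: np.random.Generator | None = None,
    *,
    within_scale: float = 1.0,
    between_scale: float = 0.15,
    lognormal_sigma: float = 1.0,
) -> BaseNetwork:
    """Synthetic connectome-like network (block-modular, heavy-tailed).

    Nodes are split into ``n_modules`` contiguous modules; undirected edge
    weights are log-normal, with within-module edges scaled up relative to
    between-module edges so the expected within-module weight exceeds the
    between-module one.  This emulates the modular, skewed-weight character
    of structural brain networks; it is a synthetic fixture, not empirical
    data.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (1 <= n_modules <= n // 2):
        raise ValueError("n_modules must be in [1, n/2]")
    modules = np.arange(n) * n_modules // n  # contiguous, near-equal sizes
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    raw = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=len(iu[0]))
    same = modules[iu[0]] == modules[iu[1]]
    raw *= np.where(same, within_scale, between_scale)
    w[iu] = raw
    w = w + w.T
    return BaseNetwork(weights=w, origin="surrogate")


def write_weight_matrix(net: BaseNetwork, path) -> None:
    """Write a network's weight matrix to ``path`` (.npz or dense headerless
    CSV, chosen by extension)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, weights=net.weights)
    elif path.suffix == ".csv":
        np.savetxt(path, net.weights, delimiter=",", fmt="%.17g")
    else:
        raise ValueError("unsupported extension (use .npz or .csv)")


def load_weight_matrix(path) -> BaseNetwork:
    """Load a square symmetric weight matrix from .npz or headerless CSV.

    Asymmetric (beyond 1e-8), non-square, negative, or nonzero-diagonal
    input is rejected; nothing is silently symmetrized.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            key = "weights" if "weights" in data else data.files[0]
            w = np.asarray(data[key], dtype=float)
    elif path.suffix == ".csv":
        w = np.atleast_2d(np.loadtxt(path, delimiter=","))
    else:
        raise ValueError("unsupported extension (use .npz or .csv)")
    return BaseNetwork(weights=w, origin="file")
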