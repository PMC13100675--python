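"""Chaotic task environments simulated by forward-Euler integration.

Six three-dimensional chaotic flows serve as the environments a reservoir
computer learns to forecast: the Lorenz attractor (sigma=10, rho=28,
beta=8/3) and five of Sprott's algebraically simple chaotic systems
(A, B, G, K, R), chosen for their tendency to stay within manageable value
ranges.  All systems are integrated with the forward-Euler scheme at a fixed
step size (h = 0.005 for Lorenz, h = 0.05 for the Sprott systems).

Initial conditions are drawn uniformly from a per-variable box covering the
approximate extent of each attractor and then burned in for a random number
of Euler steps between 1 and round(1/h) (up to one model time unit), so that
trajectories start on or near the attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnvironmentSpec",
    "Trajectory",
    "get_environment",
    "ENVIRONMENT_NAMES",
    "derivative",
    "euler_step",
    "sample_initial_condition",
    "generate_trajectory",
]

# Hard bound on any state component; beyond this the trajectory is treated
# as divergent (off to infinity, not on the attractor).
DIVERGENCE_BOUND = 1e6

# Retries when a sampled initial condition diverges during burn-in.
MAX_INIT_RETRIES = 100


class TrajectoryDivergenceError(RuntimeError):
    """A simulated trajectory left the finite/bounded regime."""


@dataclass(frozen=True)
class EnvironmentSpec:
    """Definition of one chaotic task environment.

    Parameters
    ----------
    name : str
        Canonical system name ("Lorenz", "SprottA", ...).
    step_size : float
        Forward-Euler step size h, in model time units.
    init_ranges : ndarray of shape (3, 2)
        Per-variable [low, high] intervals the initial condition is drawn
        from (unordered endpoints are normalized at construction).
    """

    name: str
    step_size: float
    init_ranges: np.ndarray = field(repr=False)
    dimension: int = 3

    def __post_init__(self):
        ranges = np.asarray(self.init_ranges, dtype=float)
        if ranges.shape != (self.dimension, 2):
            raise ValueError(f"init_ranges must be ({self.dimension}, 2)")
        # endpoints may be printed in either order; normalize to low < high
        lo = ranges.min(axis=1)
        hi = ranges.max(axis=1)
        if np.any(lo >= hi):
            raise ValueError("each init interval needs lower < upper")
        object.__setattr__(self, "init_ranges", np.column_stack([lo, hi]))
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")


def _lorenz(s):
    x, y, z = s
    return np.array([10.0 * (y - x), x * (28.0 - z) - y, x * y - (8.0 / 3.0) * z])


def _sprott_a(s):
    x, y, z = s
    return np.array([y, -x + y * z, 1.0 - y * y])


def _sprott_b(s):
    x, y, z = s
    return np.array([y * z, x - y, 1.0 - x * y])


def _sprott_g(s):
    x, y, z = s
    return np.array([0.4 * x + z, x * z - y, -x + y])


def _sprott_k(s):
    x, y, z = s
    return np.array([x * y - z, x - y, x + 0.3 * z])


def _sprott_r(s):
    x, y, z = s
    return np.array([0.9 - y, 0.4 + z, x * y - z])


_SYSTEMS = {
    "Lorenz": (_lorenz, 0.005, [(-20.0, 40.0), (-25.0, 50.0), (0.0, 50.0)]),
    "SprottA": (_sprott_a, 0.05, [(-5.0, 10.0), (-5.0, 10.0), (-5.0, 10.0)]),
    "SprottB": (_sprott_b, 0.05, [(-5.0, 10.0), (-5.0, 10.0), (-5.0, 10.0)]),
    "SprottG": (_sprott_g, 0.05, [(-3.0, 5.0), (-3.0, 4.0), (-3.0, 6.0)]),
    "SprottK": (_sprott_k, 0.05, [(-4.7, 6.6), (-2.5, 4.0), (-0.8, 6.7)]),
    "SprottR": (_sprott_r, 0.05, [(-5.0, 7.0), (-2.5, 7.5), (-9.0, 10.0)]),
}

ENVIRONMENT_NAMES = tuple(_SYSTEMS)

# accept a few aliases for CLI friendliness
_ALIASES = {name.lower(): name for name in _SYSTEMS}
_ALIASES.update({"lorenz": "Lorenz"})
_ALIASES.update({f"sprott{c}": f"Sprott{c.upper()}" for c in "abgkr"})
_ALIASES.update({f"sprott_{c}": f"Sprott{c.upper()}" for c in "abgkr"})


def get_environment(name: str) -> EnvironmentSpec:
    """Look up an :class:`EnvironmentSpec` by (case-insensitive) name."""
    canonical = _ALIASES.get(str(name).lower())
    if canonical is None:
        raise ValueError(
            f"unknown environment {name!r}; choose from {ENVIRONMENT_NAMES}"
        )
    fn, h, ranges = _SYSTEMS[canonical]
    return EnvironmentSpec(name=canonical, step_size=h, init_ranges=np.array(ranges))


@dataclass(frozen=True)
class Trajectory:
    """A simulated environmental time series.

    Attributes
    ----------
    values : ndarray of shape (T, 3)
        The state at each time step.
    spec_name : str
        Name of the generating environment.
    per_variable_sd : ndarray of shape (3,)
        Standard deviation of each variable over the stored window; used to
        standardize forecast errors.
    """

    values: np.ndarray
    spec_name: str
    per_variable_sd: np.ndarray = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 2:
            raise ValueError("values must be a (T>=2, D) array")
        if not np.all(np.isfinite(values)):
            raise ValueError("trajectory contains non-finite entries")
        object.__setattr__(self, "values", values)
        if self.per_variable_sd is None:
            object.__setattr__(self, "per_variable_sd", values.std(axis=0))

    def __len__(self):
        return self.values.shape[0]


def derivative(spec: EnvironmentSpec, state) -> np.ndarray:
    """Right-hand side of the environment's ODE at ``state``."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("state must be finite")
    fn = _SYSTEMS[spec.name][0]
    return fn(state)


def euler_step(spec: EnvironmentSpec, state) -> np.ndarray:
    """One forward-Euler update: state + h * f(state)."""
    state = np.asarray(state, dtype=float)
    return state + spec.step_size * derivative(spec, state)


def _burn_in_steps(spec: EnvironmentSpec) -> int:
    return int(round(1.0 / spec.step_size))


def sample_initial_condition(
    spec: EnvironmentSpec, rng: np.random.Generator, *, burn_in: int | None = None
) -> np.ndarray:
    """Draw an on-attractor initial condition.

    A point is drawn uniformly from the environment's init box and advanced
    by a uniformly random number of Euler steps in [1, round(1/h)] (at most
    one model time unit), which pulls it onto the attractor. Draws that
    diverge during burn-in are resampled (bounded retries).

    Parameters
    ----------
    burn_in : int, optional
        Fix the number of burn-in steps instead of drawing it (used by
        tests and for reproducible pipelines).
    """
    max_steps = _burn_in_steps(spec)
    for _ in range(MAX_INIT_RETRIES):
        state = rng.uniform(spec.init_ranges[:, 0], spec.init_ranges[:, 1])
        n = burn_in if burn_in is not None else int(rng.integers(1, max_steps + 1))
        ok = True
        for _ in range(n):
            state = euler_step(spec, state)
            if not np.all(np.isfinite(state)) or np.any(
                np.abs(state) > DIVERGENCE_BOUND
            ):
                ok = False
                break
        if ok:
            return state
    raise TrajectoryDivergenceError(
        f"could not sample a bounded initial condition for {spec.name}"
    )


def generate_trajectory(
    spec: EnvironmentSpec,
    n_steps: int,
    rng: np.random.Generator,
    *,
    max_restarts: int = 100,
) -> Trajectory:
    """Simulate ``n_steps`` states of the environment from a fresh initial
    condition.

    The init boxes cover the approximate attractor extent but not its
    basin exactly, so some draws escape to infinity (common for the Sprott
    systems at h = 0.05).  Such runs are discarded and restarted from a
    fresh initial condition, up to ``max_restarts`` times; only surviving
    (bounded, finite) trajectories are returned.

    Raises
    ------
    TrajectoryDivergenceError
        Naming the offending step index, once restarts are exhausted (or
        immediately when ``max_restarts=0``).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    err = None
    for _ in range(max_restarts + 1):
        state = sample_initial_condition(spec, rng)
        out = np.empty((n_steps, spec.dimension))
        out[0] = state
        for t in range(1, n_steps):
            state = euler_step(spec, state)
            if not np.all(np.isfinite(state)) or np.any(
                np.abs(state) > DIVERGENCE_BOUND
            ):
                err = TrajectoryDivergenceError(
                    f"{spec.name} trajectory diverged at step {t}"
                )
                break
            out[t] = state
        else:
            return Trajectory(values=out, spec_name=spec.name)
    raise err
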