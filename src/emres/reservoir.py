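"""Echo-state reservoir computers: build, drive, train, forecast, evaluate.

The reservoir is a network of N leaky tanh neurons with fixed symmetric
recurrent weights C, driven by a 3-dimensional input through W_in with a
scalar bias theta:

    r_{t+1} = h * tanh(C r_t + W_in u_t + theta) + (1 - h) * r_t        (drive)

with leak/Euler constant h = 0.005.  Only the linear readout W_out is
trained, by Tikhonov ridge regression of the next input u_{t+1} on the
current state r_t:

    W_out = U R^T (R R^T + beta I)^{-1}                                 (train)

Forecasts run the reservoir autonomously, substituting the readout's own
output for the external input:

    r_{t+1} = h * tanh(C r_t + W_in W_out r_t + theta) + (1 - h) r_t    (forecast)

Because each update is a convex combination of the previous state and a
tanh (bounded in [-1, 1]), driven states can never diverge.

Five hyperparameters (a genotype) govern reservoir construction: alpha
(spectral-radius scale of C), beta (ridge regularization), rho (connection
density), sigma (max absolute input weight), theta (input bias).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.base import BaseEstimator, RegressorMixin

from .emergence import prediction_loss, psi
from .topologies import BaseNetwork, random_symmetric_network

__all__ = [
    "Genotype",
    "Reservoir",
    "ForecastResult",
    "TrialMetrics",
    "EvaluationSummary",
    "build_coupling_matrix",
    "build_reservoir",
    "drive",
    "fit_readout",
    "forecast",
    "permute_readout",
    "evaluate_reservoir",
    "EchoStateForecaster",
]

DEFAULT_LEAK = 0.005
DEFAULT_SPIN_UP = 500
DEFAULT_FORECAST_LEN = 1000


@dataclass(frozen=True)
class Genotype:
    """Tunable reservoir hyperparameters.

    alpha : spectral-radius scale of C (dimensionless, > 0)
    beta  : Tikhonov ridge regularization (> 0)
    rho   : connection density 2E/(N(N-1)) (in (0, 1])
    sigma : maximum absolute input weight (> 0)
    theta : input bias added to every neuron's tanh argument
    """

    alpha: float
    beta: float
    rho: float
    sigma: float
    theta: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0 or self.sigma <= 0:
            raise ValueError("alpha, beta, sigma must be positive")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "rho": self.rho,
            "sigma": self.sigma,
            "theta": self.theta,
        }


@dataclass
class Reservoir:
    """A built reservoir: coupling matrix, input weights, bias, and state."""

    C: np.ndarray
    W_in: np.ndarray
    theta: float
    leak: float = DEFAULT_LEAK
    state: np.ndarray = None

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        self.W_in = np.asarray(self.W_in, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("C must be square")
        if self.W_in.shape[0] != self.C.shape[0]:
            raise ValueError("W_in must have one row per neuron")
        if self.state is None:
            self.state = np.zeros(self.C.shape[0])
        else:
            self.state = np.asarray(self.state, dtype=float)

    @property
    def n_neurons(self) -> int:
        return self.C.shape[0]

    def reset(self) -> None:
        """Zero the reservoir state (done before every spin-up)."""
        self.state = np.zeros(self.n_neurons)


@dataclass(frozen=True)
class ForecastResult:
    """Autonomous forecast (the macro feature V_t) with the underlying
    reservoir-state trajectory (the micro variables X_t)."""

    forecast: np.ndarray  # (T, 3)
    states: np.ndarray  # (T, N)

    def __post_init__(self):
        if self.forecast.shape[0] != self.states.shape[0]:
            raise ValueError("forecast and states must share the time axis")


@dataclass(frozen=True)
class TrialMetrics:
    """Loss and psi of one test forecast, with threshold flags."""

    loss: float
    psi: float
    success: bool = field(init=False)
    emergent: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "success", bool(self.loss < 1.0))
        # NaN psi (undefined) counts as non-emergent
        object.__setattr__(self, "emergent", bool(self.psi > 0))


@dataclass(frozen=True)
class EvaluationSummary:
    """Aggregated evaluation of one reservoir over repeated test forecasts."""

    trials: pd.DataFrame  # columns: trial, loss, psi, success, emergent
    mean_loss: float
    mean_psi: float
    p_success: float
    p_emergent: float

    @property
    def n_tests(self) -> int:
        return len(self.trials)

    @classmethod
    def from_trials(cls, trials: list[TrialMetrics]) -> "EvaluationSummary":
        frame = pd.DataFrame(
            {
                "trial": np.arange(len(trials)),
                "loss": [t.loss for t in trials],
                "psi": [t.psi for t in trials],
                "success": [t.success for t in trials],
                "emergent": [t.emergent for t in trials],
            }
        )
        psis = frame["psi"].to_numpy()
        return cls(
            trials=frame,
            mean_loss=float(frame["loss"].mean()),
            mean_psi=float(np.nanmean(psis)) if np.any(np.isfinite(psis)) else np.nan,
            p_success=float(frame["success"].mean()),
            p_emergent=float(frame["emergent"].mean()),
        )


def build_coupling_matrix(
    base: BaseNetwork, g: Genotype, *, scale_mode: str = "minmax"
) -> np.ndarray:
    """Derive the reservoir coupling matrix C from a base network.

    Steps: keep the E = round(rho * N(N-1)/2) largest-weight undirected
    edges (weakest edges are pruned — in tractography-derived networks weak
    edges are the most likely false positives), rescale the survivors
    linearly to [0, 1], multiply by alpha, and zero the diagonal.  Ties at
    the cutoff weight break deterministically by (i, j) index order.

    With ``scale_mode="spectral"`` the pruned matrix is instead divided by
    its true spectral radius before multiplying by alpha.
    """
    n = base.n_nodes
    e = int(round(g.rho * n * (n - 1) / 2))
    if e < 1:
        raise ValueError(f"density rho={g.rho} keeps no edges for N={n}")
    iu, ju = np.triu_indices(n, k=1)
    w = base.weights[iu, ju]
    # stable order: weight descending, then (i, j) lexicographic
    order = np.lexsort((ju, iu, -w))
    keep = order[:e]
    c = np.zeros((n, n))
    kept = w[keep]
    if scale_mode == "minmax":
        lo, hi = kept.min(), kept.max()
        scaled = np.ones_like(kept) if hi == lo else (kept - lo) / (hi - lo)
        c[iu[keep], ju[keep]] = g.alpha * scaled
        c = c + c.T
    elif scale_mode == "spectral":
        c[iu[keep], ju[keep]] = kept
        c = c + c.T
        radius = np.max(np.abs(np.linalg.eigvalsh(c)))
        if radius == 0:
            raise ValueError("pruned matrix has zero spectral radius")
        c = g.alpha * c / radius
    else:
        raise ValueError("scale_mode must be 'minmax' or 'spectral'")
    return c


def sample_input_direction(
    n_neurons: int, rng: np.random.Generator, n_inputs: int = 3
) -> np.ndarray:
    """Unit-scale input weight directions, uniform on [-1, 1].

    Sampled once per individual and rescaled by the current sigma, so that
    mutating sigma rescales rather than resamples the input weights.
    """
    return rng.uniform(-1.0, 1.0, size=(n_neurons, n_inputs))


def build_reservoir(
    base: BaseNetwork,
    g: Genotype,
    rng: np.random.Generator,
    *,
    leak: float = DEFAULT_LEAK,
    input_direction: np.ndarray | None = None,
    scale_mode: str = "minmax",
) -> Reservoir:
    """Build a reservoir from a base network and a genotype.

    W_in entries are uniform on [-sigma, sigma]; if ``input_direction`` is
    given (unit-scale, from :func:`sample_input_direction`) it is rescaled
    by sigma instead of drawing fresh weights.
    """
    c = build_coupling_matrix(base, g, scale_mode=scale_mode)
    direction = (
        sample_input_direction(base.n_nodes, rng)
        if input_direction is None
        else np.asarray(input_direction, dtype=float)
    )
    return Reservoir(C=c, W_in=g.sigma * direction, theta=g.theta, leak=leak)


def _step(res: Reservoir, r: np.ndarray, pre: np.ndarray) -> np.ndarray:
    """One leaky update given the pre-activation C r + W_in u."""
    return res.leak * np.tanh(pre + res.theta) + (1.0 - res.leak) * r


def drive(
    res: Reservoir, inputs: np.ndarray, initial_state: np.ndarray | None = None
) -> np.ndarray:
    """Drive the reservoir with an input series; return the state after
    each update (shape (T, N)).  The reservoir's state is mutated so calls
    can be chained (spin-up, then training drive)."""
    inputs = np.asarray(inputs, dtype=float)
    if not np.all(np.isfinite(inputs)):
        raise ValueError("inputs must be finite")
    r = res.state if initial_state is None else np.asarray(initial_state, dtype=float)
    t_len = inputs.shape[0]
    out = np.empty((t_len, res.n_neurons))
    c, w_in = res.C, res.W_in
    for t in range(t_len):
        r = _step(res, r, c @ r + w_in @ inputs[t])
        out[t] = r
    if not np.all(np.isfinite(r)):
        raise FloatingPointError("reservoir state became non-finite")
    res.state = r
    return out


def fit_readout(states: np.ndarray, inputs: np.ndarray, beta: float) -> np.ndarray:
    """Ridge-regress next inputs on current states; return W_out (3, N).

    ``states`` holds r_t for t = 1..T (each generated after consuming input
    u_t); ``inputs`` holds u_t for t = 1..T+1, so the targets u_{t+1} are
    ``inputs[1:]``.  Solves W_out = U R^T (R R^T + beta I)^{-1}.  Spin-up
    states are excluded by the caller.
    """
    states = np.asarray(states, dtype=float)
    inputs = np.asarray(inputs, dtype=float)
    if inputs.shape[0] != states.shape[0] + 1:
        raise ValueError("need exactly one more input row than state rows")
    targets = inputs[1:]
    gram = states.T @ states  # R R^T, (N, N)
    rhs = states.T @ targets  # R U^T, (N, 3)
    n = gram.shape[0]
    try:
        sol = sla.solve(gram + beta * np.eye(n), rhs, assume_a="pos")
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular ridge system ({err}); use beta > 0 to regularize"
        ) from err
    if not np.all(np.isfinite(sol)):
        raise np.linalg.LinAlgError(
            "non-finite readout solution; use beta > 0 to regularize"
        )
    return sol.T


def forecast(res: Reservoir, w_out: np.ndarray, n_steps: int) -> ForecastResult:
    """Run the reservoir autonomously for ``n_steps``.

    At each step the current output yhat_t = W_out r_t is recorded together
    with r_t, then fed back as the input of the next update — so the stored
    arrays satisfy forecast[t] = W_out @ states[t] exactly, and the first
    recorded state is the (already spun-up) entry state.
    """
    w_out = np.asarray(w_out, dtype=float)
    r = res.state
    ys = np.empty((n_steps, w_out.shape[0]))
    xs = np.empty((n_steps, res.n_neurons))
    c, w_in = res.C, res.W_in
    for t in range(n_steps):
        y = w_out @ r
        ys[t] = y
        xs[t] = r
        r = _step(res, r, c @ r + w_in @ y)
        if not np.all(np.isfinite(r)):
            raise FloatingPointError(f"forecast diverged at step {t}")
    res.state = r
    return ForecastResult(forecast=ys, states=xs)


def permute_readout(w_out: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute the N weights within each output row,
    preserving each target variable's weight distribution."""
    w_out = np.asarray(w_out, dtype=float)
    out = np.empty_like(w_out)
    for i in range(w_out.shape[0]):
        out[i] = w_out[i, rng.permutation(w_out.shape[1])]
    return out


# ---------------------------------------------------------------------------
# batched drive/forecast used by evaluate_reservoir (identical arithmetic to
# drive()/forecast(), vectorized over test trajectories)
# ---------------------------------------------------------------------------


def _drive_batch(res: Reservoir, inputs: np.ndarray, r: np.ndarray) -> np.ndarray:
    """inputs: (T, 3, B); r: (N, B) -> final states (N, B)."""
    c, w_in, th, h = res.C, res.W_in, res.theta, res.leak
    for t in range(inputs.shape[0]):
        r = h * np.tanh(c @ r + w_in @ inputs[t] + th) + (1.0 - h) * r
    return r


def _forecast_batch(res: Reservoir, w_out: np.ndarray, r: np.ndarray, n_steps: int):
    """Closed-loop forecast for a batch of states; returns (ys, xs) of
    shapes (T, 3, B) and (T, N, B)."""
    c, w_in, th, h = res.C, res.W_in, res.theta, res.leak
    n, b = r.shape
    ys = np.empty((n_steps, w_out.shape[0], b))
    xs = np.empty((n_steps, n, b))
    for t in range(n_steps):
        y = w_out @ r
        ys[t] = y
        xs[t] = r
        r = h * np.tanh(c @ r + w_in @ y + th) + (1.0 - h) * r
    return ys, xs


def evaluate_reservoir(
    base: BaseNetwork,
    g: Genotype,
    train,
    tests,
    rng: np.random.Generator,
    *,
    spin_up: int = DEFAULT_SPIN_UP,
    forecast_len: int = DEFAULT_FORECAST_LEN,
    input_direction: np.ndarray | None = None,
    leak: float = DEFAULT_LEAK,
    scale_mode: str = "minmax",
) -> EvaluationSummary:
    """Full train-and-evaluate cycle for one reservoir configuration.

    Builds the reservoir, drives it on the training trajectory (the first
    ``spin_up`` states are excluded from the readout fit), ridge-fits the
    readout against next-step targets, then for each test trajectory resets
    the state, spins up on its first ``spin_up`` steps, forecasts
    ``forecast_len`` steps, and scores loss (vs the ground truth
    continuation) and psi (forecast vs reservoir states).

    A trial whose forecast goes non-finite gets loss = +inf (a failure) and
    undefined psi (counted non-emergent).  Returns per-trial metrics plus
    mean loss, mean psi, P(S) = fraction(loss < 1), P(E) = fraction(psi > 0).
    """
    train_values = train.values if hasattr(train, "values") else np.asarray(train)
    if train_values.shape[0] < spin_up + 2:
        raise ValueError("training trajectory shorter than spin-up window")
    res = build_reservoir(
        base, g, rng, leak=leak, input_direction=input_direction, scale_mode=scale_mode
    )
    states = drive(res, train_values[:-1])
    w_out = fit_readout(states[spin_up:], train_values[spin_up:], g.beta)

    test_arrays = [
        t.values if hasattr(t, "values") else np.asarray(t, dtype=float) for t in tests
    ]
    need = spin_up + forecast_len
    for i, arr in enumerate(test_arrays):
        if arr.shape[0] < need:
            raise ValueError(f"test trajectory {i} shorter than {need} steps")
    b = len(test_arrays)
    spin_inputs = np.stack([arr[:spin_up] for arr in test_arrays], axis=2)
    r = _drive_batch(res, spin_inputs, np.zeros((res.n_neurons, b)))
    ys, xs = _forecast_batch(res, w_out, r, forecast_len)

    trials = []
    for i, arr in enumerate(test_arrays):
        yhat = ys[:, :, i]
        truth = arr[spin_up : spin_up + forecast_len]
        if not np.all(np.isfinite(yhat)):
            trials.append(TrialMetrics(loss=np.inf, psi=np.nan))
            continue
        loss = prediction_loss(yhat, truth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            em = psi((yhat, xs[:, :, i]))
        trials.append(TrialMetrics(loss=loss, psi=em.psi))
    return EvaluationSummary.from_trials(trials)


class EchoStateForecaster(RegressorMixin, BaseEstimator):
    """Scikit-learn-style echo-state forecaster of chaotic time series.

    ``fit(U)`` takes a (T, 3) training trajectory: the reservoir is driven
    by it and the linear readout is ridge-fitted to predict u_{t+1} from
    the reservoir state at t (the first ``spin_up`` states are excluded).
    ``predict(U_test, horizon)`` spins the reservoir up on the first
    ``spin_up`` rows of a test trajectory and forecasts autonomously.

    Parameters
    ----------
    alpha, beta, rho, sigma, theta : float
        Reservoir hyperparameters (see :class:`Genotype`).
    network : BaseNetwork or None
        Base connectivity; a fresh uniform random symmetric network of
        ``n_neurons`` nodes is drawn when None.
    n_neurons : int
        Reservoir size (used only when ``network`` is None).
    leak : float
        Leak/Euler constant h of the state update.
    spin_up : int
        Synchronization steps discarded before fitting / forecasting.
    scale_mode : {"minmax", "spectral"}
        How pruned coupling weights are normalized before scaling by alpha.
    random_state : int, Generator or None
        Seeds the base network and input-weight draws.

    Attributes
    ----------
    C_ : ndarray of shape (N, N)
        Built coupling matrix.
    W_in_ : ndarray of shape (N, 3)
        Input weights (max absolute value <= sigma).
    W_out_ : ndarray of shape (3, N)
        Trained readout.
    reservoir_ : Reservoir
        The underlying reservoir (mutable state).
    spectral_radius_ : float
        Realized spectral radius of C_ (diagnostic; equals alpha only in
        ``spectral`` mode).
    """

    def __init__(
        self,
        alpha: float = 0.9,
        beta: float = 5e-8,
        rho: float = 0.05,
        sigma: float = 0.05,
        theta: float = 0.5,
        network: BaseNetwork | None = None,
        n_neurons: int = 100,
        leak: float = DEFAULT_LEAK,
        spin_up: int = DEFAULT_SPIN_UP,
        scale_mode: str = "minmax",
        random_state=None,
    ):
        self.alpha = alpha
        self.beta = beta
        self.rho = rho
        self.sigma = sigma
        self.theta = theta
        self.network = network
        self.n_neurons = n_neurons
        self.leak = leak
        self.spin_up = spin_up
        self.scale_mode = scale_mode
        self.random_state = random_state

    def _genotype(self) -> Genotype:
        return Genotype(
            alpha=self.alpha,
            beta=self.beta,
            rho=self.rho,
            sigma=self.sigma,
            theta=self.theta,
        )

    def fit(self, X, y=None):
        """Drive the reservoir on a (T, 3) training trajectory and fit the
        readout.  ``y`` is ignored (targets are the trajectory's own next
        steps)."""
        u = np.asarray(X, dtype=float)
        if u.ndim != 2:
            raise ValueError("X must be a (T, D) trajectory")
        if u.shape[0] < self.spin_up + 2:
            raise ValueError("training trajectory shorter than spin-up window")
        rng = np.random.default_rng(self.random_state)
        base = (
            self.network
            if self.network is not None
            else random_symmetric_network(self.n_neurons, rng)
        )
        res = build_reservoir(
            base, self._genotype(), rng, leak=self.leak, scale_mode=self.scale_mode
        )
        states = drive(res, u[:-1])
        self.W_out_ = fit_readout(
            states[self.spin_up :], u[self.spin_up :], self.beta
        )
        self.reservoir_ = res
        self.C_ = res.C
        self.W_in_ = res.W_in
        self.spectral_radius_ = float(np.max(np.abs(np.linalg.eigvalsh(res.C))))
        self.n_features_in_ = u.shape[1]
        return self

    def forecast_trace(self, X, horizon: int | None = None) -> ForecastResult:
        """Spin up on the first ``spin_up`` rows of ``X`` and forecast;
        returns forecast and reservoir-state trajectories."""
        if not hasattr(self, "W_out_"):
            raise RuntimeError("call fit() before forecasting")
        u = np.asarray(X, dtype=float)
        if u.shape[0] < self.spin_up:
            raise ValueError("test trajectory shorter than spin-up window")
        if horizon is None:
            horizon = max(u.shape[0] - self.spin_up, 1)
        res = self.reservoir_
        res.reset()
        drive(res, u[: self.spin_up])
        return forecast(res, self.W_out_, horizon)

    def predict(self, X, horizon: int | None = None) -> np.ndarray:
        """Forecast the continuation of a test trajectory; returns the
        (horizon, 3) forecast."""
        return self.forecast_trace(X, horizon).forecast

    def score(self, X, y=None) -> float:
        """Negative prediction loss of forecasting ``X``'s continuation
        (higher is better)."""
        u = np.asarray(X, dtype=float)
        horizon = u.shape[0] - self.spin_up
        result = self.forecast_trace(X, horizon)
        truth = u[self.spin_up : self.spin_up + horizon]
        return -prediction_loss(result.forecast, truth)
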