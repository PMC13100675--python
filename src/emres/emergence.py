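"""Prediction loss and the psi causal-emergence statistic.

psi lower-bounds causal emergence of a macroscopic feature V_t supervenient
on a multivariate microstate X_t.  At first order (k = 1) and lag tau,

    psi = I(V_t ; V_{t+tau}) - sum_i I(X_t^i ; V_{t+tau}),

the self-predictive information of the macro feature minus the summed
predictive information of each micro variable taken separately.  psi > 0 is
a sufficient (not necessary) criterion for emergence: redundant information
shared by micro variables is subtracted once per variable, which can push
psi below zero even for genuinely emergent features.

Here V_t is the reservoir computer's 3-dimensional forecast (a linear
combination of all reservoir neuron states, hence supervenient) and X_t the
N reservoir neuron states.  Mutual information is estimated with the
Gaussian (covariance-determinant) estimator in nats, treating time points
within one forecast window as samples (a stationarity assumption).

The prediction loss is a standardized, exponentially discounted mean
absolute error: later errors count exponentially less (weight e^{-t/T}),
since chaotic divergence makes late errors uninformative about model
quality.  A forecast with loss < 1 is counted a success.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["EmergenceResult", "gaussian_mi", "psi", "prediction_loss"]

_DEGENERATE_VAR = 1e-300


class EstimatorError(ValueError):
    """Raised when the Gaussian MI estimator cannot be evaluated."""


@dataclass(frozen=True)
class EmergenceResult:
    """Decomposition of psi into its macro and micro terms (nats)."""

    psi: float
    macro_term: float
    micro_sum: float
    tau: int = 1
    k: int = 1

    @property
    def emergent(self) -> bool:
        """Whether psi > 0 (sufficient criterion; NaN counts as False)."""
        return bool(self.psi > 0)


def _logdet(cov: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(cov)
    if sign <= 0:
        raise EstimatorError(
            "singular joint covariance (collinear/degenerate data); "
            "Gaussian MI is undefined"
        )
    return ld


def gaussian_mi(X, Y) -> float:
    """Gaussian mutual information estimate between X and Y, in nats.

    Computes 0.5 * ln(det Sigma_X * det Sigma_Y / det Sigma_[X,Y]) from
    sample covariances, clipped below at 0 (the population quantity is
    nonnegative; sampling noise can make the raw value slightly negative).

    Parameters
    ----------
    X : array-like of shape (T,) or (T, p)
    Y : array-like of shape (T,) or (T, q)

    Raises
    ------
    EstimatorError
        If any marginal or the joint covariance is singular (perfectly
        collinear or constant columns).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float).T).T
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y need the same number of samples")
    t, p = X.shape
    q = Y.shape[1]
    if t <= p + q + 2:
        raise ValueError(f"need T > p + q + 2 samples (got T={t}, p={p}, q={q})")
    joint = np.cov(np.hstack([X, Y]), rowvar=False)
    ld_joint = _logdet(joint)
    ld_x = _logdet(joint[:p, :p])
    ld_y = _logdet(joint[p:, p:])
    return max(0.0, 0.5 * (ld_x + ld_y - ld_joint))


def psi(forecast_and_states, tau: int = 1) -> EmergenceResult:
    """First-order psi of a forecast with respect to its reservoir states.

    Parameters
    ----------
    forecast_and_states : object with ``forecast`` (T, 3) and ``states``
        (T, N) arrays (a :class:`~emres.reservoir.ForecastResult`), or a
        ``(forecast, states)`` tuple.
    tau : int
        Prediction lag in time steps; 1 matches the reservoir's one-step-
        ahead prediction target.

    Returns
    -------
    EmergenceResult
        With ``psi = macro_term - micro_sum`` exactly.  If the forecast is
        (near-)constant in some variable, psi is undefined: the result
        carries NaN and a warning is issued; such trials are treated as
        non-emergent downstream.

    Notes
    -----
    Each micro term I(X^i_t; V_{t+tau}) is evaluated through the Schur
    complement of the joint covariance, which is algebraically identical to
    :func:`gaussian_mi` per neuron but runs in one pass.  Neurons with zero
    variance carry no information and contribute 0.
    """
    if hasattr(forecast_and_states, "forecast"):
        v = np.asarray(forecast_and_states.forecast, dtype=float)
        x = np.asarray(forecast_and_states.states, dtype=float)
    else:
        v, x = (np.asarray(a, dtype=float) for a in forecast_and_states)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    t = v.shape[0]
    if x.shape[0] != t:
        raise ValueError("forecast and states must share the time axis")
    if t < 100 + tau:
        raise ValueError(f"need at least {100 + tau} time steps, got {t}")

    v_now = v[:-tau]
    v_fut = v[tau:]
    x_now = x[:-tau]
    d = v.shape[1]

    if np.any(v.var(axis=0) <= _DEGENERATE_VAR):
        warnings.warn(
            "constant forecast: psi undefined, flagged non-emergent",
            RuntimeWarning,
            stacklevel=2,
        )
        return EmergenceResult(psi=np.nan, macro_term=np.nan, micro_sum=np.nan, tau=tau)

    try:
        macro = gaussian_mi(v_now, v_fut)
        # joint covariance of [X_t, V_{t+tau}] in one pass
        joint = np.cov(np.hstack([x_now, v_fut]), rowvar=False)
        n = x.shape[1]
        sig_x = np.diagonal(joint)[:n].copy()
        sig_vf = joint[n:, n:]
        cross = joint[:n, n:]  # (n, d) covariances between X^i and V_fut
        # I(X^i; Vf) = -0.5 ln(1 - c_i^T Sigma_Vf^{-1} c_i / var_i)
        quad = np.einsum("ij,ij->i", cross @ np.linalg.inv(sig_vf), cross)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(sig_x > _DEGENERATE_VAR, quad / sig_x, 0.0)
        ratio = np.clip(ratio, 0.0, 1.0 - 1e-15)
        micro = float(np.sum(-0.5 * np.log1p(-ratio)))
    except EstimatorError:
        warnings.warn(
            "degenerate forecast/state covariance: psi undefined, "
            "flagged non-emergent",
            RuntimeWarning,
            stacklevel=2,
        )
        return EmergenceResult(psi=np.nan, macro_term=np.nan, micro_sum=np.nan, tau=tau)

    return EmergenceResult(psi=macro - micro, macro_term=macro, micro_sum=micro, tau=tau)


def prediction_loss(forecast, truth, sd=None) -> float:
    """Standardized, exponentially discounted forecast error.

    loss = (1/(T*D)) * sum_t sum_i (|yhat_i(t) - y_i(t)| / sigma_i) * e^(-t/T)

    with t = 1..T, sigma_i the standard deviation of the true trajectory's
    i-th variable over the window (or ``sd`` if supplied, e.g. computed over
    a longer reference window).  The loss is linear in the error magnitude
    and weights late errors down to e^-1 at t = T.

    Raises
    ------
    ValueError
        On shape mismatch or a degenerate (zero-variance) truth variable.
    """
    yhat = np.asarray(forecast, dtype=float)
    y = np.asarray(truth, dtype=float)
    if yhat.shape != y.shape or yhat.ndim != 2:
        raise ValueError("forecast and truth must be equal-shape (T, D) arrays")
    t_len, d = y.shape
    sigma = np.asarray(sd, dtype=float) if sd is not None else y.std(axis=0)
    if np.any(sigma <= 0):
        raise ValueError("degenerate truth: zero variance in some variable")
    t = np.arange(1, t_len + 1)
    weights = np.exp(-t / t_len)
    eps = np.abs(yhat - y) / sigma
    return float(np.sum(eps * weights[:, None]) / (t_len * d))
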