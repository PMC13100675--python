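"""Gaussian mutual information, the psi emergence statistic, and the
discounted prediction loss."""

import numpy as np
import pytest

from emres.emergence import (
    EstimatorError,
    gaussian_mi,
    prediction_loss,
    psi,
)


# ---------------------------------------------------------------------------
# gaussian_mi
# ---------------------------------------------------------------------------


def test_mi_matches_bivariate_closed_form():
    """For bivariate normal data with correlation r, MI = -0.5 ln(1-r^2)."""
    r = 0.5
    rng = np.random.default_rng(42)
    z = rng.standard_normal((100_000, 2))
    x = z[:, 0]
    y = r * z[:, 0] + np.sqrt(1 - r**2) * z[:, 1]
    expected = -0.5 * np.log(1 - r**2)  # 0.14384 nats
    assert abs(gaussian_mi(x, y) - expected) < 0.01


def test_mi_independent_data_near_zero():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((20_000, 2))
    y = rng.standard_normal((20_000, 3))
    # estimator bias ~ p*q/(2T)
    assert gaussian_mi(x, y) < 0.005


def test_mi_nonnegative_and_symmetric(rng):
    x = rng.standard_normal((500, 2))
    y = 0.3 * x[:, :1] + rng.standard_normal((500, 2))
    a = gaussian_mi(x, y)
    b = gaussian_mi(y, x)
    assert a >= 0
    assert abs(a - b) < 1e-12


def test_mi_invariant_under_invertible_linear_maps(rng):
    x = rng.standard_normal((2000, 2))
    y = x @ np.array([[0.5, 0.1], [0.0, 0.4]]) + rng.standard_normal((2000, 2))
    base = gaussian_mi(x, y)
    a = np.array([[2.0, 1.0], [0.5, 3.0]])
    b = np.array([[1.0, -2.0], [0.0, 0.7]])
    mapped = gaussian_mi(x @ a, y @ b)
    assert abs(mapped - base) < 1e-8 * max(1.0, abs(base))


def test_mi_errors():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(300)
    with pytest.raises(EstimatorError, match="singular"):
        gaussian_mi(np.column_stack([x, 2 * x]), rng.standard_normal(300))
    with pytest.raises(ValueError, match="samples"):
        gaussian_mi(x[:4], x[:4])


def test_mi_bias_small_at_forecast_scale():
    """Mean estimate on independent data (T=1000, p=1, q=3) stays below
    0.01 nats over 200 replicates, so psi's micro terms are not inflated
    by estimator bias at the evaluation window size."""
    rng = np.random.default_rng(2024)
    estimates = [
        gaussian_mi(rng.standard_normal(1000), rng.standard_normal((1000, 3)))
        for _ in range(200)
    ]
    assert np.mean(estimates) < 0.01


# ---------------------------------------------------------------------------
# psi
# ---------------------------------------------------------------------------


def _ar1_batch(rng, t_len, n, phi=0.8):
    x = np.zeros((t_len, n))
    for i in range(1, t_len):
        x[i] = phi * x[i - 1] + rng.standard_normal(n)
    return x


def test_psi_decomposition_identity(rng):
    x = _ar1_batch(rng, 800, 5)
    v = x @ rng.standard_normal((5, 3))
    res = psi((v, x))
    assert res.psi == res.macro_term - res.micro_sum
    assert res.macro_term >= 0
    assert res.micro_sum >= 0


def test_psi_micro_terms_match_per_neuron_gaussian_mi(rng):
    """The vectorized micro sum equals summing gaussian_mi neuron by
    neuron."""
    x = _ar1_batch(rng, 600, 4)
    v = x @ rng.standard_normal((4, 2)) + 0.1 * rng.standard_normal((600, 2))
    res = psi((v, x))
    manual = sum(gaussian_mi(x[:-1, i], v[1:]) for i in range(4))
    assert abs(res.micro_sum - manual) < 1e-9


def test_psi_single_neuron_copy_not_emergent(rng):
    """If V just copies one neuron, the macro term equals that neuron's
    micro term, so psi <= 0 (up to numerical noise)."""
    x = _ar1_batch(rng, 2000, 6)
    v = x[:, :1].copy()
    res = psi((v, x))
    assert res.psi <= 0.01
    assert not res.emergent


def test_psi_white_noise_near_zero(rng):
    v = rng.standard_normal((5000, 3))
    x = rng.standard_normal((5000, 8))
    res = psi((v, x))
    assert abs(res.psi) < 0.05


def test_psi_constant_forecast_flagged_undefined(rng):
    x = _ar1_batch(rng, 300, 4)
    v = np.ones((300, 3))
    with pytest.warns(RuntimeWarning, match="constant forecast"):
        res = psi((v, x))
    assert np.isnan(res.psi)
    assert not res.emergent


def test_psi_short_window_rejected(rng):
    with pytest.raises(ValueError, match="time steps"):
        psi((rng.standard_normal((50, 3)), rng.standard_normal((50, 4))))


def test_psi_detects_synergy_matching_analytic_oracle():
    """A 2-neuron linear-Gaussian system built so the macro feature
    V = X1 - X2 strongly predicts itself while a large shared noise mode
    leaves each neuron nearly uncorrelated with V's future.

    The stationary covariance is available in closed form, giving all
    three MI terms (and hence psi) analytically.
    """
    c, q_v, q_u = 0.9, 1.0, 50.0
    v_dir = np.array([1.0, -1.0]) / np.sqrt(2)
    u_dir = np.array([1.0, 1.0]) / np.sqrt(2)
    b_mat = c * np.outer(v_dir, v_dir)
    noise_l = np.column_stack([np.sqrt(q_v) * v_dir, np.sqrt(q_u) * u_dir])

    # analytic oracle from the stationary covariance:
    #   s_v = q_v / (1 - c^2) is the variance along the (1,-1) mode;
    #   macro r^2 = c^2; per-neuron r^2 = c^2 s_v / (s_v + q_u)
    s_v = q_v / (1 - c**2)
    macro = -0.5 * np.log(1 - c**2)
    micro = -0.5 * np.log(1 - c**2 * s_v / (s_v + q_u))
    psi_expected = macro - 2 * micro
    assert psi_expected > 0.5

    rng = np.random.default_rng(77)
    t_len, burn = 100_000, 1000
    x = np.zeros(2)
    xs = np.empty((t_len, 2))
    eps = rng.standard_normal((burn + t_len, 2)) @ noise_l.T
    for t in range(burn + t_len):
        x = b_mat @ x + eps[t]
        if t >= burn:
            xs[t - burn] = x
    v = (xs[:, 0] - xs[:, 1]).reshape(-1, 1)
    res = psi((v, xs))
    assert res.psi > 0
    assert abs(res.psi - psi_expected) < 0.02


# ---------------------------------------------------------------------------
# prediction loss
# ---------------------------------------------------------------------------


def _sine_truth(t_len=1000):
    t = np.arange(t_len)[:, None]
    return np.sin(t * np.array([0.1, 0.2, 0.3]) + np.array([0.0, 1.0, 2.0]))


def test_loss_zero_for_perfect_forecast():
    y = _sine_truth()
    assert prediction_loss(y, y) == 0.0


def test_loss_constant_one_sigma_error_matches_direct_sum():
    """A constant error of exactly one SD in every variable gives
    loss = (1/T) * sum_t e^(-t/T) ~ 0.6318 at T = 1000."""
    y = _sine_truth()
    yhat = y + y.std(axis=0)
    t = np.arange(1, 1001)
    expected = np.sum(np.exp(-t / 1000)) / 1000  # direct summation oracle
    loss = prediction_loss(yhat, y)
    assert abs(loss - expected) < 1e-12
    assert abs(expected - 0.6318) < 5e-4


def test_loss_linear_in_error_magnitude():
    y = _sine_truth()
    e = np.random.default_rng(3).standard_normal(y.shape)
    l1 = prediction_loss(y + e, y)
    l3 = prediction_loss(y + 3 * e, y)
    assert abs(l3 - 3 * l1) < 1e-12


def test_loss_permutation_invariant_across_variables():
    y = _sine_truth()
    yhat = y + 0.5 * np.random.default_rng(4).standard_normal(y.shape)
    perm = [2, 0, 1]
    assert abs(
        prediction_loss(yhat, y) - prediction_loss(yhat[:, perm], y[:, perm])
    ) < 1e-12


def test_loss_degenerate_truth_rejected():
    y = np.ones((100, 3))
    with pytest.raises(ValueError, match="degenerate"):
        prediction_loss(y, y)
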