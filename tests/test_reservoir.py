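"""Reservoir construction, dynamics, readout training, forecasting, and
the train/evaluate cycle."""

import numpy as np
import pytest
from scipy import linalg as sla
from sklearn.base import clone

from emres.environments import generate_trajectory
from emres.reservoir import (
    EchoStateForecaster,
    Genotype,
    Reservoir,
    build_coupling_matrix,
    build_reservoir,
    drive,
    evaluate_reservoir,
    fit_readout,
    forecast,
    permute_readout,
)
from emres.topologies import random_symmetric_network


@pytest.fixture
def genotype():
    return Genotype(alpha=0.9, beta=5e-8, rho=0.05, sigma=0.05, theta=0.5)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def test_density_thinning_keeps_round_rho_edges(full_base, genotype):
    g = Genotype(**{**genotype.as_dict(), "rho": 0.1})
    # spectral mode leaves kept weights positive, so the retained edge
    # count is directly round(0.1 * 100 * 99 / 2) = 495
    c_raw = build_coupling_matrix(full_base, g, scale_mode="spectral")
    iu = np.triu_indices(100, k=1)
    kept_mask = c_raw[iu] > 0
    assert kept_mask.sum() == 495
    # the survivors are exactly the largest-weight edges
    assert full_base.weights[iu][kept_mask].min() >= np.sort(
        full_base.weights[iu][~kept_mask]
    )[-1]
    # min-max rescaling then maps the weakest survivor to zero
    c = build_coupling_matrix(full_base, g)
    assert np.count_nonzero(c[iu]) == 494


def test_scaling_max_entry_equals_alpha(full_base, genotype):
    c = build_coupling_matrix(full_base, genotype)
    assert np.isclose(c.max(), genotype.alpha)
    assert np.all(np.diagonal(c) == 0)
    np.testing.assert_array_equal(c, c.T)


def test_spectral_scale_mode(full_base, genotype):
    c = build_coupling_matrix(full_base, genotype, scale_mode="spectral")
    radius = np.max(np.abs(np.linalg.eigvalsh(c)))
    assert np.isclose(radius, genotype.alpha)


def test_build_reservoir_deterministic_and_w_in_bounded(full_base, genotype):
    r1 = build_reservoir(full_base, genotype, np.random.default_rng(5))
    r2 = build_reservoir(full_base, genotype, np.random.default_rng(5))
    np.testing.assert_array_equal(r1.C, r2.C)
    np.testing.assert_array_equal(r1.W_in, r2.W_in)
    assert np.max(np.abs(r1.W_in)) <= genotype.sigma


def test_too_sparse_density_rejected(small_base):
    g = Genotype(alpha=0.9, beta=5e-8, rho=0.001, sigma=0.05, theta=0.5)
    with pytest.raises(ValueError, match="no edges"):
        build_coupling_matrix(small_base, g)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def test_drive_zero_fixed_point():
    res = Reservoir(C=np.zeros((4, 4)), W_in=np.zeros((4, 3)), theta=0.0)
    states = drive(res, np.zeros((10, 3)))
    np.testing.assert_array_equal(states, np.zeros((10, 4)))


def test_drive_two_neuron_hand_value():
    """One update of the N=2 toy (C antidiagonal, no input, unit bias)
    gives r1 = h*tanh(1) in both neurons."""
    res = Reservoir(
        C=np.array([[0.0, 1.0], [1.0, 0.0]]), W_in=np.zeros((2, 3)), theta=1.0
    )
    states = drive(res, np.zeros((1, 3)))
    h = res.leak
    np.testing.assert_allclose(states[0], [h * np.tanh(1.0), h * np.tanh(1.0)])


def test_driven_states_bounded(full_base, genotype, lorenz):
    """Each update is a convex combination of the state and tanh in
    [-1, 1], so |r| never exceeds max(|r0|, 1)."""
    res = build_reservoir(full_base, genotype, np.random.default_rng(0))
    traj = generate_trajectory(lorenz, 500, np.random.default_rng(1))
    states = drive(res, traj.values, initial_state=np.full(100, 3.0))
    assert np.max(np.abs(states)) <= 3.0
    res.reset()
    states = drive(res, traj.values)
    assert np.max(np.abs(states)) <= 1.0


# ---------------------------------------------------------------------------
# readout
# ---------------------------------------------------------------------------


def test_ridge_matches_independent_oracle(rng):
    """Closed-form solution agrees with an augmented least-squares solve
    (different factorization) to 1e-8 relative."""
    t_len, n = 200, 20
    states = rng.standard_normal((t_len, n))
    inputs = rng.standard_normal((t_len + 1, 3))
    beta = 1e-3
    w = fit_readout(states, inputs, beta)
    aug_a = np.vstack([states, np.sqrt(beta) * np.eye(n)])
    aug_b = np.vstack([inputs[1:], np.zeros((n, 3))])
    w_oracle = sla.lstsq(aug_a, aug_b)[0].T
    np.testing.assert_allclose(w, w_oracle, rtol=1e-8, atol=1e-10)


def test_ridge_shrinkage_limit(rng):
    states = rng.standard_normal((300, 10))
    inputs = rng.standard_normal((301, 3))
    w = fit_readout(states, inputs, 1e6)
    assert np.linalg.norm(w) < 1e-2


def test_ridge_exact_interpolation_when_linear(rng):
    states = rng.standard_normal((500, 8))
    w_true = rng.standard_normal((3, 8))
    inputs = np.vstack([np.zeros(3), states @ w_true.T])
    w = fit_readout(states, inputs, 1e-12)
    resid = states @ w.T - inputs[1:]
    assert np.max(np.abs(resid)) < 1e-8


def test_ridge_shape_contract(rng):
    with pytest.raises(ValueError, match="one more input row"):
        fit_readout(rng.standard_normal((10, 4)), rng.standard_normal((10, 3)), 1e-8)


# ---------------------------------------------------------------------------
# forecast
# ---------------------------------------------------------------------------


def test_forecast_equals_drive_on_own_outputs(full_base, genotype, lorenz):
    """The autonomous loop is the drive equation with u_t = W_out r_t:
    replaying the emitted outputs through drive() reproduces the forecast
    state trajectory bit for bit."""
    rng = np.random.default_rng(2)
    res = build_reservoir(full_base, genotype, rng)
    traj = generate_trajectory(lorenz, 1600, rng)
    states = drive(res, traj.values[:-1])
    w = fit_readout(states[500:], traj.values[500:], genotype.beta)

    res.reset()
    drive(res, traj.values[:500])
    entry = res.state.copy()
    fr = forecast(res, w, 200)
    np.testing.assert_array_equal(fr.states[0], entry)
    # y_t = W_out r_t at every step (matmul recomputation differs only by
    # BLAS summation order)
    np.testing.assert_allclose(fr.forecast, fr.states @ w.T, rtol=1e-12, atol=1e-12)

    res2 = Reservoir(C=res.C, W_in=res.W_in, theta=res.theta, state=entry.copy())
    replay = drive(res2, fr.forecast[:-1])
    np.testing.assert_array_equal(replay, fr.states[1:])


def test_forecast_zero_readout_constant_zero(small_base, genotype):
    res = build_reservoir(small_base, genotype, np.random.default_rng(0))
    res.theta = 0.0
    res.reset()
    fr = forecast(res, np.zeros((3, 20)), 50)
    np.testing.assert_array_equal(fr.forecast, 0.0)
    assert fr.forecast.shape == (50, 3)
    assert fr.states.shape == (50, 20)


# ---------------------------------------------------------------------------
# readout permutation
# ---------------------------------------------------------------------------


def test_permute_readout_preserves_row_multisets(rng):
    w = rng.standard_normal((3, 50))
    p = permute_readout(w, np.random.default_rng(9))
    for i in range(3):
        np.testing.assert_array_equal(np.sort(p[i]), np.sort(w[i]))
    np.testing.assert_allclose(p.sum(axis=1), w.sum(axis=1), rtol=1e-12)
    p2 = permute_readout(w, np.random.default_rng(9))
    np.testing.assert_array_equal(p, p2)
    assert not np.array_equal(p, w)  # astronomically unlikely to be identity


# ---------------------------------------------------------------------------
# evaluation cycle
# ---------------------------------------------------------------------------


def test_evaluate_reservoir_metrics_structure(tiny_context, genotype):
    ctx = tiny_context
    summary = evaluate_reservoir(
        ctx.base,
        genotype,
        ctx.train,
        ctx.tests,
        np.random.default_rng(1),
        spin_up=ctx.spin_up,
        forecast_len=ctx.forecast_len,
    )
    n = len(ctx.tests)
    assert len(summary.trials) == n
    assert 0 <= summary.p_success <= 1 and 0 <= summary.p_emergent <= 1
    # P(S), P(E) are multiples of 1/#tests
    assert np.isclose(summary.p_success * n, round(summary.p_success * n))
    assert np.isclose(summary.p_emergent * n, round(summary.p_emergent * n))
    assert (summary.trials["success"] == (summary.trials["loss"] < 1)).all()


def test_evaluate_reservoir_deterministic(tiny_context, genotype):
    ctx = tiny_context
    kw = dict(spin_up=ctx.spin_up, forecast_len=ctx.forecast_len)
    s1 = evaluate_reservoir(
        ctx.base, genotype, ctx.train, ctx.tests, np.random.default_rng(4), **kw
    )
    s2 = evaluate_reservoir(
        ctx.base, genotype, ctx.train, ctx.tests, np.random.default_rng(4), **kw
    )
    np.testing.assert_array_equal(
        s1.trials[["loss", "psi"]].to_numpy(), s2.trials[["loss", "psi"]].to_numpy()
    )


def test_competent_configuration_beats_loss_threshold(full_base, lorenz):
    """At least one seed of a hand-picked grid configuration forecasts
    Lorenz with loss < 1 (the success criterion)."""
    g = Genotype(alpha=0.9, beta=5e-8, rho=0.05, sigma=0.05, theta=0.5)
    rng = np.random.default_rng(1)
    train = generate_trajectory(lorenz, 2500, rng)
    tests = [generate_trajectory(lorenz, 1500, rng) for _ in range(10)]
    summary = evaluate_reservoir(full_base, g, train, tests, rng)
    assert summary.trials["loss"].min() < 1.0
    assert summary.p_success > 0


# ---------------------------------------------------------------------------
# sklearn estimator surface
# ---------------------------------------------------------------------------


def test_estimator_params_clone_and_fit_predict(lorenz):
    est = EchoStateForecaster(spin_up=100, n_neurons=30, random_state=0)
    assert clone(est).get_params() == est.get_params()
    est.set_params(alpha=1.1)
    assert est.alpha == 1.1

    train = generate_trajectory(lorenz, 800, np.random.default_rng(0)).values
    test = generate_trajectory(lorenz, 400, np.random.default_rng(1)).values
    est.fit(train)
    assert est.C_.shape == (30, 30)
    assert np.max(np.abs(est.W_in_)) <= est.sigma
    assert est.W_out_.shape == (3, 30)
    assert est.spectral_radius_ > 0
    pred = est.predict(test, horizon=150)
    assert pred.shape == (150, 3)
    tr = est.forecast_trace(test, horizon=150)
    np.testing.assert_array_equal(tr.forecast, pred)
    assert np.isfinite(est.score(test))


def test_estimator_reproducible_with_random_state(lorenz):
    train = generate_trajectory(lorenz, 800, np.random.default_rng(0)).values
    test = generate_trajectory(lorenz, 400, np.random.default_rng(1)).values
    p1 = EchoStateForecaster(spin_up=100, n_neurons=20, random_state=7).fit(train)
    p2 = EchoStateForecaster(spin_up=100, n_neurons=20, random_state=7).fit(train)
    np.testing.assert_array_equal(
        p1.predict(test, horizon=50), p2.predict(test, horizon=50)
    )


def test_estimator_rejects_short_training(lorenz):
    with pytest.raises(ValueError, match="spin-up"):
        EchoStateForecaster().fit(np.zeros((100, 3)))
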