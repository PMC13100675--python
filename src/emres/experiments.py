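"""Result-generating experiment drivers.

Five orchestrations couple prediction performance to emergent dynamics:

- :func:`run_random_search`: uniform sampling of the hyperparameter grids,
  scoring each configuration's success/emergence contingency (PMI,
  sufficiency, necessity);
- :func:`run_sample_size_sweep`: one competent reservoir trained on
  truncated training windows of growing length n, tracking mean log(loss)
  and P(E) against n;
- :func:`run_readout_randomization`: paired comparison of trained versus
  row-permuted readout weights (loss and psi), showing that emergence is
  carried by the learned readout and not by autocorrelation alone;
- :func:`run_transfer_experiment`: populations evolved to maximize
  kappa*P(S) + (1-kappa)*P(E) per environment, with the fittest genotype
  re-evaluated on every environment (transfer of emergence-optimized
  solutions);
- :func:`run_topology_comparison`: sister populations (identical
  generation-0 genotypes) evolved on a connectome-like surrogate versus a
  random network, compared on final P(S) and P(E).

The statistical toolbox lives in :mod:`emres.stats` and is re-exported
here.  All drivers are deterministic end to end given a master seed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .emergence import prediction_loss, psi
from .environments import EnvironmentSpec, generate_trajectory
from .evolution import (
    EvaluationContext,
    MicrobialGA,
    SearchSpace,
    best_individual,
    clone_population,
    default_search_space,
    evolve,
    init_population,
)
from .reservoir import (
    DEFAULT_FORECAST_LEN,
    DEFAULT_SPIN_UP,
    Genotype,
    _drive_batch,
    _forecast_batch,
    build_reservoir,
    drive,
    evaluate_reservoir,
    fit_readout,
    forecast,
    permute_readout,
)
from .stats import (  # noqa: F401  (re-exported toolbox)
    ContingencySummary,
    StatResult,
    bootstrap_ci,
    contingency_summary,
    fdr_adjust,
    hedges_g,
    permutation_t_test,
    pmi,
    sign_flip_test,
    spearman_perm_test,
    sufficiency_necessity,
)
from .topologies import BaseNetwork, random_symmetric_network, surrogate_connectome

__all__ = [
    "run_random_search",
    "run_sample_size_sweep",
    "run_readout_randomization",
    "run_transfer_experiment",
    "run_topology_comparison",
    "ContingencySummary",
    "StatResult",
    "pmi",
    "sufficiency_necessity",
    "hedges_g",
    "permutation_t_test",
    "fdr_adjust",
    "bootstrap_ci",
]


def _quiet_psi(forecast_states):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return psi(forecast_states)


def run_random_search(
    env: EnvironmentSpec,
    n_configs: int,
    n_tests: int,
    base: BaseNetwork,
    rng: np.random.Generator,
    *,
    space: SearchSpace | None = None,
    train_len: int = 2500,
    spin_up: int = DEFAULT_SPIN_UP,
    forecast_len: int = DEFAULT_FORECAST_LEN,
):
    """Evaluate ``n_configs`` uniformly sampled genotypes on a shared
    train/test set.

    One training trajectory and ``n_tests`` test trajectories are generated
    once and reused for every configuration (as in the evolutionary
    protocol), so configurations differ only in their genotype and input
    weights.  Per configuration, the (S, E) flags of its trials yield P(S),
    P(E), PMI, sufficiency, and necessity; the pooled contingency over all
    trials is also returned.

    Returns
    -------
    summary : ContingencySummary
        Pooled over all configurations and trials.
    table : DataFrame
        One row per configuration: genotype, mean loss/psi, P(S), P(E),
        PMI, sufficiency, necessity (NaN where undefined).
    """
    space = space or default_search_space()
    train = generate_trajectory(env, train_len, rng)
    tests = [
        generate_trajectory(env, spin_up + forecast_len, rng) for _ in range(n_tests)
    ]
    rows = []
    all_s, all_e = [], []
    for cfg in range(n_configs):
        g = space.sample_genotype(rng)
        summary = evaluate_reservoir(
            base, g, train, tests, rng, spin_up=spin_up, forecast_len=forecast_len
        )
        s = summary.trials["success"].to_numpy()
        e = summary.trials["emergent"].to_numpy()
        all_s.append(s)
        all_e.append(e)
        cont = contingency_summary(s, e)
        row = {"config": cfg, **g.as_dict()}
        row.update(
            mean_loss=summary.mean_loss,
            mean_psi=summary.mean_psi,
            p_success=summary.p_success,
            p_emergent=summary.p_emergent,
            pmi=cont.pmi,
            sufficiency=cont.sufficiency,
            necessity=cont.necessity,
        )
        rows.append(row)
    pooled = contingency_summary(np.concatenate(all_s), np.concatenate(all_e))
    return pooled, pd.DataFrame(rows)


def run_sample_size_sweep(
    genotype: Genotype,
    env: EnvironmentSpec,
    n_grid,
    n_repeats: int,
    n_tests: int,
    rng: np.random.Generator,
    *,
    base: BaseNetwork | None = None,
    spin_up: int = DEFAULT_SPIN_UP,
    forecast_len: int = DEFAULT_FORECAST_LEN,
):
    """Train one reservoir on truncated training windows and track how loss
    and emergence scale with the training sample size n.

    A single reservoir (fixed C and W_in) is trained ``n_repeats`` times on
    fresh training trajectories; for each repeat the readout is fitted on
    the first n post-spin-up steps for every n in ``n_grid`` and evaluated
    on one fixed set of ``n_tests`` test trajectories.  Values of n < 3 are
    skipped with a warning.

    Returns a DataFrame with one row per n: mean log(loss), P(E), and mean
    loss, aggregated over repeats and test trials.
    """
    n_grid = sorted({int(n) for n in n_grid})
    usable = []
    for n in n_grid:
        if n < 3:
            warnings.warn(f"skipping n={n} < 3", UserWarning, stacklevel=2)
        else:
            usable.append(n)
    if not usable:
        raise ValueError("no usable sample sizes in n_grid")
    if base is None:
        base = random_symmetric_network(100, rng)
    res = build_reservoir(base, genotype, rng)
    tests = [
        generate_trajectory(env, spin_up + forecast_len, rng) for _ in range(n_tests)
    ]
    spin_inputs = np.stack([t.values[:spin_up] for t in tests], axis=2)
    res.reset()
    spun = _drive_batch(res, spin_inputs, np.zeros((res.n_neurons, n_tests)))
    truths = [t.values[spin_up : spin_up + forecast_len] for t in tests]

    max_n = max(usable)
    records = []
    for rep in range(n_repeats):
        train = generate_trajectory(env, spin_up + max_n + 1, rng)
        res.reset()
        states = drive(res, train.values[:-1])
        for n in usable:
            w_out = fit_readout(
                states[spin_up : spin_up + n],
                train.values[spin_up : spin_up + n + 1],
                genotype.beta,
            )
            ys, xs = _forecast_batch(res, w_out, spun.copy(), forecast_len)
            for i in range(n_tests):
                yhat = ys[:, :, i]
                loss = prediction_loss(yhat, truths[i])
                em = _quiet_psi((yhat, xs[:, :, i]))
                records.append(
                    {
                        "repeat": rep,
                        "n": n,
                        "test": i,
                        "loss": loss,
                        "psi": em.psi,
                        "emergent": bool(em.psi > 0),
                    }
                )
    per_trial = pd.DataFrame(records)
    table = (
        per_trial.groupby("n")
        .agg(
            mean_log_loss=("loss", lambda s: float(np.mean(np.log(s)))),
            p_emergent=("emergent", "mean"),
            mean_loss=("loss", "mean"),
        )
        .reset_index()
    )
    return table, per_trial


def run_readout_randomization(
    genotype: Genotype,
    env: EnvironmentSpec,
    n_repeats: int,
    rng: np.random.Generator,
    *,
    base: BaseNetwork | None = None,
    train_len: int = 2500,
    spin_up: int = DEFAULT_SPIN_UP,
    forecast_len: int = DEFAULT_FORECAST_LEN,
    n_perm: int = 10000,
):
    """Paired comparison of trained versus randomly permuted readouts.

    Per repeat, the same reservoir is trained on a fresh training
    trajectory and evaluated on a fresh test trajectory twice: once with
    the trained readout and once with a readout whose weights are permuted
    within each output row (preserving each target variable's weight
    distribution).  Paired permutation t tests (sign flips) and Hedge's g
    compare loss and psi; the two p values are FDR adjusted.

    Returns (table, stats) where ``table`` has one row per repeat and
    ``stats`` maps "loss"/"psi" to :class:`StatResult`.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    if base is None:
        base = random_symmetric_network(100, rng)
    res = build_reservoir(base, genotype, rng)
    rows = []
    for rep in range(n_repeats):
        train = generate_trajectory(env, train_len, rng)
        test = generate_trajectory(env, spin_up + forecast_len, rng)
        res.reset()
        states = drive(res, train.values[:-1])
        w_out = fit_readout(states[spin_up:], train.values[spin_up:], genotype.beta)
        w_perm = permute_readout(w_out, rng)
        truth = test.values[spin_up : spin_up + forecast_len]
        row = {"repeat": rep}
        for label, w in (("trained", w_out), ("permuted", w_perm)):
            res.reset()
            drive(res, test.values[:spin_up])
            fr = forecast(res, w, forecast_len)
            row[f"loss_{label}"] = prediction_loss(fr.forecast, truth)
            row[f"psi_{label}"] = _quiet_psi(fr).psi
        rows.append(row)
    table = pd.DataFrame(rows)
    results = {}
    pvals = {}
    for metric in ("loss", "psi"):
        a = table[f"{metric}_trained"].to_numpy()
        b = table[f"{metric}_permuted"].to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        r = permutation_t_test(a[ok], b[ok], n_perm=n_perm, paired=True, rng=rng)
        ci = bootstrap_ci(a[ok], b[ok], n_boot=min(n_perm, 10000), rng=rng)
        results[metric] = StatResult(
            g=r.g, t=r.t, p=r.p, df=r.df, ci_low=ci[0], ci_high=ci[1]
        )
        pvals[metric] = r.p
    adj = fdr_adjust([pvals["loss"], pvals["psi"]])
    for metric, p_adj in zip(("loss", "psi"), adj):
        r = results[metric]
        results[metric] = StatResult(
            g=r.g, t=r.t, p=r.p, df=r.df, p_adjusted=float(p_adj),
            ci_low=r.ci_low, ci_high=r.ci_high,
        )
    return table, results


def _evaluate_genotype_on_env(
    genotype: Genotype,
    input_direction: np.ndarray,
    env: EnvironmentSpec,
    base: BaseNetwork,
    n_tests: int,
    rng: np.random.Generator,
    *,
    train_len: int = 2500,
    spin_up: int = DEFAULT_SPIN_UP,
    forecast_len: int = DEFAULT_FORECAST_LEN,
):
    train = generate_trajectory(env, train_len, rng)
    tests = [
        generate_trajectory(env, spin_up + forecast_len, rng) for _ in range(n_tests)
    ]
    return evaluate_reservoir(
        base,
        genotype,
        train,
        tests,
        rng,
        spin_up=spin_up,
        forecast_len=forecast_len,
        input_direction=input_direction,
    )


def run_transfer_experiment(
    envs: list,
    kappa_grid,
    rng: np.random.Generator,
    *,
    n_pops: int = 10,
    pop_size: int = 100,
    generations: int = 3000,
    n_tests: int = 100,
    n_tests_eval: int = 100,
    base: BaseNetwork | None = None,
    train_len: int = 2500,
    spin_up: int = DEFAULT_SPIN_UP,
    forecast_len: int = DEFAULT_FORECAST_LEN,
) -> pd.DataFrame:
    """Evolve populations to maximize kappa*P(S) + (1-kappa)*P(E) per
    environment and evaluate each fittest genotype on every environment.

    Returns a tidy DataFrame with one row per (optimized env, kappa,
    population, evaluation env): P(S), P(E), mean loss, mean psi, plus an
    ``optimized`` flag marking the home environment.
    """
    if base is None:
        base = random_symmetric_network(100, rng)
    records = []
    for env in envs:
        for kappa in kappa_grid:
            for pop_idx in range(n_pops):
                seed = int(rng.integers(2**31))
                ga = MicrobialGA(
                    env,
                    base,
                    pop_size=pop_size,
                    generations=generations,
                    objective="kappa",
                    kappa=float(kappa),
                    n_tests=n_tests,
                    train_len=train_len,
                    spin_up=spin_up,
                    forecast_len=forecast_len,
                    seed=seed,
                )
                _, pop = ga.run()
                champ = best_individual(pop, "kappa", kappa=float(kappa))
                g = champ.genotype(pop.space)
                for eval_env in envs:
                    summary = _evaluate_genotype_on_env(
                        g,
                        champ.input_direction,
                        eval_env,
                        base,
                        n_tests_eval,
                        rng,
                        train_len=train_len,
                        spin_up=spin_up,
                        forecast_len=forecast_len,
                    )
                    records.append(
                        {
                            "opt_env": env.name,
                            "kappa": float(kappa),
                            "population": pop_idx,
                            "eval_env": eval_env.name,
                            "optimized": eval_env.name == env.name,
                            "p_success": summary.p_success,
                            "p_emergent": summary.p_emergent,
                            "mean_loss": summary.mean_loss,
                            "mean_psi": summary.mean_psi,
                        }
                    )
    return pd.DataFrame(records)


def run_topology_comparison(
    envs: list,
    rng: np.random.Generator,
    *,
    n_pops: int = 10,
    pop_size: int = 100,
    generations: int = 3000,
    n_tests: int = 100,
    n_tests_eval: int = 100,
    n_neurons: int = 100,
    train_len: int = 2500,
    spin_up: int = DEFAULT_SPIN_UP,
    forecast_len: int = DEFAULT_FORECAST_LEN,
    space: SearchSpace | None = None,
):
    """Sister-population comparison of connectome-like versus random
    reservoir topology under loss minimization.

    For each environment and population index, a surrogate-connectome
    population and a randomly connected sister population share identical
    generation-0 genotypes and input directions; both evolve under
    ``neg_loss`` on the same train/test inputs, and each final champion is
    evaluated on fresh test series.  Final champion P(S) and P(E) are
    compared across population pairs with paired permutation t tests,
    Hedge's g, and FDR adjustment.

    Returns (table, stats): one table row per (env, topology, population),
    and stats keyed by "p_success"/"p_emergent".
    """
    space = space or default_search_space()
    records = []
    for env in envs:
        for pop_idx in range(n_pops):
            bio = surrogate_connectome(n_neurons, rng=rng)
            rand = random_symmetric_network(n_neurons, rng)
            master = int(rng.integers(2**31))
            local = np.random.default_rng(master)
            train = generate_trajectory(env, train_len, local)
            tests = [
                generate_trajectory(env, spin_up + forecast_len, local)
                for _ in range(n_tests)
            ]
            ctx_bio = EvaluationContext(
                base=bio, train=train, tests=tests, spin_up=spin_up,
                forecast_len=forecast_len,
            )
            ctx_rand = EvaluationContext(
                base=rand, train=train, tests=tests, spin_up=spin_up,
                forecast_len=forecast_len,
            )
            pop_bio = init_population(
                pop_size, space, ctx_bio, local, master_seed=master
            )
            pop_rand = clone_population(pop_bio, ctx_rand)
            for name, pop, net in (
                ("surrogate", pop_bio, bio),
                ("random", pop_rand, rand),
            ):
                ga_rng = np.random.default_rng(
                    np.random.SeedSequence([master, 1 if name == "random" else 0])
                )
                evolve(pop, generations, "neg_loss", ga_rng)
                champ = best_individual(pop, "neg_loss")
                summary = _evaluate_genotype_on_env(
                    champ.genotype(space),
                    champ.input_direction,
                    env,
                    net,
                    n_tests_eval,
                    ga_rng,
                    train_len=train_len,
                    spin_up=spin_up,
                    forecast_len=forecast_len,
                )
                records.append(
                    {
                        "env": env.name,
                        "topology": name,
                        "population": pop_idx,
                        "p_success": summary.p_success,
                        "p_emergent": summary.p_emergent,
                        "mean_loss": summary.mean_loss,
                        "mean_psi": summary.mean_psi,
                    }
                )
    table = pd.DataFrame(records)
    results = {}
    pvals = []
    for metric in ("p_success", "p_emergent"):
        wide = table.pivot_table(
            index=["env", "population"], columns="topology", values=metric
        )
        r = permutation_t_test(
            wide["surrogate"].to_numpy(),
            wide["random"].to_numpy(),
            paired=True,
            rng=rng,
        )
        results[metric] = r
        pvals.append(r.p)
    adj = fdr_adjust(pvals)
    for metric, p_adj in zip(("p_success", "p_emergent"), adj):
        r = results[metric]
        results[metric] = StatResult(
            g=r.g, t=r.t, p=r.p, df=r.df, p_adjusted=float(p_adj)
        )
    return table, results
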