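"""Shared statistical toolbox: contingency measures, effect sizes,
permutation tests, bootstrap, and FDR correction.

The binary events analyzed throughout are S (prediction success, loss < 1)
and E (emergence, psi > 0).  Their coupling is summarized by pointwise
mutual information PMI(S, E) = log2 P(S,E) / (P(S) P(E)) and by graded
observational sufficiency P(S|E) and necessity 1 - P(S|not E).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencySummary",
    "StatResult",
    "contingency_summary",
    "pmi",
    "sufficiency_necessity",
    "hedges_g",
    "permutation_t_test",
    "sign_flip_test",
    "spearman_perm_test",
    "bootstrap_ci",
    "fdr_adjust",
]


@dataclass(frozen=True)
class ContingencySummary:
    """2x2 summary of the success/emergence contingency.

    Counts are ordered (SE, S~E, ~SE, ~S~E).  PMI is in bits; undefined
    quantities (empty conditioning sets, zero cells) are NaN.
    """

    counts: tuple
    p_s: float
    p_e: float
    p_se: float
    pmi: float
    sufficiency: float
    necessity: float

    @property
    def n_trials(self) -> int:
        return int(sum(self.counts))


def _flags(x) -> np.ndarray:
    return np.asarray(x, dtype=bool)


def contingency_summary(s_flags, e_flags) -> ContingencySummary:
    """Full contingency summary of paired success/emergence flags."""
    s = _flags(s_flags)
    e = _flags(e_flags)
    if s.shape != e.shape or s.ndim != 1 or len(s) < 1:
        raise ValueError("s_flags and e_flags must be equal-length 1-d arrays")
    n = len(s)
    n_se = int(np.sum(s & e))
    n_sne = int(np.sum(s & ~e))
    n_nse = int(np.sum(~s & e))
    n_nsne = int(np.sum(~s & ~e))
    p_s, p_e, p_se = np.sum(s) / n, np.sum(e) / n, n_se / n
    pmi_val = (
        float(np.log2(p_se / (p_s * p_e)))
        if p_s > 0 and p_e > 0 and p_se > 0
        else np.nan
    )
    suff = n_se / (n_se + n_nse) if (n_se + n_nse) > 0 else np.nan
    nec = 1.0 - n_sne / (n_sne + n_nsne) if (n_sne + n_nsne) > 0 else np.nan
    return ContingencySummary(
        counts=(n_se, n_sne, n_nse, n_nsne),
        p_s=float(p_s),
        p_e=float(p_e),
        p_se=float(p_se),
        pmi=pmi_val,
        sufficiency=float(suff) if np.isfinite(suff) else np.nan,
        necessity=float(nec) if np.isfinite(nec) else np.nan,
    )


def pmi(s_flags, e_flags) -> float:
    """Pointwise mutual information between S and E, in bits.

    Returns NaN (flagged sentinel) when a marginal or the joint frequency
    is zero, where the log ratio is undefined/-inf.
    """
    return contingency_summary(s_flags, e_flags).pmi


def sufficiency_necessity(s_flags, e_flags) -> tuple:
    """(P(S|E), 1 - P(S|not E)); NaN where a conditioning set is empty."""
    summary = contingency_summary(s_flags, e_flags)
    return summary.sufficiency, summary.necessity


@dataclass(frozen=True)
class StatResult:
    """Effect size with test statistic and (possibly adjusted) p value."""

    g: float
    t: float
    p: float
    df: int
    p_adjusted: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan


def hedges_g(x, y) -> float:
    """Pooled-SD standardized mean difference with the small-sample
    correction factor 1 - 3/(4 df - 1), df = n_x + n_y - 2.

    NaN if the pooled SD is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = nx + ny - 2
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df)
    if pooled == 0:
        return np.nan
    d = (x.mean() - y.mean()) / pooled
    return float(d * (1.0 - 3.0 / (4.0 * df - 1.0)))


def _t_two_sample(x, y):
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    denom = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    return (x.mean() - y.mean()) / denom if denom > 0 else 0.0, df


def _t_one_sample(d):
    n = len(d)
    sd = d.std(ddof=1)
    return (d.mean() / (sd / np.sqrt(n)) if sd > 0 else 0.0), n - 1


def permutation_t_test(
    x,
    y,
    n_perm: int = 10000,
    paired: bool = False,
    rng: np.random.Generator | None = None,
) -> StatResult:
    """Permutation-based t test with Hedge's g effect size.

    Two-sided p = (1 + #{permuted |t| >= |t_obs|}) / (n_perm + 1).  Paired
    mode computes a one-sample t on the differences and permutes signs
    within pairs; unpaired mode permutes group labels (pooled-variance t).
    Degenerate data (no variation anywhere) yields p = 1.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = hedges_g(x, y)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        d = x - y
        t_obs, df = _t_one_sample(d)
        if np.all(d == 0):
            return StatResult(g=g, t=0.0, p=1.0, df=df)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, len(d)))
        perm = signs * d
        means = perm.mean(axis=1)
        sds = perm.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.where(sds > 0, means / (sds / np.sqrt(len(d))), 0.0)
    else:
        t_obs, df = _t_two_sample(x, y)
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            return StatResult(g=g, t=0.0, p=1.0, df=df)
        nx = len(x)
        t_perm = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled)
            t_perm[i], _ = _t_two_sample(perm[:nx], perm[nx:])
    p = (1.0 + np.sum(np.abs(t_perm) >= np.abs(t_obs))) / (n_perm + 1.0)
    return StatResult(g=g, t=float(t_obs), p=float(p), df=int(df))


def sign_flip_test(
    values, n_perm: int = 10000, rng: np.random.Generator | None = None
) -> StatResult:
    """One-sample test of mean != 0 by random sign flips (two-sided)."""
    if rng is None:
        rng = np.random.default_rng()
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("need at least 2 finite values")
    t_obs, df = _t_one_sample(v)
    if np.all(v == 0):
        return StatResult(g=np.nan, t=0.0, p=1.0, df=df)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(v)))
    perm = signs * v
    means = perm.mean(axis=1)
    sds = perm.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(sds > 0, means / (sds / np.sqrt(len(v))), 0.0)
    p = (1.0 + np.sum(np.abs(t_perm) >= np.abs(t_obs))) / (n_perm + 1.0)
    g = v.mean() / v.std(ddof=1) * (1.0 - 3.0 / (4.0 * df - 1.0)) if v.std(ddof=1) else np.nan
    return StatResult(g=float(g), t=float(t_obs), p=float(p), df=int(df))


def spearman_perm_test(
    x, y, n_perm: int = 2000, rng: np.random.Generator | None = None
) -> tuple:
    """Spearman rank correlation with a permutation p value (two-sided,
    shuffling one series)."""
    from scipy.stats import rankdata

    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = rankdata(x)
    ry = rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    count = 0
    for _ in range(n_perm):
        rho = np.corrcoef(rx, rng.permutation(ry))[0, 1]
        if abs(rho) >= abs(rho_obs):
            count += 1
    return float(rho_obs), (1.0 + count) / (n_perm + 1.0)


def bootstrap_ci(
    x,
    y,
    statistic=hedges_g,
    n_boot: int = 10000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple:
    """Percentile bootstrap CI of a two-sample statistic (default Hedge's
    g), resampling each sample with replacement ``n_boot`` times."""
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    stats = np.empty(n_boot)
    for i in range(n_boot):
        xb = x[rng.integers(len(x), size=len(x))]
        yb = y[rng.integers(len(y), size=len(y))]
        stats[i] = statistic(xb, yb)
    lo, hi = np.nanpercentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped
    at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]
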