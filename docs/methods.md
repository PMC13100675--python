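# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `emres`.

## Task environments

Six three-dimensional chaotic flows serve as forecasting tasks: the Lorenz
attractor (σ = 10, ρ = 28, β = 8/3) and Sprott systems A, B, G, K, and R.
All are integrated by forward Euler with fixed step sizes h = 0.005
(Lorenz) and h = 0.05 (Sprott) — deliberately simple, first-order
integration; the test suite checks first-order consistency against a
high-accuracy Runge–Kutta reference, which is used nowhere else.

Initial conditions are drawn uniformly from a per-variable box covering
the approximate attractor extent, then burned in for a uniformly random
number of Euler steps in [1, round(1/h)] (up to one model time unit).
The boxes are not attractor basins: especially for the Sprott systems at
h = 0.05, a substantial fraction of draws escapes to infinity (up to
~85 % for Sprott G). The generator therefore discards any trajectory whose
state exceeds 10⁶ in magnitude or goes non-finite and restarts from a
fresh initial condition (bounded retries, default 100), so returned
trajectories are always finite and on-attractor. Trajectories are
bit-reproducible given (environment, seed, length).

## Reservoir model

The reservoir state r ∈ ℝ¹⁰⁰ evolves as

r_{t+1} = h·tanh(C r_t + W_in u_t + θ) + (1 − h)·r_t,  h = 0.005,

a leaky update whose convex-combination form bounds driven states by
max(|r₀|∞, 1) — reservoir dynamics cannot diverge. The leak constant h is
the same for all environments (it is a property of the reservoir, not of
the task integrator).

**Construction from a genotype (α, β, ρ, σ, θ).** Starting from a
symmetric nonnegative base network, the E = round(ρ·N(N−1)/2) largest-
weight undirected edges are kept (weak edges are the likely false
positives in tractography-derived networks); ties at the cutoff break by
(i, j) index order for determinism. Surviving weights are min–max rescaled
to [0, 1] and multiplied by α; the diagonal is zero. This follows the
construction's literal wording; because the maximum coupling weight, not
the true spectral radius, then equals α, the realized spectral radius is
recorded as a fitted diagnostic (`spectral_radius_`), and an alternative
`scale_mode="spectral"` (divide by the true spectral radius) is available.
Note the min–max rescale maps the weakest surviving edge to exactly zero,
so E−1 strictly positive couplings remain. Input weights W_in ∈ ℝ^{N×3}
are uniform on [−σ, σ]; θ is a scalar bias added to every neuron.
Environment inputs are fed in raw units (only the error in the loss is
standardized).

**Training.** After a 500-step spin-up (discarded), the readout solves
the ridge system W_out = U Rᵀ (R Rᵀ + βI)⁻¹, regressing the next input
u_{t+1} on the state r_t that has consumed inputs up to u_t. β enters as
a scalar on the diagonal. The closed form is solved by a positive-definite
factorization and cross-checked in tests against an augmented
least-squares oracle.

**Forecasting.** The trained RC is spun up on the first 500 steps of a
test trajectory and then runs closed-loop for 1,000 steps, substituting
W_out r_t for the external input. The recorded arrays satisfy
ŷ_t = W_out r_t exactly, with the first recorded state being the spun-up
entry state; replaying the emitted outputs through the open-loop drive
reproduces the forecast state trajectory bit for bit (tested).
The reservoir state is zeroed before every spin-up, making test trials
exchangeable — spin-up exists precisely to synchronize.

## Evaluation

**Loss.** loss = (1/(T·D)) Σ_t Σ_i (|ŷ_i(t) − y_i(t)|/σ_i)·e^{−t/T} with
T = 1,000, D = 3, σ_i the SD of the true trajectory's i-th variable over
the forecast window. The absolute difference is componentwise; the
exponent is e^{−t/T} (weight e⁻¹ at t = T), discounting late errors that
chaotic divergence renders uninformative. Success is loss < 1.

**ψ.** Computed at first order (k = 1) and lag τ = 1 — matching the
one-step-ahead prediction target — over each 1,000-step forecast window
separately, then averaged across test trajectories. Mutual information
uses the Gaussian (covariance-determinant) estimator in nats,
I = ½ ln(det Σ_X det Σ_Y / det Σ_[X,Y]), treating time points within a
window as samples (a stationarity assumption) and clipping each term
below at 0. The micro sum is evaluated through the Schur complement of
one joint covariance — algebraically identical to the per-neuron
definition (tested) but a single pass over N = 100 neurons. No covariance
regularization, detrending, or bias-correction subtraction is applied; a
property test keeps the estimator's bias on independent data below
0.01 nats at the window size used. Degenerate cases: a (near-)constant
forecast makes ψ undefined (NaN, warned, counted non-emergent);
zero-variance neurons contribute 0. Emergence is ψ > 0 — sufficient, not
necessary, so ψ ≤ 0 is reported as inconclusive, never inverted. P(E) is
the fraction of test trials with ψ > 0.

## Hyperparameter evolution

A microbial (steady-state tournament) GA operates on discrete grids:
α ∈ {0.1, …, 2.0} step 0.1; β ∈ {1.0, 1.5, …, 10.0}×10⁻⁸ (the grid's
printed upper endpoint is ambiguous in the protocol table; the monotone
continuation of the half-step sequence is adopted); ρ ∈ {0.01, …, 0.15}
step 0.01 (bounded by typical consensus-connectome density);
σ ∈ {0.01, …, 0.1}; θ ∈ {0.1, 0.3, …, 1.9}. Each generation draws two
distinct individuals; the loser's genes mutate with probability 0.2 (one
grid step, direction uniform where both neighbors exist, forced inward at
boundaries), then each gene is overwritten by the winner's with
probability 0.2, in that order; the winner is untouched, so best-so-far
fitness is non-decreasing under the fixed evaluation.

One training and n_test test trajectories are generated before evolution
and reused throughout, freezing evaluation noise. Each individual's
unit-scale input-direction matrix is fixed at birth and rescaled by its
current σ, so mutating σ rescales rather than resamples W_in. Evaluation
RNG streams derive from (master seed, individual id, genotype version):
metrics are cached per genotype and only the modified loser is
re-evaluated each generation, which makes 3,000-generation runs tractable
and full runs bit-reproducible.

## Experiments

- **Random search** shares one train trajectory and one test set across
  all sampled configurations (mirroring the evolution protocol), so
  configurations differ only in genotype and input weights. PMI(S, E) is
  computed per configuration across its trials (the aggregate over
  configurations is the analysis unit) and additionally pooled over all
  trials; sufficiency P(S|E) and necessity 1 − P(S|¬E) come from the same
  2×2 counts. PMI uses log base 2 (bits). Configurations with a zero
  marginal or joint cell have undefined PMI/conditionals and carry NaN.
- **Sample-size sweep** holds one reservoir (fixed C, W_in) and one test
  set fixed, refits the readout on the first n post-spin-up training
  steps for each n, and reports mean log(loss) and P(E) per n. The
  competent genotype is taken from a loss-minimizing evolution run, as in
  the source protocol.
- **Readout permutation** compares, per repeat on fresh train/test pairs,
  the trained readout against one whose weights are permuted within each
  output row (preserving per-variable weight distributions); paired
  sign-flip permutation t tests and Hedge's g quantify the loss and ψ
  differences.
- **Transfer** evolves populations under κ·P(S) + (1−κ)·P(E) per
  environment and re-evaluates each champion genotype on every
  environment (training freshly on the evaluation environment).
- **Topology comparison** evolves sister populations — identical
  generation-0 genotypes and input directions — on a connectome-like
  surrogate versus a random network, under loss minimization, and
  compares final champion P(S)/P(E) pairwise.

**Statistics.** Permutation t tests (10,000 permutations by default;
sign flips for paired/one-sample designs, label shuffles with a pooled-
variance t otherwise; p = (1 + #{|t*| ≥ |t|})/(n_perm + 1)); Hedge's g
with the small-sample factor 1 − 3/(4·df − 1); 10,000-resample percentile
bootstrap CIs on g (the bootstrap's target quantity is declared here as
an assumption); Benjamini–Hochberg FDR (via statsmodels).

## Synthetic data and what tests can show

No empirical data is required or shipped. The connectome-like surrogate
(5 contiguous modules, log-normal weights, elevated within-module scale)
emulates the modular, heavy-tailed character of group-level structural
brain networks but none of their empirical specifics — spatial embedding,
degree sequence, streamline-count distribution, hemispheric symmetry. The
topology comparison therefore tests the pipeline's paired design, not any
claim about the human connectome; the null result it mirrors (no
performance or emergence advantage of brain-like topology) makes topology
exchangeable for the other experiments, which default to random networks.
A consensus aggregation rule (entrywise subject mean; edges zero in a
strict majority of subjects removed, ties kept) is provided for users
with their own subject-level matrices, along with CSV/NPZ loading of any
100×100 (or other square) symmetric nonnegative weight matrix.

## Problem sizes

Full-scale runs (10 populations × 3,000 generations per objective and
environment; 4,000 random configurations × 100 evaluations) are
cluster-scale; the shipped test suite and acceptance script use
scaled-down versions chosen to keep each analysis in the minutes range on
one CPU while preserving the qualitative effects: populations of 30 for
300 generations with 10 test series and 500-step forecasts for the
evolutionary coupling; 300 configurations × 25 test series for the random
search; 3 repeats × 5 test series across n ∈ {10, …, 2000} for the
sample-size sweep; 30 repeats for the readout permutation. The full-scale
protocol ships as `configs/fullscale.yaml`.

## Known limitations

- ψ is a lower bound: redundancy across 100 neurons is subtracted once
  per neuron, so strongly redundant reservoirs can be emergent yet show
  ψ ≪ 0; only first-order (k = 1) emergence at τ = 1 is computed, and the
  Gaussian estimator captures only linear dependence.
- The Euler integrator is part of the task definition, not a numerical
  convenience; its trajectories differ from the true flows, especially at
  the Sprott step size.
- Min–max weight scaling means α is an upper bound on coupling weights,
  not the true spectral radius (the alternative mode is provided).
- The exact bootstrap target and the PMI log base in the source protocol
  are underdetermined; both are declared above and configurable.
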