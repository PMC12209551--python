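# Methods

## Model

`curefrail` fits the Weibull mixture cure frailty model (MCFM). Each
subject carries a latent susceptibility indicator `Y` and, if
susceptible, a latent frailty `W`:

- **Incidence.** `P(Y=1 | z) = π(z) = expit(b0 + z_u'b_u + z_p'b_p)`.
- **Latency.** Given `Y=1` and `W=w`, the hazard is
  `w · αγ t^{γ−1} · e^{x'β}` with `β = (β_u, β_p)`; there is no latency
  intercept (it is absorbed by the Weibull scale `α`).
- **Frailty.** `W ~ Gamma(mean 1, variance 1/θ)`; the identifiability
  constraint `E[W]=1` is built in. Marginally,
  `S(t|Y=1,x) = (1 + α t^γ e^{x'β}/θ)^{−θ}`.

The population survival `S_pop = 1 − π + π S(·|Y=1)` is improper: it
plateaus at the cure fraction `1 − π(z)`. Setting `θ = None` removes the
frailty and recovers the classical Weibull mixture cure model (MCM); the
model also reduces to it continuously as `θ → ∞`, and to a plain gamma
frailty model as `π → 1`. Both limits are exercised in the test suite.

Assumptions: independent right censoring (non-informative given
covariates), a Weibull baseline, gamma frailty acting multiplicatively on
the hazard of the susceptible only, and linear covariate effects on the
logit and log-hazard scales.

## Penalized EM

The complete-data log-likelihood separates into an incidence term
(logistic in `b`), a latency term (Weibull regression weighted by `w·y`),
and a frailty term (in `θ` only). The E-step posterior expectations
`p_i = E[y_i]`, `a_i = E[w_i]`, `b_i = E[log w_i]` (via the digamma
function) and `c_i = E[w_i y_i]` are closed-form; events have `p_i = 1`.

The M-step maximizes each term separately, with elastic-net penalties on
`b_p` and `β_p`:

- **Incidence:** minimize
  `−(1/n) Σ [p_i z_i'b − log(1+e^{z_i'b})] + λ[(1−α_E)/2 Σ b_{p,j}² + α_E Σ w_j |b_{p,j}|]`.
  The fractional responses `p_i` rule out off-the-shelf GLM lasso
  solvers, so the subproblem is solved in-package (below).
- **Latency:** the analogous penalized Weibull regression with
  multiplicative weight `c_i`, with `(α, γ)` optimized on the log scale.
- **Frailty:** the expected complete-data objective in `θ` has the
  strictly decreasing derivative
  `n(log θ + 1 − ψ(θ)) + Σ(b_i − a_i)`, so the update is a safeguarded
  1-D root find on the log scale, boxed to `[1e−4, 1e6]`; hitting the
  upper box sets a negligible-frailty flag instead of failing. The
  derivative is validated against numerical differentiation in the
  tests, and the returned maximizer against a dense grid search.

The whole EM is repeated `k_adaptive` times; between rounds the L1
weights are refreshed by the reciprocal rule `w_j = 1/|b̂_{p,j}|`, with
exact zeros mapped to `+∞` (hard exclusion from the next round; an
epsilon-floor variant `1/(|b̂|+10⁻⁶)` is available via
`PenaltySpec(weight_mode="epsilon")`). `k_adaptive=1` with unit weights
is the plain elastic net; multi-step re-weighting is what drives the
false-positive rate down in the high-dimensional experiments.

Because every M-step is warm-started at the current parameters and the
inner solver is monotone, each EM iteration is a generalized EM step:
the penalized observed log-likelihood trace is nondecreasing within
every adaptive round (asserted to 1e−8 in the suite) even when the inner
solver is iteration-capped for speed.

### Inner solver

The two penalized subproblems are solved by a monotone proximal-gradient
loop with Barzilai-Borwein step sizes and backtracking; soft
thresholding yields exact zeros, per-coordinate L1 weights and `+∞`
exclusions are native, and convergence is declared on the subgradient
(KKT) residual (default 1e−6). Smooth subproblems (`λ=0`) dispatch to
L-BFGS-B. For wide penalized blocks (≥100 columns) a glmnet-style
ever-active working-set wrapper optimizes only the current support plus
KKT violators and verifies the full KKT system before returning, which
is what makes cross-validation over a 1000-column block practical on one
CPU.

### Initialization and scaling

Starting values: Cox partial-likelihood estimates (lifelines) for
`β_u`, Weibull moment matching on the event times for `(α, γ)` (falling
back to `γ=1, α=1/mean` for degenerate inputs), zeros for all other
coefficients, `θ=1`. Penalized covariate blocks are standardized
internally to zero mean and unit variance (computed on the fitting
rows), which makes a single shared `λ` meaningful across columns;
coefficients are reported on the original scale, with the standardization
constants folded back into `b0` and `α`. Default controls: relative
penalized-log-likelihood tolerance 1e−6, at most 500 EM iterations, at
most 1000 inner-solver iterations — all configurable, and deliberately
reduced inside cross-validation (see below).

## GMIFS

The forward-stagewise fitter targets the observed log-likelihood
directly. Penalized coefficients are expanded into nonnegative parts;
each step increments by `ε` (default 0.01) the single part with the
steepest ascent direction of the log-likelihood, then refreshes the
low-dimensional parameters (`b0, b_u, β_u, log α, log γ` and, in the
frailty variant, `log θ`) by warm-started L-BFGS. The path stops when
the log-likelihood gain falls below a tolerance, and the returned model
is the path point with minimal AIC (`df` = nonzero penalized
coefficients + low-dimensional parameters). Selection by AIC on the
training path was chosen because the stagewise path has no natural `λ`
to cross-validate; the step size and stopping rule are configurable.
Variants: `penMCFM` (gamma frailty) and `MCM` (frailty-free), the latter
serving as the classical penalized mixture cure comparator.

## Simulator

Sampling inverts the improper population CDF: draw `u ~ U(0,1)`; if
`u ≥ π(z)` the subject is cured (infinite latent event time), else the
event time is the closed-form quantile

    F⁻¹(u) = {θ α⁻¹ e^{−x'β} ([1 − u/π(z)]^{−1/θ} − 1)}^{1/γ},

verified to 1e−10 by forward composition. Censoring is independent
exponential with **rate** `λ_c` (default 0.5; mean 2 time units) — the
generation literature this design follows leaves rate-vs-mean ambiguous,
and the rate reading reproduces the reference censoring/cure levels, so
it is the default. Cured subjects are always censored at their censoring
draw.

The default `SimulationDesign` emulates a high-dimensional omics cohort:
n=500; a single penalized block of P=1000 Gaussian covariates shared by
incidence and latency, block-diagonal correlation `ρ^{|i−j|}` within
blocks of 50 (sampled by per-block Cholesky); a 3-level categorical
incidence covariate with probabilities (0.40, 0.35, 0.25), dummy-coded
against the first level so that `(b0, b_u) = (−2, −1, 1)`; 10 standard
normal unpenalized latency covariates with `β_u ~ U[−3, 3]` redrawn per
replicate; s=20 nonzero penalized coefficients, all equal to the signal
magnitude `v ∈ {0.5, …, 2.5}`, placed deterministically at the first
index of each of the first 20 blocks (one signal per block; the
placement is configurable and reported); Weibull `(α, γ) = (1.25, 2.5)`
and frailty `θ = 0.5`. Under these defaults the mean censoring (cure)
rates are ≈85% (76%) at `v=0.5` and ≈63% (57%) at `v=2.5`.

What the simulator does **not** emulate: real covariate distributions
(RNA-seq counts are non-Gaussian even after normalization), measurement
error, informative censoring, non-Weibull baselines, or signals of mixed
sign and magnitude. Passing tests therefore demonstrate correctness of
the machinery and its behaviour under the stated design, not performance
guarantees on real cohorts. The stored per-subject frailty is an
independent prior draw kept for reference; event times are generated
from the frailty-marginalized survival, so the stored values are not the
posterior frailties given the times.

## Tuning

`lambda_path` anchors the grid at
`λ_max = max_j |score_j| / (n · max(α_E, 0.001))`, where `score` is the
null-model Cox partial-likelihood score over the standardized penalized
latency columns (Breslow ties), then places 50 log-equispaced values
down to `0.01 · λ_max` — the usual convention for n < p paths.

`cross_validate` stratifies folds by the event indicator (so every
training split keeps events), warm-starts fits along each decreasing
λ path, and scores held-out folds by the cure-adjusted concordance
index, with events treated as known-uncured and all censored subjects
weighted by their estimated uncured probability — the same information
available on real data, even for simulated datasets where the truth is
known. CV fits use a looser tolerance (1e−3) and an iteration cap; the
final fit re-runs at full precision.

**λ selection rule.** The held-out concordance curve is typically flat
over the dense tail of the path: rank-based concordance barely penalizes
dozens of small noise coefficients once the strong signals are in the
model, so the raw maximizer is weakly identified and often lands on the
densest fit. The default selection therefore applies the
one-standard-error rule — the largest λ whose mean CV score is within
one SE (across folds) of the maximum — which is the standard sparse
backoff for flat CV curves; the raw maximizer remains available via
`rule="max"` and is reported alongside. Ties break toward larger λ.
AIC/BIC selection is supported but non-default, as information criteria
tend to select very few variables in this model class.

## Evaluation metrics

- `c_index_harrell`: evaluable pairs
  `I_{ij} = I[t_i<t_j, δ_i=1] + I[t_i=t_j, δ_i=1, δ_j=0]`, strict
  inequality on risk scores in the numerator (score ties contribute 0).
- `c_index_cure`: each pair weighted by the second member's cure-status
  weight — known `y_j` where available, else `π̂(z_j)`; reduces exactly
  to Harrell's C under unit weights.
- Support recovery: sensitivity / specificity / FPR of the estimated
  nonzero sets, plus the selected-model size.
- `rme_err`: `(β̂−β)'Σ(β̂−β) / (β̂*−β)'Σ(β̂*−β)` and the unweighted
  analogue, where the oracle `β̂*` is the unpenalized EM refit restricted
  to the true support (same initialization rules); the two ratios
  coincide whenever `Σ = I`.
- `pi_bias_mse`: replicate-averaged subject-mean bias and MSE of the
  estimated uncured probability.
- `prognostic_risk_score`: linear score over selected features with
  averaged coefficients, dichotomized at the median (ties to the
  low-risk group); log-rank testing of the groups is left to standard
  survival packages.

Degenerate metric cases (no evaluable pairs, zero denominators,
constant risk scores) return NaN / `None` rather than raising, so
replicate aggregation stays simple.

## Numerical choices

- All survival and incidence quantities are computed on the log scale
  (softplus / log1p forms), so linear predictors beyond ±700 stay
  finite; probabilities and survival values are clipped to
  `[1e−15, 1−1e−15]` before logs, and `p_i` to `[1e−12, 1−1e−12]` before
  the M-steps.
- `t = 0` is allowed in the survival functions (where `S=1`) but
  rejected in datasets, since the density carries a `t^{γ−1}` factor.
- Time units are caller-defined; nothing is rescaled internally.
- Subject order never affects results; all reductions are
  order-independent sums (asserted by a permutation test).
- The inverse-CDF support is `0 ≤ u < π(z)`; `u ≥ π(z)` is the cured
  region and is rejected (a printed support of `1 − π(z)` in the source
  material is inconsistent with the population CDF's range and is
  treated as a typo).

## Problem sizes in the default test run

The suite keeps the expensive checks at sizes chosen to be informative
yet quick on a single CPU: the design-rate check uses 100 replicates per
signal level (no fitting); the E-step oracle uses 20 random subjects at
2×10⁵ importance-sampling draws each; low-dimensional parameter recovery
uses 50 replicates of n=2000 with two unpenalized covariates per block
and a balanced incidence (`b0=0`, `β_u ~ U[−1,1]`) so that all parameter
blocks are well informed; high-dimensional support recovery uses the
full n=500 / P=1000 design at `v=2.5` over 10 seeds with a 16-point λ
path. The full-scale replicated method comparison (penalized EM vs both
GMIFS variants across signal levels, 20+ replicates, 50-point path)
lives in `scripts/benchmark_table1.py` and takes CPU-hours at reference
scale.

## Known limitations

- The latency baseline is parametric (Weibull); no semi-parametric
  option.
- No standard errors or post-selection inference on coefficients;
  uncertainty is assessed across simulation replicates only.
- The GMIFS path refreshes low-dimensional parameters by a capped
  quasi-Newton step per increment; with very large `ε` the AIC-selected
  point can be coarse.
- `m_step_latency` is mildly nonconvex in `(log α, log γ, β)`; the
  proximal solver guarantees monotone improvement, not a global optimum
  (warm starts across EM iterations and λ values mitigate this in
  practice).
- The penalized-Cox comparator of the benchmark is intentionally thin
  and delegates to established solvers; it is optional and not part of
  the core test gate.
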