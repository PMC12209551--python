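# curefrail

Penalized Weibull mixture cure frailty modelling for right-censored
survival data with high-dimensional covariates.

## The problem

In many clinical cohorts — notably oncology cohorts with long follow-up —
a fraction of patients is effectively *cured*: they will never experience
the event, and their survival curve plateaus. At the same time, modern
studies measure thousands of molecular features (e.g. RNA-seq gene
expression) that may drive both *whether* a patient is susceptible and
*how fast* susceptible patients progress. `curefrail` fits a mixture cure
model that separates these two questions, accounts for unobserved
individual heterogeneity through a frailty term, and performs variable
selection in both model parts when the number of covariates far exceeds
the sample size.

## The model

The population survival function is the improper mixture

    S_pop(t | x, z) = 1 − π(z) + π(z) · S(t | Y=1, x)

where `Y` indicates susceptibility. The incidence is logistic,
`π(z) = exp(z'b) / (1 + exp(z'b))` with `b = (b0, b_u, b_p)`, and the
latency is a Weibull proportional-hazards model (baseline cumulative
hazard `H0(t) = α t^γ`) with a multiplicative gamma frailty `W` of mean 1
and variance `1/θ`. Marginalizing the frailty gives the closed form

    S(t | Y=1, x) = (1 + α t^γ e^{x'β} / θ)^{−θ},   β = (β_u, β_p).

The high-dimensional blocks `b_p` and `β_p` are estimated under a
multi-step adaptive elastic-net penalty inside an EM algorithm over the
latent `(Y, W)`: the E-step has closed-form posterior expectations, and
the M-step separates into a penalized fractional-response logistic
regression, a penalized Weibull regression, and a one-dimensional frailty
update. A monotone incremental forward stagewise fitter (GMIFS) over the
observed likelihood is provided as an alternative, in both frailty
(`penMCFM`) and frailty-free (`MCM`) variants, together with the matching
data simulator, λ-path/cross-validation tuning, and the evaluation
metrics used in simulation studies (cure-adjusted concordance,
sensitivity/specificity/FPR of support recovery, relative model and
estimation error against the oracle refit, bias/MSE of the estimated
uncured probability, prognostic risk scores).

## Worked example

```python
import numpy as np
import curefrail as cf

# simulate a high-dimensional cohort: n=500 subjects, 1000 shared penalized
# covariates, 20 true signals of magnitude 2.5, ~63% censoring
design = cf.SimulationDesign(n=500, v=2.5)
data, truth = cf.simulate_dataset(design, seed=1000)

# tune the shared elastic-net penalty by 4-fold CV on the cure-adjusted
# C-index, then fit with three adaptive re-weighting rounds
lams = cf.lambda_path(data, n_lambda=16)
cv = cf.cross_validate(data, lams, alpha_grid=(1.0,), K=4, seed=0,
                       control=cf.EMControl(tol=1e-3, max_iter=15),
                       k_adaptive=2)
fit = cf.run_em(data,
                cf.PenaltySpec(lambda_enet=cv.best_lambda, alpha_enet=1.0,
                               k_adaptive=3),
                cf.EMControl(tol=1e-4, max_iter=30))

m = cf.selection_metrics(truth.beta_p, fit.params.beta_p)
print(f"lambda (1-SE) = {cv.best_lambda:.4f}")
print(f"latency support: sensitivity {m['sensitivity']:.2f}, "
      f"FPR {m['fpr']:.3f}, {m['n_selected']} selected")
```

prints

```
lambda (1-SE) = 0.0135
latency support: sensitivity 1.00, FPR 0.000, 20 selected
```

i.e. exactly the 20 true latency signals are recovered, with no false
positives among the 980 noise covariates (selection quality varies by
replicate; across seeds this pipeline averages ≈0.86 sensitivity at
≈0.03 FPR). A command-line interface exposes the same pipeline
(`curefrail simulate | fit | cv | evaluate | benchmark`).

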