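# iepfit

Maximum-likelihood and Bayesian estimation for the two-parameter
**inverse exponential power (IEP) distribution**, a flexible lifetime
model for strictly positive data with inverted-bathtub or J-shaped
hazards — built for, and bundled with, COVID-19 case-fatality-rate (CFR)
data by WHO region and OECD membership.

The IEP(α, λ) distribution has cdf and density

    F(x) = exp(1 − exp((λ/x)^α)),
    f(x) = (α/λ)(λ/x)^(α+1) exp((λ/x)^α) exp(1 − exp((λ/x)^α)),   x > 0,

with power exponent α > 0 and scale λ > 0. The package provides:

* the distribution itself (pdf/cdf/survival/hazard, closed-form quantile,
  exact inverse-transform sampling), evaluated through overflow-safe
  log-space forms;
* Newton–Raphson maximum likelihood with analytic score/Hessian, the
  observed Fisher information, Wald intervals, and percentile parametric-
  bootstrap intervals;
* Bayes estimators under squared-error loss with independent Gamma
  priors, via Lindley's approximation (analytic third-order partials),
  the Tierney–Kadane Laplace approximation, and random-walk
  Metropolis–Hastings — plus a 2-D quadrature posterior-mean oracle used
  to cross-check all three;
* a reproducible Monte Carlo harness for bias/MSE and interval-coverage
  studies;
* Kolmogorov–Smirnov goodness of fit (exact small-n or asymptotic
  p-values) and ECDF utilities;
* the seven regional CFR datasets as packaged plain-text fixtures.

It is aimed at statisticians and epidemiologists fitting parametric
models to positive rate/lifetime data and at anyone comparing
Bayesian-approximation schemes against MCMC and brute-force quadrature.

## Worked example

Fit the African-region CFR sample (42 countries, values in percent) and
test the fit:

```sh
$ iepfit gof --region AFR
# source=AFR
# n=42
# version=1.0.0
# ks_method=exact
alpha   lam     ks_statistic    p_value
0.9993  0.6609  0.1810  0.1122
```

The MLE is α̂ = 0.9993, λ̂ = 0.6609: with α ≈ 1 the fitted model is close
to an inverse-exponential-type law with scale ~0.66 percentage points.
The K-S distance between the empirical and fitted cdfs is D = 0.1810
with exact p = 0.112 at n = 42, so the IEP fit is not rejected at the 5%
level. All four estimators with 95% Wald intervals:

```sh
$ iepfit fit --region AFR --method all --ci wald --seed 1
# source=AFR
# n=42
# seed=1
# version=1.0.0
# prior=1,2,2,1
method  alpha   lam
mle     0.999304        0.660936
lindley 0.963492        0.669208
tk      0.964509        0.669487
mcmc    0.962541        0.668289
wald_ci_alpha   0.772527        1.226081
wald_ci_lam     0.534561        0.787312
```

The three Bayes estimates agree with each other to ~0.002 and are pulled
slightly toward the prior means (0.5 for α, 2 for λ) relative to the
MLE, as expected at n = 42 under the default Gamma(1,2)/Gamma(2,1)
priors. In Python the same computation is:

```python
from iepfit import fit_mle, tk_estimates, load_region, GammaPriorPair

sample = load_region("AFR").sample
fit = fit_mle(sample)                       # alpha=0.9993, lam=0.6609
tk = tk_estimates(sample, GammaPriorPair(), fit=fit)
```

Simulation studies are one call (or one CLI invocation) each:

```python
from iepfit import IEPParams, StudyConfig, run_bias_mse_study

cfg = StudyConfig(truth=IEPParams(2, 2), n_grid=[10, 50, 100],
                  n_reps=2000, methods=("mle", "lindley", "tk"),
                  master_seed=7)
table = run_bias_mse_study(cfg)   # tidy rows: method, n, parameter,
                                  # average, bias (MAE), signed_bias, mse
```

## Layout

| Module | Contents |
| --- | --- |
| `iepfit.distribution` | IEP pdf/cdf/survival/hazard/quantile/sampling |
| `iepfit.likelihood` | log-likelihood, analytic score, 2nd/3rd partials |
| `iepfit.mle` | Newton–Raphson fit, observed information, Wald + bootstrap CIs |
| `iepfit.bayes` | Gamma priors, Lindley, Tierney–Kadane, MH sampler, quadrature oracle |
| `iepfit.simulation` | bias/MSE and coverage Monte Carlo studies |
| `iepfit.gof` | Kolmogorov–Smirnov test, ECDF / fitted-cdf curves |
| `iepfit.datasets`, `iepfit.io` | bundled CFR data, file readers |
| `iepfit.cli` | `iepfit fit / gof / simulate / data` |

See `docs/methods.md` for the estimation details, numerical choices, and
known limitations.
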