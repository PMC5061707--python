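# llsurv — log-logistic survival analysis by maximum likelihood and MCMC

`llsurv` fits the two-parameter log-logistic lifetime model to complete
(uncensored) samples of survival or remission times. It is aimed at
biostatisticians and epidemiologists modelling event times whose hazard
rises to a peak and then declines — the pattern typical of remission and
relapse data, where the Weibull's monotone hazard is too rigid.

## The model

A positive random variable X follows the log-logistic distribution
LL(α, λ) with shape α > 0 and scale λ > 0 when

```
f(x) = (α/λ)(x/λ)^(α−1) / (1 + (x/λ)^α)²,      x ≥ 0
F(x) = 1 / (1 + (x/λ)^(−α))
```

Equivalently, log X is logistic — which is why the scale λ equals the
median and why, for α > 1, the hazard h(x) = α / (x[1 + (x/λ)^(−α)])
is hump-shaped. The package provides:

- the full distribution family: pdf, CDF, survival, hazard, cumulative
  hazard, failure-rate average, conditional survival and NBU/NWU aging
  classification, quantiles, and inverse-CDF random sampling;
- **maximum likelihood**: Newton–Raphson on (log α, log λ) with analytic
  score and Hessian, the observed Fisher information, and Wald confidence
  intervals from its inverse;
- **Bayesian estimation**: Metropolis-within-Gibbs sampling of the
  posterior under independent uniform priors, with the ten standard
  numerical posterior summaries, central and highest-posterior-density
  (HPD) credible intervals;
- **convergence diagnostics**: autocorrelation, ergodic (running) means,
  the Brooks–Gelman–Rubin interval diagnostic and classic R-hat, kernel
  densities and box summaries;
- **goodness of fit**: Kolmogorov–Smirnov distance with asymptotic or
  parametric-bootstrap significance, Q–Q/P–P point sets, and overlay
  tables comparing MLE and Bayes fits.

The package embeds the classic Lee & Wang dataset of remission times
(months) for 128 bladder-cancer patients, validated at load time against
its published summary statistics.

## Worked example

```python
from llsurv import fit_mle, ks_test, load_bladder_fixture

sample = load_bladder_fixture()      # 128 remission times, months
fit = fit_mle(sample)
print(fit.params.alpha, fit.params.lam, fit.loglik)
# 1.725158  6.089826  -411.4575
print(fit.ci_alpha, fit.ci_lambda)
# (1.474430, 1.975887)  (5.034702, 7.144950)
gof = ks_test(sample, fit.params)
print(gof.ks_D, gof.ks_pvalue)
# 0.03207273  0.999
```

The shape estimate α̂ ≈ 1.73 > 1 says the relapse hazard rises and then
falls; the scale estimate λ̂ ≈ 6.09 months is the fitted median remission
time. The tiny K–S distance (with significance far above 0.05) says the
fitted CDF tracks the empirical one closely.

The Bayesian route with the same data:

```python
from llsurv import MCMCConfig, sample_posterior, summarize

chains = sample_posterior(sample, config=MCMCConfig(seed=1))
su = summarize(chains[0], "alpha")
print(su.mean, su.sd, su.hpd_interval_95)
# 1.7295  0.1286  (1.478, 1.985)
```

With a flat prior and n = 128 the posterior concentrates on the MLE, the
usual large-sample agreement between the two paradigms.

The `examples/` directory holds one short narrative script per
capability; each prints the numbers it computes and one line on what they
mean. A thin CLI mirrors the pipeline:

```
llsurv fit-mle times.csv --out report.json
llsurv fit-bayes times.csv --seed 1 --out-chains chains.csv
llsurv validate times.csv --params report.json
llsurv diagnose chains.csv
llsurv simulate --alpha 2 --lambda 5 --n 1000 --seed 7 --out sample.csv
```

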