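# Methods

## Model

The log-logistic distribution LL(α, λ) has density
f(x) = (α/λ)(x/λ)^(α−1) / (1 + (x/λ)^α)² on x ≥ 0, with shape α > 0
(dimensionless) and scale λ > 0 in the units of time. log X is logistic
with location log λ and scale 1/α, so the median is exactly λ, all moments
of order ≥ α diverge, and for α > 1 the hazard is unimodal (rises to a
peak near λ(α−1)^(1/α), then decays like α/x). The package models
complete, uncensored samples of positive times only; censoring is out of
scope.

All distribution functions are evaluated in log space:
(x/λ)^α as exp(α(log x − log λ)), the CDF as a logistic sigmoid of
z = α(log x − log λ), log(1 + (x/λ)^α) via `logaddexp(0, z)`. This keeps
evaluation stable for shapes up to the order of 10², which the MCMC
explorer can visit under a wide prior. Boundary values at x = 0 are
defined by limits (pdf 0 / 1/λ / +∞ for α >, =, < 1; CDF 0; survival 1)
rather than raised, so that empirical-CDF comparisons can include the
infimum of the support.

The conditional survival is implemented as R(x + t)/R(t) — the survival
of a unit of age t over a further horizon x. The aging classifier compares
it with R(x) pointwise: smaller means "new better than used" (NBU) at that
point, larger NWU, and differences within a tolerance (default 1e-9) are
labelled exponential-like, since exact equality everywhere characterizes
the exponential law and is never attained by a log-logistic.

## Maximum likelihood

For x₁…xₙ the log-likelihood is
ℓ = n log α − nα log λ + (α−1)Σ log xᵢ − 2Σ log[1 + (xᵢ/λ)^α].
The score and Hessian are analytic; with sᵢ = wᵢ/(1+wᵢ), wᵢ = (xᵢ/λ)^α
and tᵢ = log(xᵢ/λ):

- ∂ℓ/∂α = n/α + Σtᵢ − 2Σ sᵢtᵢ
- ∂ℓ/∂λ = −nα/λ + (2α/λ)Σ sᵢ
- ∂²ℓ/∂α² = −n/α² − 2Σ tᵢ²sᵢ(1−sᵢ)
- ∂²ℓ/∂α∂λ = −n/λ + (2/λ)Σ sᵢ + (2α/λ)Σ tᵢsᵢ(1−sᵢ)
- ∂²ℓ/∂λ² = nα/λ² − (2α/λ²)Σ sᵢ − (2α²/λ²)Σ sᵢ(1−sᵢ)

The second derivatives are cross-checked against finite differences in
the test suite. Optimization is Newton–Raphson on θ = (log α, log λ) —
the log parameterization keeps iterates in the domain — with step-halving
on ℓ and a gradient-ascent fallback whenever the transformed Hessian is
not usable; if Newton fails to converge, a Nelder–Mead polish is run
before the result is flagged unconverged. Starting values: λ₀ = sample
median (the LL median is λ) and α₀ = π/(√3 · sd(log x)), the
moment-matching value implied by the logistic distribution of log X.
Convergence is declared when the sup-norm of the score drops below 1e-8,
with a cap of 200 iterations. Degenerate inputs (all times equal, n < 3)
are rejected.

Inference is the standard observed-information route: O(δ̂) = −H(δ̂),
vcov = O⁻¹, SEs the square roots of its diagonal, and 1−γ Wald intervals
δ̂ ± z_{γ/2}·SE. The observed information and the variance–covariance
matrix are distinct, correctly-labelled fields of the result: one is the
negated Hessian, the other its inverse, and the test suite checks their
product against the identity. (Published tables in this literature
occasionally print the information matrix under a covariance heading; the
self-consistency check — the inverse reproducing the standard errors —
resolves which is which.)

## Bayesian estimation

Priors are independent uniforms on a box, default (1e-4, 100) for both
parameters: wide enough to be effectively flat over the likelihood mass
for data on the scale of months while keeping the posterior proper. The
unnormalized log posterior is the log-likelihood inside the box and −∞
outside.

The sampler is Metropolis-within-Gibbs: each iteration updates α, then λ,
with a Gaussian random-walk proposal on the natural scale; proposals
outside the prior box are rejected outright. During burn-in only, each
proposal scale is multiplied or divided by 1.1 every 100 iterations to
steer the per-coordinate acceptance rate toward 0.44 (the scalar
random-walk optimum); the scales are frozen afterwards so the retained
chain satisfies detailed balance. Chain c uses `default_rng(seed + c)` and
starts from the moment-based initial point jittered by a log-normal factor
(sd 0.15), giving overdispersed starts for the convergence diagnostics.
Identical seeds give bit-identical chains. A chain whose post-burn-in
acceptance is exactly zero raises an error; a chain that never moves
(e.g. a zero proposal scale) is flagged `stuck` with a warning.

The default run design is 2 chains × 40,000 iterations, burn-in 5,000,
thinning 5, hence exactly 7,000 retained draws per chain. Chain 1 drives
numerical summaries, chain 2 visual ones; both enter the BGR diagnostic.

Posterior summaries per parameter and chain: mean, SD, naive SE,
time-series SE, minimum, P2.5, Q1, median, Q3, P97.5, maximum, the central
95% interval (P2.5, P97.5), and the 95% HPD interval by the Chen–Shao
empirical-shortest-window construction (narrowest (x₍ⱼ₎, x₍ⱼ₊ₘ₎) over
windows of m = ⌊level·N⌋ consecutive order statistics, smallest j on
ties). Quantile-type summaries use the retained (thinned) draws. The
naive SE divides the SD by √N with N the post-burn-in, *pre-thinning*
count by default: published tables computed with standard MCMC
post-processors follow this convention (SD/√35,000 reproduces their naive
SE, whereas the 7,000 retained draws would not), and the retained-count
convention remains available via `summarize(..., naive_se_on="retained")`.
The time-series SE uses non-overlapping batch means with batch size
⌊√N⌋ on the pre-thinning series. One further published-table wrinkle is
documented rather than asserted: a chain-1 HPD upper bound for the shape
parameter that is inconsistent with the same chain's 97.5th percentile
(and with chain 2) is treated as a typo and not used as a reference value.

## Convergence diagnostics

Computed on post-burn-in, pre-thinning draws by default (consistent with
the naive-SE convention), configurable to thinned draws.

- **Autocorrelation**: standard sample ACF (overall-mean centering, lag-0
  normalization); constant chains return NaN beyond lag 0.
- **Running (ergodic) mean**: prefix means; the final entry equals the
  chain mean exactly.
- **BGR**: the interval-based Brooks–Gelman variant — for growing windows,
  the ratio of the pooled-sample 80% interval width to the mean
  within-chain width — plus the classic variance-ratio R-hat on the full
  window. Interval widths use inverted-CDF (type-1) quantiles, which are
  invariant under sample duplication, so duplicated chains give a ratio of
  exactly 1 at every window; with zero between-chain variance R-hat sits
  at its deterministic floor √((n−1)/n). Thresholds are reported, never
  enforced.
- **Kernel density**: Gaussian KDE with Silverman's bandwidth (no
  bandwidth is prescribed by convention in this setting).
- **Box summary**: (P2.5, Q1, mean, Q3, P97.5) — whiskers cover the
  central 95%.

## Goodness of fit

The K–S statistic is computed by default as D = maxᵢ |F(x₍ᵢ₎) − i/n| —
the fitted CDF against the right-continuous empirical CDF evaluated at
the order statistics. This is the convention used by the common
distribution-fitting workflows this package mirrors; the exact two-sided
supremum maxᵢ max(i/n − F(x₍ᵢ₎), F(x₍ᵢ₎) − (i−1)/n) is available as
`method="sup"` (it is slightly larger, and is the variant checked against
a brute-force grid supremum in the tests). The significance value uses
the asymptotic Kolmogorov series Q(t) = 2Σ(−1)^{k−1}e^{−2k²t²} at
t = √n·D, with **no correction for the parameters having been estimated
from the same data**. That naive usage matches standard practice in this
literature, but it makes the test conservative as a model check (fitted
parameters shrink D), so the p-value is best read descriptively; a
parametric-bootstrap option (`n_boot`) at fixed parameters is provided,
off by default. Q–Q and P–P point sets use Hazen plotting positions
(i − 0.5)/n — symmetric, conventional, and irrelevant to D.

## Synthetic data

`simulate_dataset` draws by the inverse-CDF transform
x = λ(u⁻¹ − 1)^(−1/α), u ~ U(0,1), seeded, with provenance metadata. It
emulates a complete, i.i.d. sample from a single homogeneous population —
exactly the sampling model the estimators assume. Real remission data
depart from this in ways the generator does not imitate: censoring,
covariate heterogeneity, measurement rounding (the embedded dataset is
recorded to 0.01 months) and possible dependence. Passing recovery tests
on synthetic data therefore demonstrates internal correctness of the
estimators, not robustness to those departures.

## Problem sizes and numerical choices

The test suite uses n = 5,000 synthetic samples for point-estimate
recovery, 200 replicates of n = 200 for Wald coverage (expected 90–99%
at the nominal 95%), 500 replicates of n = 128 for the conservativeness
of the naive K–S test, and short chains (8,000–12,000 iterations) wherever
full-length runs are not the point; the published-table reproduction runs
the full 2 × 40,000 design, which takes a few seconds. Monte-Carlo
assertions use seeded generators and 3-sigma-style bands throughout.
The 95% Wald z-quantile is taken from the normal distribution at full
precision (1.959964…), which reproduces published interval bounds to the
printed digits.

## Known limitations

- No censoring or truncation; the likelihood is for complete samples.
- Expected (integrated) Fisher information is not provided in closed
  form; inference uses the observed information.
- The uniform prior is a pragmatic non-informative choice; no informative
  (gamma/beta/normal) priors are implemented.
- The asymptotic K–S p-value ignores parameter estimation (see above).
- Moments of LL(α, λ) with α ≤ 2 are infinite or undefined; summary
  statistics of heavy-tailed samples should be read with that in mind.
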