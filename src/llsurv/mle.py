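"""Maximum-likelihood estimation for the log-logistic model.

For an uncensored sample x_1..x_n the log-likelihood is

    l(alpha, lam) = n log alpha - n alpha log lam + (alpha - 1) sum log x_i
                    - 2 sum log[1 + (x_i/lam)^alpha].

The maximizer is found by Newton-Raphson on (log alpha, log lam) with
analytic first and second derivatives and a step-halving line search,
falling back to Nelder-Mead when the curvature is unusable.  Asymptotic
inference uses the observed Fisher information (negated Hessian at the MLE):
its inverse is the variance-covariance matrix, whose diagonal square roots
are the Wald standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .distributions import LLParams

__all__ = [
    "SurvivalSample",
    "MLEResult",
    "log_likelihood",
    "score",
    "observed_information",
    "fit_mle",
]


@dataclass(frozen=True)
class SurvivalSample:
    """An uncensored sample of positive survival/remission times."""

    times: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.times, dtype=float).ravel()
        if arr.size < 1:
            raise ValueError("sample must contain at least one time")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            bad = int(np.flatnonzero(~np.isfinite(arr) | (arr <= 0))[0])
            raise ValueError(
                f"all times must be positive and finite; offending entry at index {bad}: {arr[bad]}"
            )
        object.__setattr__(self, "times", arr)

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class MLEResult:
    """MLE of (alpha, lam) with asymptotic Wald inference."""

    params: LLParams
    loglik: float
    observed_info: np.ndarray  # 2x2 negated Hessian at the MLE
    vcov: np.ndarray  # observed_info^{-1}
    se_alpha: float
    se_lambda: float
    ci_alpha: tuple[float, float]
    ci_lambda: tuple[float, float]
    gamma: float  # significance level; intervals have coverage 1 - gamma
    converged: bool
    iterations: int
    info_pos_def: bool = True

    def to_dict(self) -> dict:
        """Flat JSON-serializable report."""
        return {
            "alpha": self.params.alpha,
            "lambda": self.params.lam,
            "loglik": self.loglik,
            "se_alpha": self.se_alpha,
            "se_lambda": self.se_lambda,
            "ci_alpha": list(self.ci_alpha),
            "ci_lambda": list(self.ci_lambda),
            "level": 1.0 - self.gamma,
            "observed_info": self.observed_info.tolist(),
            "vcov": self.vcov.tolist(),
            "converged": self.converged,
            "iterations": self.iterations,
        }


def _parts(p: LLParams, x: np.ndarray):
    """Shared pieces: t_i = log(x_i/lam), w_i = (x_i/lam)^alpha, s_i = w/(1+w)."""
    t = np.log(x) - math.log(p.lam)
    z = p.alpha * t
    s = 1.0 / (1.0 + np.exp(-z))  # w/(1+w)
    return t, z, s


def log_likelihood(p: LLParams, s: SurvivalSample) -> float:
    x = s.times
    n = s.n
    t, z, _ = _parts(p, x)
    return float(
        n * math.log(p.alpha)
        - n * p.alpha * math.log(p.lam)
        + (p.alpha - 1.0) * np.sum(np.log(x))
        - 2.0 * np.sum(np.logaddexp(0.0, z))
    )


def score(p: LLParams, s: SurvivalSample) -> np.ndarray:
    """Gradient (dl/dalpha, dl/dlam) of the log-likelihood."""
    x = s.times
    n = s.n
    t, _, sw = _parts(p, x)
    d_alpha = n / p.alpha + np.sum(t) - 2.0 * np.sum(sw * t)
    d_lam = -n * p.alpha / p.lam + 2.0 * p.alpha / p.lam * np.sum(sw)
    return np.array([d_alpha, d_lam])


def _hessian(p: LLParams, s: SurvivalSample) -> np.ndarray:
    """Analytic Hessian of the log-likelihood at p.

    With s_i = w_i/(1+w_i) and t_i = log(x_i/lam):
      d2l/da2   = -n/a^2 - 2 sum t^2 s(1-s)
      d2l/dadl  = -n/l + (2/l) sum s + (2a/l) sum t s(1-s)
      d2l/dl2   =  n a/l^2 - (2a/l^2) sum s - (2a^2/l^2) sum s(1-s)
    """
    x = s.times
    n = s.n
    a, l = p.alpha, p.lam
    t, _, sw = _parts(p, x)
    v = sw * (1.0 - sw)
    h_aa = -n / a**2 - 2.0 * np.sum(t * t * v)
    h_al = -n / l + 2.0 / l * np.sum(sw) + 2.0 * a / l * np.sum(t * v)
    h_ll = n * a / l**2 - 2.0 * a / l**2 * np.sum(sw) - 2.0 * a**2 / l**2 * np.sum(v)
    return np.array([[h_aa, h_al], [h_al, h_ll]])


def observed_information(p: LLParams, s: SurvivalSample) -> np.ndarray:
    """Observed Fisher information: the negated Hessian of l at ``p``.

    Symmetric by construction; positive definite at a proper interior
    maximum.  Indefiniteness is not raised here — ``fit_mle`` flags it.
    """
    return -_hessian(p, s)


def _initial_params(x: np.ndarray) -> LLParams:
    """Moment-style start: log X is logistic(log lam, 1/alpha)."""
    logx = np.log(x)
    sd = float(np.std(logx, ddof=1))
    alpha0 = math.pi / (math.sqrt(3.0) * sd) if sd > 0 else 1.0
    return LLParams(alpha=max(alpha0, 1e-3), lam=float(np.median(x)))


def fit_mle(
    s: SurvivalSample,
    level: float = 0.95,
    tol: float = 1e-8,
    max_iter: int = 200,
    init: LLParams | None = None,
) -> MLEResult:
    """Fit LL(alpha, lam) by Newton-Raphson on (log alpha, log lam).

    Parameters
    ----------
    s : SurvivalSample
        Positive, uncensored times; needs n >= 3 for a usable information
        matrix.
    level : float
        Confidence level of the Wald intervals (default 0.95).
    tol : float
        Convergence: sup-norm of the score below ``tol``.
    max_iter : int
        Newton iteration cap; on failure a Nelder-Mead polish is attempted
        before the result is flagged unconverged.
    """
    if s.n < 3:
        raise ValueError("MLE needs at least 3 observations")
    x = s.times
    if np.all(x == x[0]):
        raise ValueError("degenerate sample: all observations identical")
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must be in (0, 1)")

    p = init if init is not None else _initial_params(x)
    theta = np.array([math.log(p.alpha), math.log(p.lam)])
    ll_cur = log_likelihood(p, s)
    converged = False
    iterations = 0

    for iterations in range(1, max_iter + 1):
        g = score(p, s)
        if float(np.max(np.abs(g))) < tol:
            converged = True
            break
        H = _hessian(p, s)
        # chain rule to theta = (log alpha, log lam)
        d = np.array([p.alpha, p.lam])
        g_t = d * g
        H_t = (d[:, None] * H * d[None, :]) + np.diag(g_t)
        # Newton direction; fall back to gradient ascent if not a descent
        # direction for -l (H_t must be negative definite)
        try:
            step = np.linalg.solve(H_t, -g_t)
        except np.linalg.LinAlgError:
            step = g_t
        if float(step @ g_t) <= 0.0:
            step = g_t / max(1.0, float(np.linalg.norm(g_t)))
        # step-halving line search on l
        for _ in range(60):
            cand = theta + step
            p_cand = LLParams(math.exp(cand[0]), math.exp(cand[1]))
            ll_cand = log_likelihood(p_cand, s)
            if ll_cand > ll_cur - 1e-14:
                theta, p, ll_cur = cand, p_cand, ll_cand
                break
            step = step / 2.0
        else:  # no improving step found
            break

    if not converged:
        res = minimize(
            lambda th: -log_likelihood(LLParams(math.exp(th[0]), math.exp(th[1])), s),
            theta,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 5000},
        )
        p = LLParams(math.exp(res.x[0]), math.exp(res.x[1]))
        ll_cur = -float(res.fun)
        converged = float(np.max(np.abs(score(p, s)))) < max(tol, 1e-6)

    info = observed_information(p, s)
    eigs = np.linalg.eigvalsh(info)
    pos_def = bool(np.all(eigs > 0))
    if pos_def:
        vcov = np.linalg.inv(info)
        se = np.sqrt(np.diag(vcov))
    else:
        vcov = np.full((2, 2), np.nan)
        se = np.array([np.nan, np.nan])

    gamma = 1.0 - level
    z = float(norm.ppf(1.0 - gamma / 2.0))
    ci_a = (p.alpha - z * se[0], p.alpha + z * se[0])
    ci_l = (p.lam - z * se[1], p.lam + z * se[1])
    return MLEResult(
        params=p,
        loglik=ll_cur,
        observed_info=info,
        vcov=vcov,
        se_alpha=float(se[0]),
        se_lambda=float(se[1]),
        ci_alpha=ci_a,
        ci_lambda=ci_l,
        gamma=gamma,
        converged=converged,
        iterations=iterations,
        info_pos_def=pos_def,
    )
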