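"""Goodness of fit of a fitted log-logistic model.

Kolmogorov-Smirnov distance between the empirical and fitted CDFs with an
asymptotic significance value, Q-Q and P-P point sets, and overlay tables
comparing a maximum-likelihood fit with a Bayesian one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from .distributions import LLParams, cdf, pdf, quantile, rvs, survival
from .mle import SurvivalSample

__all__ = ["GOFResult", "ks_test", "qq_points", "pp_points", "compare_fits"]


@dataclass(frozen=True)
class GOFResult:
    ks_D: float
    ks_pvalue: float
    params: LLParams
    n: int
    method: str

    def to_dict(self) -> dict:
        return {
            "ks_D": self.ks_D,
            "ks_pvalue": self.ks_pvalue,
            "alpha": self.params.alpha,
            "lambda": self.params.lam,
            "n": self.n,
            "method": self.method,
        }


def _ks_distance(xs: np.ndarray, p: LLParams, method: str) -> float:
    n = xs.size
    F = cdf(xs, p)
    i = np.arange(1, n + 1)
    if method == "ecdf":
        # distance between the fitted CDF and the right-continuous ECDF
        # evaluated at the order statistics
        return float(np.max(np.abs(F - i / n)))
    if method == "sup":
        # exact two-sided supremum over the whole line
        return float(max(np.max(i / n - F), np.max(F - (i - 1) / n)))
    raise ValueError("method must be 'ecdf' or 'sup'")


def ks_test(
    s: SurvivalSample,
    p: LLParams,
    method: str = "ecdf",
    n_boot: int = 0,
    seed=None,
) -> GOFResult:
    """Kolmogorov-Smirnov test of the sample against a fitted LL model.

    ``method="ecdf"`` (default) measures max_i |F(x_(i)) - i/n|;
    ``method="sup"`` is the exact two-sided supremum statistic
    max_i max(i/n - F(x_(i)), F(x_(i)) - (i-1)/n).

    The p-value comes from the asymptotic Kolmogorov distribution of
    sqrt(n) * D with no correction for the parameters having been estimated
    from the same data, so it is anti-conservative as an absolute test and
    best read as a descriptive distance.  Set ``n_boot > 0`` for a
    parametric-bootstrap p-value at fixed parameters instead.
    """
    if s.n == 0:
        raise ValueError("empty sample")
    xs = np.sort(s.times)
    D = _ks_distance(xs, p, method)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_boot):
            sim = np.sort(rvs(p, s.n, rng))
            if _ks_distance(sim, p, method) >= D:
                hits += 1
            # +1/+1 correction keeps the estimate away from exactly 0
        pval = (hits + 1) / (n_boot + 1)
    else:
        pval = float(kolmogorov(np.sqrt(s.n) * D))
    return GOFResult(ks_D=D, ks_pvalue=pval, params=p, n=s.n, method=method)


def _plotting_positions(n: int) -> np.ndarray:
    """Hazen positions p_(i:n) = (i - 0.5)/n."""
    return (np.arange(1, n + 1) - 0.5) / n


def ecdf_table(s: SurvivalSample, p: LLParams) -> pd.DataFrame:
    """Empirical and fitted CDF at the order statistics."""
    xs = np.sort(s.times)
    n = s.n
    return pd.DataFrame(
        {"x": xs, "ecdf": np.arange(1, n + 1) / n, "fitted_cdf": cdf(xs, p)}
    )


def qq_points(s: SurvivalSample, p: LLParams) -> pd.DataFrame:
    """(theoretical quantile at p_(i:n), observed order statistic) pairs."""
    xs = np.sort(s.times)
    pp = _plotting_positions(s.n)
    return pd.DataFrame({"theoretical": quantile(pp, p), "observed": xs})


def pp_points(s: SurvivalSample, p: LLParams) -> pd.DataFrame:
    """(fitted CDF at the order statistic, plotting position) pairs."""
    xs = np.sort(s.times)
    return pd.DataFrame({"fitted": cdf(xs, p), "position": _plotting_positions(s.n)})


def compare_fits(
    s: SurvivalSample,
    mle_params: LLParams,
    bayes_params: LLParams,
    grid: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Overlay tables contrasting an MLE fit with a Bayesian fit.

    Returns tidy tables: ``density`` and ``survival`` curves for both
    parameter sets on a common grid, the empirical survival (1 - ECDF) at
    the order statistics, and the Q-Q pairs under both fits.
    """
    if grid is None:
        grid = np.linspace(0.0, float(np.max(s.times)) * 1.05, 400)
    grid = np.asarray(grid, dtype=float)
    curves = pd.DataFrame(
        {
            "x": grid,
            "pdf_mle": pdf(grid, mle_params),
            "pdf_bayes": pdf(grid, bayes_params),
            "survival_mle": survival(grid, mle_params),
            "survival_bayes": survival(grid, bayes_params),
        }
    )
    xs = np.sort(s.times)
    emp = pd.DataFrame(
        {"x": xs, "empirical_survival": 1.0 - np.arange(1, s.n + 1) / s.n}
    )
    pp = _plotting_positions(s.n)
    qq = pd.DataFrame(
        {
            "observed": xs,
            "theoretical_mle": quantile(pp, mle_params),
            "theoretical_bayes": quantile(pp, bayes_params),
        }
    )
    return {"curves": curves, "empirical_survival": emp, "qq": qq}
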