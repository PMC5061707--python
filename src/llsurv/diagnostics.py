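"""MCMC convergence diagnostics.

Trace-level summaries of retained chains: sample autocorrelation, running
(ergodic) mean, the Brooks-Gelman interval-based convergence trajectory
with the classic Gelman-Rubin potential scale reduction factor, plus kernel
density and box-plot summaries.  Everything is returned as plain arrays or
tidy DataFrames so that any plotting layer can render the usual panels.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "autocorrelation",
    "running_mean",
    "bgr",
    "kernel_density",
    "boxplot_stats",
    "diagnostics_report",
]


def autocorrelation(draws: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample ACF at lags 0..max_lag.

    Overall-mean centering and lag-0 variance normalization; a constant
    chain yields NaN beyond lag 0 (correlation undefined).
    """
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the chain length")
    xc = x - x.mean()
    c0 = float(xc @ xc) / n
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    if c0 == 0.0:
        out[1:] = np.nan
        return out
    for k in range(1, max_lag + 1):
        out[k] = float(xc[:-k] @ xc[k:]) / n / c0
    return out


def running_mean(draws: np.ndarray) -> np.ndarray:
    """Ergodic mean: cumulative mean of draws up to each iteration."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty chain")
    return np.cumsum(x) / np.arange(1, x.size + 1)


def _interval_width(x: np.ndarray, level: float = 0.80) -> float:
    # inverted_cdf quantiles are invariant under sample duplication, which
    # keeps the ratio exactly 1 for identical chains
    lo, hi = np.quantile(x, [(1 - level) / 2, (1 + level) / 2], method="inverted_cdf")
    return float(hi - lo)


def _psrf(chains: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    chains: (m, n) array of m parallel chains.
    """
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    B_over_n = float(np.var(means, ddof=1))  # = B/n
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else math.inf
    var_hat = (n - 1) / n * W + B_over_n
    return math.sqrt(var_hat / W)


def bgr(chains, n_windows: int = 20, level: float = 0.80):
    """Brooks-Gelman-Rubin diagnostic over growing windows.

    For each window end (first k draws of every chain) the interval-based
    ratio is the width of the pooled-sample ``level`` interval divided by
    the mean within-chain ``level`` interval width; a ratio settling at 1
    indicates the chains have mixed.  Returns a DataFrame with columns
    ``window_end``, ``pooled_width``, ``within_width``, ``ratio`` and the
    classic variance-ratio R-hat on the final (full) window.
    """
    arr = np.asarray([np.asarray(c, dtype=float).ravel() for c in chains])
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("bgr needs at least 2 chains of equal length")
    m, n = arr.shape
    ends = np.unique(np.linspace(max(10, n // n_windows), n, n_windows, dtype=int))
    rows = []
    for e in ends:
        seg = arr[:, :e]
        pooled = _interval_width(seg.ravel(), level)
        within = float(np.mean([_interval_width(seg[j], level) for j in range(m)]))
        ratio = pooled / within if within > 0 else (1.0 if pooled == 0 else math.inf)
        rows.append((int(e), pooled, within, ratio))
    traj = pd.DataFrame(rows, columns=["window_end", "pooled_width", "within_width", "ratio"])
    return traj, _psrf(arr)


def kernel_density(draws: np.ndarray, grid: np.ndarray | None = None) -> pd.DataFrame:
    """Gaussian-kernel density estimate (Silverman bandwidth) on a grid."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 draws for a density estimate")
    kde = gaussian_kde(x, bw_method="silverman")
    if grid is None:
        pad = 3.0 * x.std()
        grid = np.linspace(x.min() - pad, x.max() + pad, 512)
    grid = np.asarray(grid, dtype=float)
    return pd.DataFrame({"value": grid, "density": kde(grid)})


def boxplot_stats(draws: np.ndarray) -> dict:
    """Box summary with 95%-coverage whiskers: (P2.5, Q1, mean, Q3, P97.5)."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 draws")
    p2_5, q1, q3, p97_5 = np.quantile(x, [0.025, 0.25, 0.75, 0.975])
    return {
        "p2_5": float(p2_5),
        "q1": float(q1),
        "mean": float(x.mean()),
        "q3": float(q3),
        "p97_5": float(p97_5),
    }


def diagnostics_report(chains, param: str = "alpha", max_lag: int = 40,
                       thinned: bool = False) -> dict:
    """Bundle of all per-parameter diagnostics for a list of ChainDraws.

    By default the diagnostics run on the post-burn-in, pre-thinning draws.
    Returns a dict of tidy tables keyed by diagnostic name.
    """
    series = [c.param(param, thinned=thinned) for c in chains]
    acf_tab = pd.DataFrame(
        {
            "lag": np.arange(max_lag + 1),
            **{f"chain_{c.chain_id}": autocorrelation(s, max_lag)
               for c, s in zip(chains, series)},
        }
    )
    rm_tab = pd.DataFrame(
        {
            "iteration": np.arange(1, len(series[0]) + 1),
            **{f"chain_{c.chain_id}": running_mean(s)
               for c, s in zip(chains, series)},
        }
    )
    out = {"acf": acf_tab, "running_mean": rm_tab}
    if len(series) >= 2:
        traj, rhat = bgr(series)
        out["bgr_trajectory"] = traj
        out["rhat_final"] = rhat
    out["density"] = kernel_density(series[-1])
    out["boxplot"] = boxplot_stats(series[-1])
    return out
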