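"""MCMC convergence diagnostics: Gelman--Rubin PSRF and effective sample size.

The PSRF follows the classic between/within-chain variance comparison with
the 95% upper confidence bound obtained from the F-quantile of the
between-to-within variance ratio (the construction used by coda's
``gelman.diag``), applied to split chains (each chain halved) so that
within-chain trends inflate the statistic.  ESS delegates to arviz's
autocorrelation-based bulk estimator.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import f as f_dist

__all__ = ["psrf", "ess"]


def _as_chains(chains) -> np.ndarray:
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D array (n_chains, n_draws)")
    return arr


def _split(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[1] // 2
    return np.concatenate([arr[:, :n], arr[:, n : 2 * n]], axis=0)


def psrf(chains) -> dict:
    """Split-chain potential scale reduction factor with its 95% upper bound.

    Parameters
    ----------
    chains
        Array-like of shape (n_chains, n_draws) for one scalar parameter;
        at least two chains of equal length.

    Returns
    -------
    dict with keys ``point`` and ``upper95``.
    """
    arr = _as_chains(chains)
    if arr.shape[0] < 2:
        raise ValueError("psrf needs at least two chains")
    x = _split(arr)
    m, n = x.shape
    if n < 4:
        raise ValueError("chains too short for a split-chain PSRF")
    means = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    W = s2.mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        return {"point": 1.0, "upper95": 1.0}  # all chains constant and equal
    muhat = x.mean()
    var_w = s2.var(ddof=1) / m
    var_b = 2.0 * B**2 / (m - 1)
    cov_wb = (n / m) * (
        np.cov(s2, means**2, ddof=1)[0, 1] - 2.0 * muhat * np.cov(s2, means, ddof=1)[0, 1]
    )
    V = (n - 1) / n * W + (1.0 + 1.0 / m) * B / n
    var_V = ((n - 1) ** 2 * var_w + (1 + 1 / m) ** 2 * var_b + 2 * (n - 1) * (1 + 1 / m) * cov_wb) / n**2
    df_V = 2.0 * V**2 / var_V if var_V > 0 else np.inf
    df_adj = (df_V + 3.0) / (df_V + 1.0)
    b_df = m - 1
    w_df = 2.0 * W**2 / (s2.var(ddof=1) / m) if s2.var(ddof=1) > 0 else np.inf
    r2_fixed = (n - 1.0) / n
    r2_random = (1.0 + 1.0 / m) / n * (B / W)
    point = np.sqrt(df_adj * (r2_fixed + r2_random))
    upper = np.sqrt(df_adj * (r2_fixed + f_dist.ppf(0.975, b_df, w_df) * r2_random))
    return {"point": float(point), "upper95": float(upper)}


def ess(chains) -> float:
    """Autocorrelation-based effective sample size across chains (arviz bulk ESS)."""
    arr = _as_chains(chains)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        return float(az.ess(arr))
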