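"""Posterior summaries: sign probabilities, one-sided bounds, partial
correlations, smoothed-trend tables, residual diagnostics, and densities.

These operations turn pooled MCMC draws into the tables an analyst reads:
for every pair of series, the posterior probability that a correlation is
positive (the fraction of draws above zero) and the lower bound of a
one-sided 95% credible interval (the 5% empirical quantile).  Partial
correlations come from the negated, normalized inverse of each covariance
draw and measure conditional (given all other series) co-movement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import gammaln, hyp1f1
from scipy.stats import gaussian_kde

from .kalman import ObservedSeries
from .model import ModelSpec

__all__ = [
    "CorrelationSummaryTable",
    "prob_positive",
    "one_sided_lower",
    "empirical_quantile",
    "partial_correlations",
    "correlation_summary",
    "smoothed_series",
    "residuals",
    "energy_normality_test",
    "raw_correlations",
    "density_summary",
]


def prob_positive(samples) -> float:
    """Fraction of draws strictly greater than zero."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    return float(np.mean(x > 0))


def empirical_quantile(samples, q: float) -> float:
    """Order-statistic quantile: the ceil(q*K)-th smallest of K draws."""
    x = np.sort(np.asarray(samples, dtype=float))
    # tolerance guards against float noise in q*K (e.g. 0.05*100 -> 5.0000000004)
    k = int(np.ceil(q * x.size - 1e-9))
    return float(x[max(k, 1) - 1])


def one_sided_lower(samples, level: float = 0.95) -> float:
    """Lower bound of the one-sided credible interval: the (1-level) empirical quantile."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    return empirical_quantile(x, 1.0 - level)


def partial_correlations(cov: np.ndarray) -> np.ndarray:
    """Partial correlation matrix -P_ij / sqrt(P_ii P_jj) from P = cov^-1."""
    cov = np.asarray(cov, dtype=float)
    sign, _ = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance matrix must be positive definite")
    P = np.linalg.inv(cov)
    d = np.sqrt(np.diag(P))
    out = -P / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


@dataclass
class CorrelationSummaryTable:
    """Square table: P(rho_ij > 0 | Y) above the diagonal, one-sided 95%
    lower credible bounds below, diagonal empty."""

    series_names: Sequence[str]
    prob_positive: np.ndarray  # C x C, upper triangle meaningful
    lower_bound: np.ndarray  # C x C, lower triangle meaningful
    kind: str

    def to_frame(self) -> pd.DataFrame:
        """Mixed layout mirroring the published presentation."""
        C = len(self.series_names)
        out = pd.DataFrame("", index=self.series_names, columns=self.series_names, dtype=object)
        for i in range(C):
            for j in range(C):
                if i < j:
                    out.iat[i, j] = round(float(self.prob_positive[i, j]), 4)
                elif i > j:
                    out.iat[i, j] = round(float(self.lower_bound[i, j]), 4)
                else:
                    out.iat[i, j] = "-"
        return out

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        C = len(self.series_names)
        for i in range(C):
            for j in range(i + 1, C):
                rows.append(
                    {
                        "series_i": self.series_names[i],
                        "series_j": self.series_names[j],
                        "kind": self.kind,
                        "prob_positive": self.prob_positive[i, j],
                        "lower95_one_sided": self.lower_bound[j, i],
                    }
                )
        return pd.DataFrame(rows)


def correlation_summary(posterior, kind: str) -> CorrelationSummaryTable:
    """Elementwise sign probabilities and one-sided bounds over pooled chains.

    ``kind`` is ``evolution`` (slope-innovation correlations), ``error``
    (observation-error correlations) or ``partial-evolution`` (each pooled
    Sigma_delta~ draw mapped through :func:`partial_correlations` first).
    """
    if kind in ("evolution", "error"):
        mats = posterior.corr_draws(kind)
    elif kind == "partial-evolution":
        covs = posterior.cov_draws("evolution")
        mats = np.empty_like(covs)
        for k in range(covs.shape[0]):
            mats[k] = partial_correlations(covs[k])
    else:
        raise ValueError(f"unknown summary kind: {kind!r}")
    names = list(posterior.series_names)
    C = len(names)
    prob = np.full((C, C), np.nan)
    low = np.full((C, C), np.nan)
    for i in range(C):
        for j in range(i + 1, C):
            draws = mats[:, i, j]
            prob[i, j] = prob_positive(draws)
            low[j, i] = one_sided_lower(draws)
    return CorrelationSummaryTable(series_names=names, prob_positive=prob, lower_bound=low, kind=kind)


def smoothed_series(
    state_draws: np.ndarray,
    spec: ModelSpec,
    scale: str = "count",
    component: str = "trend",
    months=None,
    series_names=None,
) -> pd.DataFrame:
    """Pointwise posterior mean and 95% band of the smoothed series.

    ``component='trend'`` uses the level coordinates only (the deseasonalized
    trend); ``component='fit'`` uses the full observation mean F theta.  On
    ``scale='count'`` every draw is exponentiated before the pointwise mean
    and 2.5%/97.5% quantiles are taken, so the mean is the mean of
    exponentials, not the exponential of the mean.

    ``state_draws`` is (n_draws, T+1, p) from FFBS; the initial state row is
    dropped.  Returns a long DataFrame (series, month, mean, lower95, upper95).
    """
    draws = np.asarray(state_draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[None]
    if draws.ndim != 3 or draws.shape[0] == 0:
        raise ValueError("state_draws must be a non-empty (n, T+1, p) array")
    if component == "trend":
        vals = draws[:, 1:, spec.level_idx]
    elif component == "fit":
        vals = np.einsum("ntp,cp->ntc", draws[:, 1:], spec.obs_matrix)
    else:
        raise ValueError(f"unknown component: {component!r}")
    if scale == "count":
        vals = np.exp(vals)
    elif scale != "log":
        raise ValueError(f"unknown scale: {scale!r}")
    mean = vals.mean(axis=0)
    lo = np.quantile(vals, 0.025, axis=0)
    hi = np.quantile(vals, 0.975, axis=0)
    T, C = mean.shape
    names = list(series_names) if series_names is not None else [f"series_{c}" for c in range(C)]
    month_col = list(months) if months is not None else list(range(1, T + 1))
    rows = []
    for c in range(C):
        for t in range(T):
            rows.append(
                {
                    "series": names[c],
                    "month": month_col[t],
                    "mean": mean[t, c],
                    "lower95": lo[t, c],
                    "upper95": hi[t, c],
                }
            )
    return pd.DataFrame(rows)


def residuals(data: ObservedSeries, state_draws: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Log-scale residuals: data minus the pointwise posterior mean of F theta."""
    draws = np.asarray(state_draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[None]
    fit = np.einsum("ntp,cp->ntc", draws[:, 1:], spec.obs_matrix).mean(axis=0)
    if fit.shape != data.log_counts.shape:
        raise ValueError("state draws and data have inconsistent dimensions")
    return data.log_counts - fit


def _mean_norm_to_gaussian(x: np.ndarray) -> np.ndarray:
    """E||a - Z|| for rows a of x, Z standard normal in d dimensions (closed form)."""
    d = x.shape[1]
    const = np.sqrt(2.0) * np.exp(gammaln((d + 1) / 2.0) - gammaln(d / 2.0))
    sq = np.sum(x * x, axis=1)
    return const * hyp1f1(-0.5, d / 2.0, -0.5 * sq)


def _energy_statistic(y: np.ndarray) -> float:
    """Szekely--Rizzo energy statistic for multinormality of standardized data."""
    n, d = y.shape
    e_xz = _mean_norm_to_gaussian(y).mean()
    e_zz = 2.0 * np.exp(gammaln((d + 1) / 2.0) - gammaln(d / 2.0))
    diff = y[:, None, :] - y[None, :, :]
    e_xx = np.sqrt(np.sum(diff * diff, axis=2)).sum() / (n * n)
    return float(n * (2.0 * e_xz - e_zz - e_xx))


def _standardize(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    S = np.cov(xc.T, ddof=1) if x.shape[1] > 1 else np.atleast_2d(np.var(xc, ddof=1))
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("sample covariance of residuals is singular") from exc
    return solve_triangular(L, xc.T, lower=True).T


def energy_normality_test(
    residuals: np.ndarray, n_boot: int = 500, rng: np.random.Generator | int | None = None
) -> dict:
    """Energy test of multivariate normality with a parametric bootstrap p-value.

    The input is centered and whitened by its sample covariance; the null
    distribution of the statistic is estimated from ``n_boot`` standard-normal
    datasets of the same shape, each standardized the same way.
    """
    x = np.atleast_2d(np.asarray(residuals, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    n, d = x.shape
    if n <= d:
        raise ValueError("need more observations than dimensions")
    if n_boot < 99:
        raise ValueError("n_boot must be at least 99")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))
    stat = _energy_statistic(_standardize(x))
    null = np.empty(n_boot)
    for b in range(n_boot):
        z = rng.standard_normal((n, d))
        null[b] = _energy_statistic(_standardize(z))
    p = (1.0 + np.sum(null >= stat)) / (n_boot + 1.0)
    return {"statistic": stat, "p_value": float(p)}


def raw_correlations(counts) -> pd.DataFrame:
    """Pearson correlation matrix of the raw (count-scale) monthly series."""
    df = pd.DataFrame(counts)
    if len(df) < 3:
        raise ValueError("need at least three time points")
    if (df.std(ddof=1) == 0).any():
        bad = df.columns[df.std(ddof=1) == 0].tolist()
        raise ValueError(f"constant column(s): {bad}")
    return df.corr(method="pearson")


def density_summary(samples, grid_size: int = 512) -> dict:
    """Gaussian KDE on [-1, 1] (Silverman bandwidth) plus the sample median.

    Returns ``{"grid", "density", "median"}``; the density integrates to ~1
    over the grid for samples supported inside (-1, 1).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples for a density summary")
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(-1.0, 1.0, grid_size)
    return {"grid": grid, "density": kde(grid), "median": empirical_quantile(x, 0.5)}
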