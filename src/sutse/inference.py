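"""Bayesian inference for SUTSE covariance hyperparameters.

Priors follow the weakly-informative standard for this model class:
independent half-Cauchy Ca+(0, scale) on every observation and evolution
standard deviation, and LKJ(v) on both correlation matrices (v = 1 is uniform
over valid correlation matrices).  The latent states are marginalized exactly
by the Kalman filter, so MCMC runs on the 2C + C(C-1) covariance parameters
only; state trajectories are recovered afterwards by FFBS.

The built-in sampler is an adaptive independence Metropolis--Hastings chain:
a multivariate-t proposal centred on the posterior mode (found by BFGS on the
unconstrained scale, with the inverse Hessian as initial proposal covariance),
re-estimated from the chain's own history during warm-up and frozen
afterwards, mixed with a small fraction of random-walk moves for robustness.
For the low-dimensional, near-Gaussian posteriors this model produces on the
unconstrained scale, acceptance rates are high and autocorrelation is low,
which is what the convergence gates (split-chain PSRF, ESS) require.  The
sampler contract is backend-agnostic: any correct MCMC kernel targeting
``exp(log_posterior_hyper)`` may be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln

from .kalman import NumericalSingularityError, ObservedSeries, kalman_filter, ffbs
from .model import CovParams, ModelSpec
from .transforms import ParamTransform

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "InitializationError",
    "log_half_cauchy",
    "lkj_log_density",
    "log_prior",
    "sample_prior_corr",
    "log_posterior_hyper",
    "sample_posterior",
    "sample_states",
    "dic",
]


class InitializationError(RuntimeError):
    """No finite-posterior starting point found within the retry budget."""


@dataclass(frozen=True)
class PriorSpec:
    """Hyperprior configuration.

    ``sd_scale``: half-Cauchy scale for every sigma_i and gamma_i (default 1).
    ``corr_shape``: LKJ shape v (default 1, uniform over correlation matrices).
    ``init_state_var``: kappa of the diffuse N(0, kappa I) initial-state prior.
    """

    sd_scale: float = 1.0
    corr_shape: float = 1.0
    init_state_var: float = 1e7

    def __post_init__(self):
        if self.sd_scale <= 0 or self.corr_shape <= 0 or self.init_state_var <= 0:
            raise ValueError("prior hyperparameters must be positive")


def log_half_cauchy(x, scale: float = 1.0):
    """Log density of Ca+(0, scale): 2 / (pi scale (1 + (x/scale)^2)) on x >= 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x < 0, -np.inf, np.log(2.0) - np.log(np.pi * scale) - np.log1p((x / scale) ** 2)
    )
    return out if out.ndim else float(out)


def _lkj_log_norm(d: int, v: float) -> float:
    """Log normalizing constant of the LKJ(v) density c^-1 |Omega|^(v-1) in dimension d."""
    ks = np.arange(1, d)
    log2pow = np.log(2.0) * np.sum((2.0 * v - 2.0 + d - ks) * (d - ks))
    a = v + (d - ks - 1) / 2.0
    return float(log2pow + np.sum((d - ks) * betaln(a, a)))


def lkj_log_density(omega: np.ndarray, v: float, normalized: bool = False) -> float:
    """(v-1) log|Omega|, optionally with the exact LKJ normalizing constant."""
    omega = np.asarray(omega, dtype=float)
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        raise ValueError("correlation matrix must be positive definite")
    out = (v - 1.0) * logdet
    if normalized:
        out -= _lkj_log_norm(omega.shape[0], v)
    return float(out)


def log_prior(params: CovParams, priors: PriorSpec | None = None, normalized: bool = False) -> float:
    """Joint log prior of the 2C standard deviations and the two correlation matrices."""
    priors = priors or PriorSpec()
    out = float(
        np.sum(log_half_cauchy(params.obs_sd, priors.sd_scale))
        + np.sum(log_half_cauchy(params.evo_sd, priors.sd_scale))
    )
    out += lkj_log_density(params.obs_corr, priors.corr_shape, normalized)
    out += lkj_log_density(params.evo_corr, priors.corr_shape, normalized)
    return out


def sample_prior_corr(d: int, v: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n correlation matrices from LKJ(v) by the partial-correlation vine.

    Layer-k canonical partial correlations are rescaled Beta(a_k, a_k) on
    (-1, 1) with a_k = v + (d - 1 - k)/2; in particular every marginal
    correlation is a rescaled Beta(v + (d-2)/2, v + (d-2)/2), the Beta(d/2, d/2)
    law at v = 1.
    """
    if d < 2:
        raise ValueError("dimension must be at least 2")
    if v <= 0 or n < 1:
        raise ValueError("need v > 0 and n >= 1")
    out = np.empty((n, d, d))
    for s in range(n):
        P = np.zeros((d, d))
        for k in range(1, d):  # tree level, 1-based
            a = v + (d - 1 - k) / 2.0
            P[k - 1, k:] = 2.0 * rng.beta(a, a, size=d - k) - 1.0
        R = np.eye(d)
        for i in range(d - 1):
            for j in range(i + 1, d):
                rho = P[i, j]
                for l in range(i - 1, -1, -1):
                    rho = rho * np.sqrt((1 - P[l, i] ** 2) * (1 - P[l, j] ** 2)) + P[l, i] * P[l, j]
                R[i, j] = R[j, i] = rho
        out[s] = R
    return out


def log_posterior_hyper(
    u: np.ndarray,
    data: ObservedSeries,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    transform: ParamTransform | None = None,
) -> float:
    """Unnormalized log posterior of the unconstrained covariance parameters.

    Kalman-filter log marginal likelihood (states integrated out) plus the log
    prior plus the log-Jacobian of the constraining transform.  A filter
    singularity yields -inf (a rejected MCMC state), not an exception.
    """
    priors = priors or PriorSpec()
    tr = transform or ParamTransform(spec.n_series)
    u = np.asarray(u, dtype=float)
    if u.shape != (tr.dim,):
        raise ValueError(f"expected free vector of length {tr.dim}")
    if not np.all(np.isfinite(u)):
        return -np.inf
    # extreme proposals (exp overflow, tanh saturation) are rejected as -inf;
    # suppress the intermediate numpy warnings they generate
    with np.errstate(all="ignore"):
        try:
            params = tr.constrain(u)
        except (ValueError, FloatingPointError):
            return -np.inf
        try:
            fr = kalman_filter(spec, params, data, init_mean=None, init_var=priors.init_state_var)
            lp = fr.log_marginal_likelihood + log_prior(params, priors) + tr.log_jacobian(u)
        except (NumericalSingularityError, ValueError, np.linalg.LinAlgError):
            return -np.inf
    return lp if np.isfinite(lp) else -np.inf


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 3
    n_warmup: int = 1000
    n_keep: int = 4000
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chains, self.n_warmup, self.n_keep) < 1:
            raise ValueError("chains, warmup and kept iterations must be positive")


@dataclass
class PosteriorSamples:
    """Per-chain posterior draws of the covariance parameters.

    ``chains`` holds one DataFrame per chain (equal lengths, one named column
    per parameter: sigma[...], gamma[...], rho_eps[...], rho_delta[...]).
    ``state_draws``, when attached by :func:`sample_states`, is an
    (n_draws, T+1, p) array of FFBS trajectories.
    """

    chains: list
    config: MCMCConfig
    spec: ModelSpec
    series_names: Sequence[str]
    priors: PriorSpec
    accept_rates: Sequence[float] = ()
    state_draws: np.ndarray | None = None
    _u_chains: list = field(default_factory=list, repr=False)

    def pooled(self) -> pd.DataFrame:
        return pd.concat(self.chains, ignore_index=True)

    @property
    def n_draws(self) -> int:
        return sum(len(c) for c in self.chains)

    def corr_columns(self, kind: str) -> list[str]:
        prefix = {"evolution": "rho_delta", "error": "rho_eps"}[kind]
        return [c for c in self.chains[0].columns if c.startswith(prefix)]

    def corr_draws(self, kind: str) -> np.ndarray:
        """Pooled draws of a correlation matrix as an (n, C, C) array."""
        prefix = {"evolution": "rho_delta", "error": "rho_eps"}[kind]
        pool = self.pooled()
        C = len(self.series_names)
        out = np.repeat(np.eye(C)[None], len(pool), axis=0)
        for i in range(C):
            for j in range(i + 1, C):
                col = f"{prefix}[{self.series_names[i]},{self.series_names[j]}]"
                out[:, i, j] = out[:, j, i] = pool[col].to_numpy()
        return out

    def sd_draws(self, kind: str) -> np.ndarray:
        prefix = {"evolution": "gamma", "error": "sigma"}[kind]
        pool = self.pooled()
        cols = [f"{prefix}[{nm}]" for nm in self.series_names]
        return pool[cols].to_numpy()

    def cov_draws(self, kind: str) -> np.ndarray:
        """Pooled draws of Sigma_eps ('error') or Sigma_delta~ ('evolution')."""
        sd = self.sd_draws(kind)
        return self.corr_draws(kind) * (sd[:, :, None] * sd[:, None, :])

    def params_at(self, row: int) -> CovParams:
        pool = self.pooled()
        C = len(self.series_names)
        sd = np.array([pool[f"sigma[{nm}]"].iat[row] for nm in self.series_names])
        gm = np.array([pool[f"gamma[{nm}]"].iat[row] for nm in self.series_names])

        def mat(prefix):
            M = np.eye(C)
            for i in range(C):
                for j in range(i + 1, C):
                    v = pool[f"{prefix}[{self.series_names[i]},{self.series_names[j]}]"].iat[row]
                    M[i, j] = M[j, i] = v
            return M

        return CovParams(obs_sd=sd, obs_corr=mat("rho_eps"), evo_sd=gm, evo_corr=mat("rho_delta"))

    def to_csv(self, path) -> None:
        pool = self.pooled()
        pool.insert(0, "chain", np.repeat(np.arange(len(self.chains)), [len(c) for c in self.chains]))
        pool.insert(1, "draw", np.concatenate([np.arange(len(c)) for c in self.chains]))
        pool.to_csv(path, index=False)


class _TProposal:
    """Multivariate-t independence proposal."""

    def __init__(self, mu: np.ndarray, cov: np.ndarray, df: float = 6.0):
        self.mu = np.asarray(mu, dtype=float)
        self.df = float(df)
        cov = 0.5 * (cov + cov.T)
        w, V = np.linalg.eigh(cov)
        w = np.clip(w, max(w.max(), 1e-12) * 1e-10, None)
        self.L = V * np.sqrt(w)
        self.d = len(mu)
        self._logdet = float(np.sum(np.log(w)))
        self._Vinv_sqrt = V / np.sqrt(w)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.d)
        g = rng.chisquare(self.df)
        return self.mu + (self.L @ z) * np.sqrt(self.df / g)

    def logpdf(self, x: np.ndarray) -> float:
        y = (x - self.mu) @ self._Vinv_sqrt
        q = y @ y
        d, df = self.d, self.df
        return float(
            gammaln((df + d) / 2)
            - gammaln(df / 2)
            - 0.5 * d * np.log(df * np.pi)
            - 0.5 * self._logdet
            - 0.5 * (df + d) * np.log1p(q / df)
        )


class _MixProposal:
    """Two-component mixture of independence proposals (adapted + mode-Hessian).

    Keeping a fixed mass on the mode-Hessian component bounds the damage a
    poorly adapted component can do to the acceptance rate.
    """

    def __init__(self, main: _TProposal, base: _TProposal, w_main: float = 0.75):
        self.main, self.base, self.w = main, base, w_main

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return self.main.sample(rng) if rng.random() < self.w else self.base.sample(rng)

    def logpdf(self, x: np.ndarray) -> float:
        a = np.log(self.w) + self.main.logpdf(x)
        b = np.log1p(-self.w) + self.base.logpdf(x)
        hi = max(a, b)
        return hi + np.log(np.exp(a - hi) + np.exp(b - hi))


def _init_point(
    tr: ParamTransform, priors: PriorSpec, logpost, rng: np.random.Generator, max_tries: int = 100
) -> np.ndarray:
    """Starting point drawn from the priors with sds truncated to (0.001, 2)."""
    C = tr.C
    for _ in range(max_tries):
        sds = np.empty(2 * C)
        k = 0
        while k < 2 * C:
            x = abs(rng.standard_cauchy()) * priors.sd_scale
            if 0.001 < x < 2.0:
                sds[k] = x
                k += 1
        corrs = sample_prior_corr(C, priors.corr_shape, 2, rng) if C > 1 else np.ones((2, 1, 1))
        params = CovParams(obs_sd=sds[:C], obs_corr=corrs[0], evo_sd=sds[C:], evo_corr=corrs[1])
        u = tr.unconstrain(params)
        if np.isfinite(logpost(u)):
            return u
    raise InitializationError(f"no finite log posterior found in {max_tries} attempts")


def _find_mode(logpost, u0: np.ndarray, maxiter: int | None = None, hess_step: float = 1e-3):
    """Posterior mode by restarted BFGS plus a central-difference Hessian.

    The finite-difference step for BFGS gradients is kept well above the
    filter's numerical noise floor; the proposal covariance comes from an
    explicit second-difference Hessian at the mode (eigenvalue-clipped to
    keep it positive definite even when the mode is imperfect).
    """

    def neg(u):
        return -logpost(u)

    d = len(u0)
    if maxiter is None:
        # each BFGS iteration costs ~d function evaluations (numerical gradient)
        maxiter = int(np.clip(3000 // max(d, 1), 60, 300))
    opts = {"maxiter": maxiter, "gtol": 1e-4, "eps": 1e-5}
    res = minimize(neg, u0, method="BFGS", options=opts)
    res = minimize(neg, res.x, method="BFGS", options=opts)
    x = res.x
    h = hess_step
    f0 = neg(x)
    H = np.empty((d, d))
    steps = np.eye(d) * h
    for i in range(d):
        H[i, i] = (neg(x + steps[i]) - 2.0 * f0 + neg(x - steps[i])) / h**2
    for i in range(d):
        for j in range(i + 1, d):
            H[i, j] = H[j, i] = (
                neg(x + steps[i] + steps[j])
                - neg(x + steps[i] - steps[j])
                - neg(x - steps[i] + steps[j])
                + neg(x - steps[i] - steps[j])
            ) / (4.0 * h**2)
    w, V = np.linalg.eigh(0.5 * (H + H.T))
    w = np.clip(w, max(w.max(), 1e-6) * 1e-8, None)
    cov = (V / w) @ V.T
    return x, cov


def _run_chain(
    logpost,
    x0: np.ndarray,
    prop_mu: np.ndarray,
    prop_cov: np.ndarray,
    n_warmup: int,
    n_keep: int,
    rng: np.random.Generator,
    rw_prob: float = 0.02,
    t_df: float = 20.0,
):
    d = len(x0)
    base = _TProposal(prop_mu, 1.3 * prop_cov, t_df)
    prop = base
    rw_L = np.linalg.cholesky(0.5 * (prop_cov + prop_cov.T) + 1e-12 * np.eye(d))
    rw_scale = 2.38 / np.sqrt(d) * 0.5
    x = x0.copy()
    lp = logpost(x)
    if not np.isfinite(lp):
        raise InitializationError("chain started at a non-finite log posterior")
    lq = prop.logpdf(x)
    draws = np.empty((n_keep, d))
    hist = np.empty((n_warmup, d))
    accepted = 0
    seg_accepted = 0
    seg_start = 0
    checkpoints = (
        {n_warmup // 4, n_warmup // 2, (3 * n_warmup) // 4, n_warmup} if n_warmup >= 200 else set()
    )
    for i in range(n_warmup + n_keep):
        if rng.random() < rw_prob:
            xp = x + rw_scale * (rw_L @ rng.standard_normal(d))
            lpp = logpost(xp)
            if np.log(rng.random()) < lpp - lp:
                x, lp = xp, lpp
                lq = prop.logpdf(x)
                accepted += 1
                seg_accepted += 1
        else:
            xp = prop.sample(rng)
            lpp = logpost(xp)
            lqp = prop.logpdf(xp)
            if np.log(rng.random()) < (lpp - lp) + (lq - lqp):
                x, lp, lq = xp, lpp, lqp
                accepted += 1
                seg_accepted += 1
        if i < n_warmup:
            hist[i] = x
            if i + 1 in checkpoints and i + 1 >= max(50, 2 * d):
                # the final adaptation pools the whole second half of warm-up
                lo = n_warmup // 2 if i + 1 == n_warmup else seg_start
                seg = hist[lo : i + 1]
                seg_rate = seg_accepted / (i + 1 - seg_start)
                if seg_rate < 0.15:
                    # stuck: widen rather than trust a collapsed history
                    base = _TProposal(base.mu, 4.0 * (base.L @ base.L.T), t_df)
                    prop = base
                    cov = base.L @ base.L.T
                else:
                    cov = np.atleast_2d(np.cov(seg.T)) if d > 1 else np.array([[np.var(seg)]])
                    cov = 1.1 * cov + 1e-9 * np.eye(d)
                    prop = _MixProposal(_TProposal(seg.mean(axis=0), cov, t_df), base)
                lq = prop.logpdf(x)
                rw_L = np.linalg.cholesky(0.5 * (cov + cov.T) + 1e-12 * np.eye(d))
                seg_accepted, seg_start = 0, i + 1
        else:
            draws[i - n_warmup] = x
    return draws, accepted / (n_warmup + n_keep)


def _param_names(series_names: Sequence[str]) -> list[str]:
    names = [f"sigma[{nm}]" for nm in series_names] + [f"gamma[{nm}]" for nm in series_names]
    for prefix in ("rho_eps", "rho_delta"):
        for i in range(len(series_names)):
            for j in range(i + 1, len(series_names)):
                names.append(f"{prefix}[{series_names[i]},{series_names[j]}]")
    return names


def _table_from_u(u_draws: np.ndarray, tr: ParamTransform, series_names) -> pd.DataFrame:
    n = len(u_draws)
    C, m = tr.C, tr.m
    cols = np.empty((n, 2 * C + 2 * m))
    for k, u in enumerate(u_draws):
        p = tr.constrain(u)
        row = [p.obs_sd, p.evo_sd]
        tri = np.triu_indices(C, 1)
        row += [p.obs_corr[tri], p.evo_corr[tri]]
        cols[k] = np.concatenate(row)
    return pd.DataFrame(cols, columns=_param_names(series_names))


def sample_posterior(
    data: ObservedSeries,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorSamples:
    """MCMC over the covariance hyperparameters, states marginalized by the filter.

    All randomness derives from ``config.seed`` (per-chain generators are
    spawned deterministically), so repeated calls are bitwise reproducible.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    tr = ParamTransform(spec.n_series)

    def logpost(u):
        return log_posterior_hyper(u, data, spec, priors, transform=tr)

    ss = np.random.SeedSequence(config.seed)
    mode_seed, *chain_seeds = ss.spawn(config.n_chains + 1)
    mode_rng = np.random.default_rng(mode_seed)
    u_start = _init_point(tr, priors, logpost, mode_rng)
    mu, cov = _find_mode(logpost, u_start)

    chains, u_chains, rates = [], [], []
    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        x0 = _init_point(tr, priors, logpost, rng)
        draws, rate = _run_chain(logpost, x0, mu, cov, config.n_warmup, config.n_keep, rng)
        u_chains.append(draws)
        rates.append(rate)
        chains.append(_table_from_u(draws, tr, data.series_names))
    return PosteriorSamples(
        chains=chains,
        config=config,
        spec=spec,
        series_names=list(data.series_names),
        priors=priors,
        accept_rates=tuple(rates),
        _u_chains=u_chains,
    )


def sample_states(
    posterior: PosteriorSamples,
    data: ObservedSeries,
    spec: ModelSpec,
    thin: int = 1,
    rng: np.random.Generator | int | None = None,
) -> PosteriorSamples:
    """Attach one FFBS trajectory per (thinned) pooled hyperparameter draw."""
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if posterior.n_draws == 0:
        raise ValueError("posterior holds no draws")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))
    rows = range(0, posterior.n_draws, thin)
    T, p = data.n_obs, spec.state_dim
    out = np.empty((len(rows), T + 1, p))
    for k, row in enumerate(rows):
        params = posterior.params_at(row)
        fr = kalman_filter(spec, params, data, init_var=posterior.priors.init_state_var)
        out[k] = ffbs(fr, spec, params, rng).states
    posterior.state_draws = out
    return posterior


def dic(
    posterior: PosteriorSamples,
    data: ObservedSeries,
    spec: ModelSpec,
    thin: int = 1,
) -> dict:
    """Deviance information criterion with the states integrated out.

    Deviance D(Sigma) = -2 log p(Y | Sigma_eps, Sigma_delta) from the Kalman
    filter; DIC = mean deviance + p_D with p_D = mean deviance - deviance at
    the posterior mean of the covariance matrices on the natural (Sigma)
    scale.
    """
    if posterior.n_draws < 2:
        raise ValueError("need at least two posterior draws")
    rows = range(0, posterior.n_draws, thin)
    kappa = posterior.priors.init_state_var
    devs = np.empty(len(rows))
    sig_eps_sum = np.zeros((spec.n_series, spec.n_series))
    sig_del_sum = np.zeros_like(sig_eps_sum)
    for k, row in enumerate(rows):
        params = posterior.params_at(row)
        fr = kalman_filter(spec, params, data, init_var=kappa)
        devs[k] = -2.0 * fr.log_marginal_likelihood
        sig_eps_sum += params.obs_cov
        sig_del_sum += params.evo_cov
    sig_eps_bar = sig_eps_sum / len(rows)
    sig_del_bar = sig_del_sum / len(rows)

    def decompose(S):
        sd = np.sqrt(np.diag(S))
        return sd, S / np.outer(sd, sd)

    osd, ocorr = decompose(sig_eps_bar)
    esd, ecorr = decompose(sig_del_bar)
    params_bar = CovParams(obs_sd=osd, obs_corr=ocorr, evo_sd=esd, evo_corr=ecorr)
    try:
        fr_bar = kalman_filter(spec, params_bar, data, init_var=kappa)
    except NumericalSingularityError as exc:
        raise ValueError(
            f"deviance at the posterior-mean covariance is not finite: {exc}"
        ) from exc
    d_bar = float(devs.mean())
    d_hat = -2.0 * fr_bar.log_marginal_likelihood
    if not np.isfinite(d_hat):
        raise ValueError("deviance at the posterior-mean covariance is not finite")
    p_d = d_bar - d_hat
    return {"dic": d_bar + p_d, "p_d": p_d, "mean_deviance": d_bar}
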