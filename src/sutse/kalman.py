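"""Exact Gaussian filtering, smoothing, and joint-state sampling for SUTSE DLMs.

The evolution covariance Sigma_delta = R Sigma_delta~ R' is rank-deficient by
construction (noise enters only the C slope coordinates), so the backward
sampling step of FFBS is carried out on the C-dimensional slope innovations
delta~_t rather than on the p-dimensional state: given theta_{t+1}, the state
theta_t = G^{-1}(theta_{t+1} - R delta~_{t+1}) is an affine function of
delta~_{t+1}, whose conditional given (theta_{t+1}, Y_{1:t}) is a proper
C-dimensional Gaussian.  This is exact and avoids any inversion of the
singular p x p innovation covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .model import CovParams, ModelSpec

__all__ = [
    "ObservedSeries",
    "StateTrajectory",
    "FilterResult",
    "NumericalSingularityError",
    "kalman_filter",
    "smooth",
    "smooth_from_filter",
    "ffbs",
]

_LOG2PI = np.log(2.0 * np.pi)


class NumericalSingularityError(np.linalg.LinAlgError):
    """Innovation covariance not positive definite at some time index."""


@dataclass
class ObservedSeries:
    """T x C table of log monthly counts.

    ``log_counts`` may contain NaN to flag missing observations (whole rows or
    individual entries); missing entries are skipped in the filter update but
    propagate through prediction.  ``months`` are consecutive calendar month
    labels (anything pandas can parse to a monthly PeriodIndex).
    """

    log_counts: np.ndarray
    months: Sequence
    series_names: Sequence[str]

    def __post_init__(self):
        self.log_counts = np.atleast_2d(np.asarray(self.log_counts, dtype=float))
        T, C = self.log_counts.shape
        if T < 2:
            raise ValueError("need at least two time points")
        if len(self.series_names) != C:
            raise ValueError("series_names length must match column count")
        if len(self.months) != T:
            raise ValueError("months length must match row count")
        idx = pd.PeriodIndex([str(m) for m in self.months], freq="M")
        diffs = np.diff(idx.asi8)
        if len(diffs) and not np.all(diffs == 1):
            raise ValueError("months must be strictly increasing and consecutive")
        self.months = idx
        if np.any(np.isinf(self.log_counts)):
            raise ValueError("log counts must be finite (use NaN for missing)")

    @property
    def n_obs(self) -> int:
        return self.log_counts.shape[0]

    @property
    def n_series(self) -> int:
        return self.log_counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log_counts, index=self.months, columns=list(self.series_names))


@dataclass
class StateTrajectory:
    """(T+1) x p latent-state path; row 0 is theta_0."""

    states: np.ndarray
    spec: ModelSpec

    def __post_init__(self):
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[1] != self.spec.state_dim:
            raise ValueError(
                f"state rows must have length {self.spec.state_dim}, got {self.states.shape[1]}"
            )

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (time, coordinate)."""
        T1, p = self.states.shape
        labels = [f"s{c}:{r}" for c, r in self.spec.coord_labels]
        return pd.DataFrame(
            {
                "time": np.repeat(np.arange(T1), p),
                "coordinate": np.tile(labels, T1),
                "value": self.states.ravel(),
            }
        )


@dataclass
class FilterResult:
    """Per-time one-step-ahead and filtered state moments plus the log marginal likelihood."""

    predicted_mean: np.ndarray  # T x p, a_t = E[theta_t | Y_{1:t-1}]
    predicted_cov: np.ndarray  # T x p x p, R_t
    filtered_mean: np.ndarray  # T x p, m_t
    filtered_cov: np.ndarray  # T x p x p, C_t
    init_mean: np.ndarray
    init_cov: np.ndarray
    log_marginal_likelihood: float
    spec: ModelSpec = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        """Long format: time, coordinate label, filtered mean and sd."""
        T, p = self.filtered_mean.shape
        labels = [f"s{c}:{r}" for c, r in self.spec.coord_labels]
        sd = np.sqrt(np.maximum(self.filtered_cov[:, np.arange(p), np.arange(p)], 0.0))
        return pd.DataFrame(
            {
                "time": np.repeat(np.arange(1, T + 1), p),
                "coordinate": np.tile(labels, T),
                "mean": self.filtered_mean.ravel(),
                "sd": sd.ravel(),
            }
        )


def _sym(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + a.T)


try:  # compiled fast path for fully observed data; numpy path remains the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco


@_njit(cache=True)
def _chol_lower(S):
    """Cholesky with a success flag instead of an exception (small matrices)."""
    n = S.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            s = S[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return L, False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L, True


@_njit(cache=True)
def _filter_core(Y, F, G, Sd, Se, m0, C0):
    """Dense no-missing-data filter loop; returns the failing time index or -1."""
    T, C = Y.shape
    p = G.shape[0]
    a = np.empty((T, p))
    Rc = np.empty((T, p, p))
    fm = np.empty((T, p))
    fc = np.empty((T, p, p))
    Ip = np.eye(p)
    m = m0.copy()
    Cm = C0.copy()
    ll = 0.0
    for t in range(T):
        am = G @ m
        Rt = G @ Cm @ G.T + Sd
        Rt = 0.5 * (Rt + Rt.T)
        a[t] = am
        Rc[t] = Rt
        S = F @ Rt @ F.T + Se
        S = 0.5 * (S + S.T)
        L, ok = _chol_lower(S)
        if not ok:
            return a, Rc, fm, fc, ll, t
        innov = Y[t] - F @ am
        # z = L^{-1} innov ; logdet = 2 sum log diag L
        z = np.empty(C)
        logdet = 0.0
        for i in range(C):
            s = innov[i]
            for k in range(i):
                s -= L[i, k] * z[k]
            z[i] = s / L[i, i]
            logdet += 2.0 * np.log(L[i, i])
        ll += -0.5 * (C * _LOG2PI + logdet + z @ z)
        # K = Rt F' S^{-1} = (S^{-1} F Rt)'  via two triangular solves
        FR = F @ Rt  # C x p
        X = np.empty((C, p))
        for j in range(p):
            # forward: L w = FR[:, j]
            w = np.empty(C)
            for i in range(C):
                s = FR[i, j]
                for k in range(i):
                    s -= L[i, k] * w[k]
                w[i] = s / L[i, i]
            # backward: L' x = w
            for i in range(C - 1, -1, -1):
                s = w[i]
                for k in range(i + 1, C):
                    s -= L[k, i] * X[k, j]
                X[i, j] = s / L[i, i]
        K = X.T  # p x C
        m = am + K @ innov
        IKF = Ip - K @ F
        Cm = IKF @ Rt @ IKF.T + K @ Se @ K.T
        Cm = 0.5 * (Cm + Cm.T)
        fm[t] = m
        fc[t] = Cm
    return a, Rc, fm, fc, ll, -1


def _prepare_init(spec: ModelSpec, init_mean, init_var):
    p = spec.state_dim
    m0 = np.zeros(p) if init_mean is None else np.asarray(init_mean, dtype=float)
    if m0.shape != (p,):
        raise ValueError(f"init_mean must have length {p}")
    if init_var is None:
        init_var = 1e7
    C0 = np.asarray(init_var, dtype=float)
    if C0.ndim == 0:
        C0 = float(C0) * np.eye(p)
    if C0.shape != (p, p):
        raise ValueError(f"init_var must be a scalar or {p}x{p} matrix")
    if np.linalg.eigvalsh(_sym(C0)).min() < -1e-8:
        raise ValueError("init_var must be positive semidefinite")
    return m0, _sym(C0)


def kalman_filter(
    spec: ModelSpec,
    params: CovParams,
    data: ObservedSeries,
    init_mean=None,
    init_var=1e7,
) -> FilterResult:
    """Kalman filter for the SUTSE DLM, accumulating the log marginal likelihood.

    The likelihood is sum_t log N(Y_t; F a_t, F R_t F' + Sigma_eps) over the
    observed entries; missing (NaN) entries drop out of the update but the
    state still propagates.  Joseph-form covariance updates and per-step
    symmetrization keep the filtered covariances PSD.

    Raises
    ------
    NumericalSingularityError
        If the innovation covariance is not positive definite at some time
        step (the error message names the offending index).
    """
    if data.n_series != spec.n_series:
        raise ValueError(
            f"data has {data.n_series} series but spec expects {spec.n_series}"
        )
    F, G = spec.obs_matrix, spec.transition
    Sig_eps = params.obs_cov
    Sig_delta = params.state_evo_cov(spec)
    Y = data.log_counts
    T, C = Y.shape
    p = spec.state_dim

    m, Cmat = _prepare_init(spec, init_mean, init_var)
    init_mean_arr, init_cov_arr = m.copy(), Cmat.copy()

    if _HAVE_NUMBA and not np.isnan(Y).any():
        a, Rcov, fm, fc, loglik, fail = _filter_core(
            np.ascontiguousarray(Y), np.ascontiguousarray(F), np.ascontiguousarray(G),
            np.ascontiguousarray(Sig_delta), np.ascontiguousarray(Sig_eps), m, Cmat
        )
        if fail >= 0:
            raise NumericalSingularityError(
                f"innovation covariance not positive definite at time index {fail}"
            )
        return FilterResult(
            predicted_mean=a, predicted_cov=Rcov, filtered_mean=fm, filtered_cov=fc,
            init_mean=init_mean_arr, init_cov=init_cov_arr,
            log_marginal_likelihood=float(loglik), spec=spec,
        )

    a = np.empty((T, p))
    Rcov = np.empty((T, p, p))
    fm = np.empty((T, p))
    fc = np.empty((T, p, p))
    loglik = 0.0

    for t in range(T):
        am = G @ m
        Rt = _sym(G @ Cmat @ G.T + Sig_delta)
        a[t], Rcov[t] = am, Rt

        obs = ~np.isnan(Y[t])
        if not obs.any():
            m, Cmat = am, Rt
            fm[t], fc[t] = m, Cmat
            continue

        Fo = F[obs]
        yo = Y[t, obs]
        S = _sym(Fo @ Rt @ Fo.T + Sig_eps[np.ix_(obs, obs)])
        try:
            cS = cho_factor(S, lower=True)
        except np.linalg.LinAlgError as exc:
            raise NumericalSingularityError(
                f"innovation covariance not positive definite at time index {t}"
            ) from exc
        innov = yo - Fo @ am
        half = solve_triangular(cS[0], innov, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(cS[0])))
        loglik += -0.5 * (obs.sum() * _LOG2PI + logdet + half @ half)

        K = cho_solve(cS, Fo @ Rt).T  # p x n_obs gain
        m = am + K @ innov
        IKF = np.eye(p) - K @ Fo
        Cmat = _sym(IKF @ Rt @ IKF.T + K @ Sig_eps[np.ix_(obs, obs)] @ K.T)
        fm[t], fc[t] = m, Cmat

    return FilterResult(
        predicted_mean=a,
        predicted_cov=Rcov,
        filtered_mean=fm,
        filtered_cov=fc,
        init_mean=init_mean_arr,
        init_cov=init_cov_arr,
        log_marginal_likelihood=float(loglik),
        spec=spec,
    )


def _solve_psd(A: np.ndarray, B: np.ndarray, t: int) -> np.ndarray:
    """Solve A X = B for symmetric PSD A.

    Cholesky when A is numerically PD; otherwise an eigenvalue-clipped
    pseudo-solve, which keeps the backward recursions exact in degenerate
    limits (e.g. vanishing noise variances) where the one-step covariance
    collapses.
    """
    As = _sym(A)
    try:
        return cho_solve(cho_factor(As, lower=True), B)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(As)
        floor = max(np.abs(w).max(), 1e-300) * 1e-12
        w = np.where(w < floor, floor, w)
        return V @ ((V.T @ B) / w[:, None])


def smooth(
    spec: ModelSpec,
    params: CovParams,
    data: ObservedSeries,
    init_mean=None,
    init_var=1e7,
):
    """Fixed-interval (RTS) smoother.

    Returns
    -------
    (means, covs)
        ``means`` is (T+1) x p with row 0 the smoothed initial state;
        ``covs`` is (T+1) x p x p.
    """
    fr = kalman_filter(spec, params, data, init_mean, init_var)
    return smooth_from_filter(fr, spec)


def smooth_from_filter(fr: FilterResult, spec: ModelSpec):
    """RTS backward pass on an existing FilterResult; see :func:`smooth`."""
    G = spec.transition
    T, p = fr.filtered_mean.shape
    sm = np.empty((T + 1, p))
    sc = np.empty((T + 1, p, p))
    sm[T], sc[T] = fr.filtered_mean[T - 1], fr.filtered_cov[T - 1]
    # backward pass over t = T-1 .. 0 (state index; row t of sm is theta_t)
    for t in range(T - 1, -1, -1):
        if t == 0:
            m_t, C_t = fr.init_mean, fr.init_cov
        else:
            m_t, C_t = fr.filtered_mean[t - 1], fr.filtered_cov[t - 1]
        a_next, R_next = fr.predicted_mean[t], fr.predicted_cov[t]
        J = _solve_psd(R_next, G @ C_t, t).T  # C_t G' R_next^{-1}
        sm[t] = m_t + J @ (sm[t + 1] - a_next)
        sc[t] = _sym(C_t + J @ (sc[t + 1] - R_next) @ J.T)
    return sm, sc


def _psd_sqrt(C: np.ndarray) -> np.ndarray:
    """Matrix square root tolerant of semidefiniteness (eigenvalue clip at 0)."""
    try:
        return np.linalg.cholesky(_sym(C))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(_sym(C))
        return V * np.sqrt(np.clip(w, 0.0, None))


def ffbs(
    filter_result: FilterResult,
    spec: ModelSpec,
    params: CovParams,
    rng: np.random.Generator,
    n_draws: int | None = None,
):
    """Forward-filtering backward-sampling: exact joint draws of theta_{0:T}.

    Backward recursion samples the C-dimensional slope innovations
    delta~_{t+1} | theta_{t+1}, Y_{1:t} and reconstructs
    theta_t = G^{-1}(theta_{t+1} - R delta~_{t+1}), which is exact under the
    rank-deficient state innovation covariance.  When the evolution scale is
    zero the innovations are exactly zero and the back-propagation is
    deterministic, so slopes are exactly constant across draws.

    Parameters
    ----------
    n_draws
        If None, returns a single StateTrajectory; otherwise returns an
        ``(n_draws, T+1, p)`` array of trajectories (draws share the
        per-time backward matrices, so sampling many draws is vectorized).
    """
    if filter_result.filtered_mean.shape[1] != spec.state_dim:
        raise ValueError("filter_result was produced under a different model spec")
    G = spec.transition
    R = spec.evo_selection
    Sig = params.evo_cov  # C x C slope innovation covariance
    T, p = filter_result.filtered_mean.shape
    N = 1 if n_draws is None else int(n_draws)
    if N < 1:
        raise ValueError("n_draws must be positive")

    Ginv = np.linalg.inv(G)
    theta = np.empty((N, T + 1, p))

    LT = _psd_sqrt(filter_result.filtered_cov[T - 1])
    theta[:, T] = filter_result.filtered_mean[T - 1] + rng.standard_normal((N, p)) @ LT.T

    RSig = R @ Sig  # p x C
    for t in range(T - 1, -1, -1):
        a_next, R_next = filter_result.predicted_mean[t], filter_result.predicted_cov[t]
        # A = Sig R' R_next^{-1}  (C x p);  conditional covariance of delta~
        A = _solve_psd(R_next, RSig, t).T
        cond_cov = _sym(Sig - A @ RSig)
        L = _psd_sqrt(cond_cov)
        mean_d = (theta[:, t + 1] - a_next) @ A.T
        delta = mean_d + rng.standard_normal((N, Sig.shape[0])) @ L.T
        theta[:, t] = (theta[:, t + 1] - delta @ R.T) @ Ginv.T

    if n_draws is None:
        return StateTrajectory(states=theta[0], spec=spec)
    return theta
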