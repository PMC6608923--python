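"""Independent brute-force oracles used by the test suite.

These build the exact joint Gaussian distribution implied by the state-space
model directly from the structural matrices (no filtering recursions), so
they stay independent of the code paths they check.  Only tiny instances are
tractable, which is the point.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal


def joint_state_obs_moments(spec, params, T, init_mean, init_var):
    """Mean/covariance of (theta_0..theta_T, Y_1..Y_T) built by direct linear algebra."""
    p, C = spec.state_dim, spec.n_series
    G, F, R = spec.transition, spec.obs_matrix, spec.evo_selection
    m0 = np.asarray(init_mean, dtype=float)
    C0 = np.eye(p) * init_var if np.ndim(init_var) == 0 else np.asarray(init_var, float)
    Sd = params.evo_cov
    Se = params.obs_cov

    # theta_t = A_t theta_0 + sum_{s=1..t} B_{t,s} delta~_s
    A = [np.eye(p)]
    for _ in range(T):
        A.append(G @ A[-1])
    B = {}
    for t in range(1, T + 1):
        for s in range(1, t + 1):
            B[(t, s)] = A[t - s] @ R  # G^{t-s} R

    mean_th = np.concatenate([A[t] @ m0 for t in range(T + 1)])
    cov_th = np.zeros(((T + 1) * p, (T + 1) * p))
    for t in range(T + 1):
        for u in range(T + 1):
            block = A[t] @ C0 @ A[u].T
            for s in range(1, min(t, u) + 1):
                block = block + B[(t, s)] @ Sd @ B[(u, s)].T
            cov_th[t * p : (t + 1) * p, u * p : (u + 1) * p] = block

    H = np.zeros((T * C, (T + 1) * p))  # vec(Y) = H vec(theta) + noise
    for t in range(1, T + 1):
        H[(t - 1) * C : t * C, t * p : (t + 1) * p] = F
    mean_y = H @ mean_th
    cov_y = H @ cov_th @ H.T + np.kron(np.eye(T), Se)
    cov_cross = cov_th @ H.T  # Cov(theta, Y)
    return mean_th, cov_th, mean_y, cov_y, cov_cross


def brute_force_loglik(spec, params, Y, init_mean, init_var):
    """Log density of the observed entries of Y under the joint Gaussian."""
    Y = np.asarray(Y, dtype=float)
    T = Y.shape[0]
    _, _, mean_y, cov_y, _ = joint_state_obs_moments(spec, params, T, init_mean, init_var)
    yv = Y.ravel()
    obs = ~np.isnan(yv)
    return multivariate_normal.logpdf(
        yv[obs], mean=mean_y[obs], cov=cov_y[np.ix_(obs, obs)], allow_singular=True
    )


def brute_force_smoother(spec, params, Y, init_mean, init_var):
    """Conditional mean/cov of every theta_t given the observed Y entries."""
    Y = np.asarray(Y, dtype=float)
    T = Y.shape[0]
    p = spec.state_dim
    mean_th, cov_th, mean_y, cov_y, cov_cross = joint_state_obs_moments(
        spec, params, T, init_mean, init_var
    )
    yv = Y.ravel()
    obs = ~np.isnan(yv)
    K = cov_cross[:, obs] @ np.linalg.inv(cov_y[np.ix_(obs, obs)])
    mean_cond = mean_th + K @ (yv[obs] - mean_y[obs])
    cov_cond = cov_th - K @ cov_cross[:, obs].T
    means = mean_cond.reshape(T + 1, p)
    covs = np.array([cov_cond[t * p : (t + 1) * p, t * p : (t + 1) * p] for t in range(T + 1)])
    return means, covs


def energy_stat_hand(y, d):
    """Term-by-term energy statistic for already-standardized data (d=1 closed form)."""
    from scipy.stats import norm

    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    assert d == 1
    e_xz = np.mean(2.0 * norm.pdf(y) + y * (2.0 * norm.cdf(y) - 1.0))
    e_zz = 2.0 / np.sqrt(np.pi)
    e_xx = np.abs(y[:, None] - y[None, :]).sum() / n**2
    return n * (2.0 * e_xz - e_zz - e_xx)
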