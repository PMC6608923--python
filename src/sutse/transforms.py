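"""Bijections between constrained covariance parameters and unconstrained vectors.

Standard deviations map through log.  Correlation matrices map through the
canonical partial-correlation (unconstrained Cholesky) bijection: the free
vector is atanh of the canonical partial correlations z, each row of the
Cholesky factor L is filled as ``L[i,j] = z_ij * sqrt(1 - sum_{k<j} L[i,k]^2)``,
and ``Omega = L L'``.  The log-Jacobian of u -> Omega is

    sum_{i>j} [ log(1 - z_ij^2) + (1/2) log(1 - sum_{k<j} L[i,k]^2) ]
    + sum_j (d - 1 - j) log L_jj

(tanh term, row-normalization term, and the L -> L L' term, respectively).
"""

from __future__ import annotations

import numpy as np

from .model import CovParams

__all__ = ["ParamTransform", "corr_from_unconstrained", "corr_to_unconstrained"]


def _chol_from_z(z: np.ndarray, d: int):
    """Cholesky factor of a correlation matrix from canonical partial corrs.

    Returns (L, log_jac) where log_jac is the full log-Jacobian of the map
    from atanh(z) to the correlation matrix.
    """
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    lj = 0.0
    k = 0
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            zij = z[k]
            k += 1
            lj += np.log1p(-zij * zij) + 0.5 * np.log(rem)
            L[i, j] = zij * np.sqrt(rem)
            rem *= 1.0 - zij * zij
        L[i, i] = np.sqrt(rem)
    for j in range(d):
        lj += (d - 1 - j) * np.log(L[j, j])
    return L, lj


def corr_from_unconstrained(u: np.ndarray, d: int):
    """Map a free vector of length d(d-1)/2 to (Omega, log_jacobian)."""
    u = np.asarray(u, dtype=float)
    if u.shape != (d * (d - 1) // 2,):
        raise ValueError(f"expected {d * (d - 1) // 2} free entries for d={d}")
    z = np.tanh(u)
    L, lj = _chol_from_z(z, d)
    omega = L @ L.T
    np.fill_diagonal(omega, 1.0)
    return omega, lj


def corr_to_unconstrained(omega: np.ndarray) -> np.ndarray:
    """Inverse of :func:`corr_from_unconstrained` (requires PD input)."""
    omega = np.asarray(omega, dtype=float)
    d = omega.shape[0]
    L = np.linalg.cholesky(omega)
    z = np.empty(d * (d - 1) // 2)
    k = 0
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            z[k] = L[i, j] / np.sqrt(rem)
            rem -= L[i, j] ** 2
            k += 1
    return np.arctanh(np.clip(z, -1 + 1e-15, 1 - 1e-15))


class ParamTransform:
    """Bijection between CovParams for C series and R^(2C + C(C-1)).

    Layout of the free vector u: ``log sigma (C), log gamma (C),
    free(Omega_eps) (C(C-1)/2), free(Omega_delta) (C(C-1)/2)``.
    """

    def __init__(self, n_series: int):
        self.C = int(n_series)
        self.m = self.C * (self.C - 1) // 2
        self.dim = 2 * self.C + 2 * self.m

    def constrain(self, u: np.ndarray) -> CovParams:
        u = np.asarray(u, dtype=float)
        if u.shape != (self.dim,):
            raise ValueError(f"expected free vector of length {self.dim}")
        C, m = self.C, self.m
        obs_sd = np.exp(u[:C])
        evo_sd = np.exp(u[C : 2 * C])
        omega_eps, _ = corr_from_unconstrained(u[2 * C : 2 * C + m], C)
        omega_delta, _ = corr_from_unconstrained(u[2 * C + m :], C)
        return CovParams(obs_sd=obs_sd, obs_corr=omega_eps, evo_sd=evo_sd, evo_corr=omega_delta)

    def unconstrain(self, params: CovParams) -> np.ndarray:
        if params.n_series != self.C:
            raise ValueError("params dimension mismatch")
        return np.concatenate(
            [
                np.log(params.obs_sd),
                np.log(params.evo_sd),
                corr_to_unconstrained(params.obs_corr),
                corr_to_unconstrained(params.evo_corr),
            ]
        )

    def log_jacobian(self, u: np.ndarray) -> float:
        """log |d(constrained)/du|: sum of log-sds plus the two correlation terms."""
        u = np.asarray(u, dtype=float)
        C, m = self.C, self.m
        lj = float(np.sum(u[: 2 * C]))  # d exp(u)/du = exp(u)
        for block in (u[2 * C : 2 * C + m], u[2 * C + m :]):
            if m:
                _, ljc = _chol_from_z(np.tanh(block), C)
                lj += ljc
        return lj
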