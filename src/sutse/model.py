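"""Structural matrices for SUTSE dynamic linear models.

A SUTSE (seemingly unrelated time series equations) model ties C univariate
structural time-series models together only through the covariance matrices of
their observation errors and state evolutions.  Each series carries a local
linear trend (level + slope, with evolution noise entering the slope only, so
the level is an integrated random walk) and optionally ``q`` Fourier harmonics
of a seasonal cycle of period ``s``.

State layout, per series: ``(level, slope, harm_1, conj_1, ..., harm_q[, conj_q])``;
series blocks are concatenated in input order.  When ``q == s/2`` the final
harmonic is a single alternating coordinate (its conjugate is redundant), so a
series block has ``2 + 2q - 1`` coordinates instead of ``2 + 2q``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "CovParams",
    "InvalidSpecError",
    "build_model",
    "seasonal_value",
    "observation_mean",
]


class InvalidSpecError(ValueError):
    """Raised when a model specification is structurally impossible."""


@dataclass(frozen=True)
class ModelSpec:
    """Structural objects of a C-series, q-harmonic SUTSE DLM.

    Attributes
    ----------
    n_series
        Number of parallel series C.
    n_harmonics
        Number of Fourier harmonics q (0 disables seasonality).
    period
        Seasonal period s in time steps (12 for monthly data with an
        annual cycle).
    state_dim
        Length p of the concatenated latent state vector.
    obs_matrix
        C x p binary matrix F of the observation equation Y_t = F theta_t + eps_t.
    transition
        p x p block-diagonal transition matrix G of theta_t = G theta_{t-1} + delta_t.
    evo_selection
        p x C binary matrix R mapping the C-dimensional slope innovations
        delta~_t to the state innovation delta_t = R delta~_t.
    coord_labels
        Sequence of (series index, role) pairs, one per state coordinate;
        role is one of ``level``, ``slope``, ``harmonic_j``, ``conjugate_j``.
    """

    n_series: int
    n_harmonics: int
    period: int
    state_dim: int
    obs_matrix: np.ndarray
    transition: np.ndarray
    evo_selection: np.ndarray
    coord_labels: tuple = field(repr=False, default=())

    @property
    def block_dim(self) -> int:
        """State coordinates per series."""
        return self.state_dim // self.n_series

    def coords_of(self, series: int, role: str) -> int:
        """Index of the coordinate with the given role for one series."""
        for k, (c, r) in enumerate(self.coord_labels):
            if c == series and r == role:
                return k
        raise KeyError(f"no coordinate ({series}, {role!r})")

    @property
    def level_idx(self) -> np.ndarray:
        return np.array([k for k, (_, r) in enumerate(self.coord_labels) if r == "level"])

    @property
    def slope_idx(self) -> np.ndarray:
        return np.array([k for k, (_, r) in enumerate(self.coord_labels) if r == "slope"])

    def to_json(self) -> str:
        """Serialize dimensions and labels (not the dense matrices) for provenance."""
        return json.dumps(
            {
                "n_series": self.n_series,
                "n_harmonics": self.n_harmonics,
                "period": self.period,
                "state_dim": self.state_dim,
                "coord_labels": [list(cl) for cl in self.coord_labels],
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "ModelSpec":
        d = json.loads(doc)
        spec = build_model(d["n_series"], d["n_harmonics"], d["period"])
        if spec.state_dim != d["state_dim"]:
            raise InvalidSpecError("serialized state_dim inconsistent with dimensions")
        return spec


def _check_corr(omega: np.ndarray, name: str) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(omega, omega.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(omega), 1.0, atol=1e-10):
        raise ValueError(f"{name} must have unit diagonal")
    if np.linalg.eigvalsh(omega).min() < -1e-10:
        raise ValueError(f"{name} must be positive semidefinite")
    return omega


@dataclass(frozen=True)
class CovParams:
    """Covariance hyperparameters of a SUTSE DLM.

    ``obs_sd`` (sigma, log-count units) and ``obs_corr`` (Omega_eps) define the
    observation error covariance; ``evo_sd`` (gamma, log-counts per step per
    step — the slope innovation scale) and ``evo_corr`` (Omega_delta) define
    the slope evolution covariance.
    """

    obs_sd: np.ndarray
    obs_corr: np.ndarray
    evo_sd: np.ndarray
    evo_corr: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "obs_sd", np.asarray(self.obs_sd, dtype=float))
        object.__setattr__(self, "evo_sd", np.asarray(self.evo_sd, dtype=float))
        if np.any(self.obs_sd < 0) or np.any(self.evo_sd < 0):
            raise ValueError("standard deviations must be nonnegative")
        object.__setattr__(self, "obs_corr", _check_corr(self.obs_corr, "obs_corr"))
        object.__setattr__(self, "evo_corr", _check_corr(self.evo_corr, "evo_corr"))
        if not (len(self.obs_sd) == self.obs_corr.shape[0] == len(self.evo_sd) == self.evo_corr.shape[0]):
            raise ValueError("inconsistent dimensions in CovParams")

    @property
    def n_series(self) -> int:
        return len(self.obs_sd)

    @property
    def obs_cov(self) -> np.ndarray:
        """Sigma_eps = diag(sigma) Omega_eps diag(sigma)."""
        return self.obs_corr * np.outer(self.obs_sd, self.obs_sd)

    @property
    def evo_cov(self) -> np.ndarray:
        """Sigma_delta~ = diag(gamma) Omega_delta diag(gamma) (slope innovations)."""
        return self.evo_corr * np.outer(self.evo_sd, self.evo_sd)

    def state_evo_cov(self, spec: ModelSpec) -> np.ndarray:
        """Rank-deficient p x p state innovation covariance Sigma_delta = R Sigma_delta~ R'."""
        R = spec.evo_selection
        return R @ self.evo_cov @ R.T


def _series_block(q: int, s: int) -> tuple[np.ndarray, list[str]]:
    """Transition block and coordinate roles for a single series."""
    blocks = [np.array([[1.0, 1.0], [0.0, 1.0]])]
    roles = ["level", "slope"]
    for j in range(1, q + 1):
        if 2 * j == s:
            blocks.append(np.array([[-1.0]]))
            roles.append(f"harmonic_{j}")
        else:
            w = 2.0 * np.pi * j / s
            blocks.append(np.array([[np.cos(w), np.sin(w)], [-np.sin(w), np.cos(w)]]))
            roles += [f"harmonic_{j}", f"conjugate_{j}"]
    dim = len(roles)
    G = np.zeros((dim, dim))
    k = 0
    for b in blocks:
        G[k : k + b.shape[0], k : k + b.shape[1]] = b
        k += b.shape[0]
    return G, roles


def build_model(n_series: int, n_harmonics: int = 0, period: int = 12) -> ModelSpec:
    """Construct the structural matrices of a SUTSE DLM.

    Parameters
    ----------
    n_series
        Number of parallel series C (>= 1).
    n_harmonics
        Number of seasonal harmonics q, between 0 and period/2.  At
        ``q == period/2`` the last harmonic degenerates to one alternating
        state coordinate.
    period
        Seasonal period s (must be even so the maximum harmonic is s/2).

    Returns
    -------
    ModelSpec

    Raises
    ------
    InvalidSpecError
        If C < 1, s is odd, or q is outside [0, s/2].
    """
    if n_series < 1:
        raise InvalidSpecError(f"need at least one series, got {n_series}")
    if period % 2 != 0 or period < 2:
        raise InvalidSpecError(f"period must be a positive even integer, got {period}")
    if not 0 <= n_harmonics <= period // 2:
        raise InvalidSpecError(
            f"n_harmonics must lie in [0, {period // 2}] for period {period}, got {n_harmonics}"
        )

    G1, roles = _series_block(n_harmonics, period)
    bd = len(roles)
    p = n_series * bd
    G = np.kron(np.eye(n_series), G1)

    f_row = np.array([1.0 if r == "level" or r.startswith("harmonic") else 0.0 for r in roles])
    F = np.kron(np.eye(n_series), f_row)

    r_col = np.array([1.0 if r == "slope" else 0.0 for r in roles])
    R = np.kron(np.eye(n_series), r_col[:, None])

    labels = tuple((c, r) for c in range(n_series) for r in roles)
    return ModelSpec(
        n_series=n_series,
        n_harmonics=n_harmonics,
        period=period,
        state_dim=p,
        obs_matrix=F,
        transition=G,
        evo_selection=R,
        coord_labels=labels,
    )


def seasonal_value(
    spec: ModelSpec, seasonal_state_at_origin: Sequence[float], series: int, t: int
) -> float:
    """Summed harmonic contribution of one series at integer time t.

    ``seasonal_state_at_origin`` holds the seasonal coordinates of the series
    block at the time origin (length 2q, or 2q-1 when q = s/2).  The harmonics
    are propagated by the seasonal rotation blocks of G, so the value is
    sum_j [zeta_j cos(t w_j) + eta_j sin(t w_j)] with w_j = 2 pi j / s, exactly
    periodic with period s.
    """
    q, s = spec.n_harmonics, spec.period
    expected = 2 * q - (1 if 2 * q == s else 0)
    x = np.asarray(seasonal_state_at_origin, dtype=float)
    if x.shape != (expected,):
        raise ValueError(f"seasonal state must have length {expected}, got {x.shape}")
    if not 0 <= series < spec.n_series:
        raise ValueError(f"series index {series} out of range")
    total = 0.0
    k = 0
    for j in range(1, q + 1):
        w = 2.0 * np.pi * j / s
        if 2 * j == s:
            total += x[k] * (-1.0) ** t
            k += 1
        else:
            total += x[k] * np.cos(t * w) + x[k + 1] * np.sin(t * w)
            k += 2
    return float(total)


def observation_mean(spec: ModelSpec, state: Sequence[float]) -> np.ndarray:
    """Observation-equation mean F @ theta: per series, level plus all harmonic values."""
    theta = np.asarray(state, dtype=float)
    if theta.shape != (spec.state_dim,):
        raise ValueError(f"state must have length {spec.state_dim}, got {theta.shape}")
    return spec.obs_matrix @ theta
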