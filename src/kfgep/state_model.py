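"""Kalman machinery over pen-velocity states.

The state is the 2-vector of coordinate increments (Δx, Δy) per 50 ms step.
The state-transition matrix ``A`` and process-noise covariance ``Q`` are
estimated by binary linear regression (BiLR) of each next increment on the
current increment pair:

    Δx_{i+1} = a1 Δx_i + a2 Δy_i + u_i
    Δy_{i+1} = b1 Δx_i + b2 Δy_i + v_i

with A = [[a1, a2], [b1, b2]] and Q = cov(u, v) (sample covariance, n-1
denominator).  No intercept appears in the regression, matching the model as
published.  ``fit_linear_observation`` provides the multivariate-linear
observation map used by the KF-only baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

COND_LIMIT = 1e12
RIDGE = 1e-10


class RankDeficientWarning(UserWarning):
    """Regressor matrix is rank deficient; a minimum-norm solution was used."""


@dataclass
class StateModel:
    """Fitted first-order linear dynamics of the increment state."""

    A: np.ndarray  # (2, 2)
    Q: np.ndarray  # (2, 2) PSD
    beta_x: np.ndarray = field(default=None)  # (2,)
    beta_y: np.ndarray = field(default=None)
    residuals_u: np.ndarray = field(default=None, repr=False)
    residuals_v: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float).reshape(2, 2)
        self.Q = np.asarray(self.Q, dtype=float).reshape(2, 2)
        if self.beta_x is None:
            self.beta_x = self.A[0].copy()
        if self.beta_y is None:
            self.beta_y = self.A[1].copy()

    def to_dict(self) -> dict:
        return {"A": self.A.tolist(), "Q": self.Q.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "StateModel":
        return cls(A=np.asarray(d["A"]), Q=np.asarray(d["Q"]))


@dataclass
class KFState:
    """Filter state: increment estimate S, covariance P, step index t."""

    S: np.ndarray
    P: np.ndarray
    t: int = 0

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float).reshape(2)
        self.P = np.asarray(self.P, dtype=float).reshape(2, 2)

    @classmethod
    def initial(cls) -> "KFState":
        """S0 = 0, P0 = I2."""
        return cls(S=np.zeros(2), P=np.eye(2), t=0)


def _ols(X: np.ndarray, Y: np.ndarray, min_rows: int, what: str):
    """Least squares Y ~ X (no intercept); warns and falls back to the
    minimum-norm solution when X is rank deficient."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] < min_rows:
        raise ValueError(f"{what}: need at least {min_rows} rows, got {X.shape[0]}")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError(f"{what}: non-finite values in inputs")
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"{what}: regressor matrix is rank deficient (rank {rank} < "
            f"{X.shape[1]}); returning the minimum-norm solution",
            RankDeficientWarning,
            stacklevel=3,
        )
    resid = Y - X @ coef
    return coef, resid


def _sample_cov(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """2x2 sample covariance of paired residuals, n-1 denominator."""
    m = np.cov(np.vstack([u, v]), ddof=1)
    m = np.atleast_2d(m)
    return (m + m.T) / 2.0


def fit_bilr(deltas: np.ndarray, next_deltas: np.ndarray | None = None) -> StateModel:
    """Fit the increment dynamics by binary linear regression.

    Parameters
    ----------
    deltas : (k, 2) array
        Increment sequence (Δx_i, Δy_i).  If ``next_deltas`` is omitted the
        one-step-ahead targets are taken from ``deltas`` itself (rows 2..k
        regressed on rows 1..k-1).
    next_deltas : (k, 2) array, optional
        Explicit targets aligned row-by-row with ``deltas`` — used when
        pooling several trials so that no regression row straddles a trial
        boundary.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.ndim != 2 or deltas.shape[1] != 2:
        raise ValueError(f"deltas must be (k, 2), got {deltas.shape}")
    if next_deltas is None:
        if deltas.shape[0] < 4:
            raise ValueError("need at least 4 increments to fit the dynamics")
        X, Y = deltas[:-1], deltas[1:]
    else:
        next_deltas = np.asarray(next_deltas, dtype=float)
        if next_deltas.shape != deltas.shape:
            raise ValueError("deltas and next_deltas must have matching shapes")
        X, Y = deltas, next_deltas
    coef, resid = _ols(X, Y, min_rows=3, what="fit_bilr")
    beta_x, beta_y = coef[:, 0], coef[:, 1]
    A = np.vstack([beta_x, beta_y])
    Q = _sample_cov(resid[:, 0], resid[:, 1])
    return StateModel(A=A, Q=Q, beta_x=beta_x, beta_y=beta_y,
                      residuals_u=resid[:, 0], residuals_v=resid[:, 1])


def fit_linear_observation(features: np.ndarray, deltas: np.ndarray):
    """Multivariate linear map from RMS features to increments (KF baseline).

    Returns ``(H, R)`` with H of shape (2, 7) such that C_t = H @ RMS_t, and
    R the 2x2 sample covariance of the fit residuals.
    """
    features = np.asarray(features, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if features.shape[0] != deltas.shape[0]:
        raise ValueError(
            f"features rows ({features.shape[0]}) != deltas rows ({deltas.shape[0]})"
        )
    coef, resid = _ols(features, deltas, min_rows=max(8, features.shape[1] + 1),
                       what="fit_linear_observation")
    H = coef.T  # (2, n_channels)
    R = _sample_cov(resid[:, 0], resid[:, 1])
    return H, R


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.isfinite(a).all():
            raise ValueError("non-finite entries in filter inputs")


def kf_predict(state: KFState, model: StateModel) -> KFState:
    """Time update: S^ = A S, P^ = A P A' + Q."""
    _check_finite(state.S, state.P, model.A, model.Q)
    S = model.A @ state.S
    P = model.A @ state.P @ model.A.T + model.Q
    P = (P + P.T) / 2.0
    return KFState(S=S, P=P, t=state.t + 1)


def kf_update(state_pred: KFState, observation: np.ndarray, R: np.ndarray) -> KFState:
    """Measurement update with the observation living in state space
    (identity measurement matrix): K = P^(P^+R)^-1, S = S^ + K(C - S^),
    P = P^ - K P^."""
    C = np.asarray(observation, dtype=float).reshape(2)
    R = np.asarray(R, dtype=float).reshape(2, 2)
    _check_finite(state_pred.S, state_pred.P, C, R)
    M = state_pred.P + R
    if np.linalg.cond(M) > COND_LIMIT:
        warnings.warn(
            "P^ + R is ill-conditioned; adding ridge regularization",
            UserWarning,
            stacklevel=2,
        )
        M = M + RIDGE * np.eye(2)
        if np.linalg.cond(M) > 1 / np.finfo(float).eps:
            raise np.linalg.LinAlgError("P^ + R singular even after regularization")
    # K = P^ M^-1 computed via a solve on the transposed system
    K = np.linalg.solve(M.T, state_pred.P.T).T
    S = state_pred.S + K @ (C - state_pred.S)
    P = state_pred.P - K @ state_pred.P
    P = (P + P.T) / 2.0
    return KFState(S=S, P=P, t=state_pred.t)
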