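"""The KF-GEP decoder: training and the three reconstruction paths.

Training fits, from aligned feature/trace pairs:

* the increment dynamics ``A``, ``Q`` by binary linear regression (per trial,
  residuals pooled, so no regression row straddles a trial boundary);
* two symbolic observation models ``GEP_X``, ``GEP_Y`` mapping the 7-channel
  RMS vector to the coordinate increments, evolved by the GEP engine with
  derived seeds (seed, seed + 1);
* the observation-noise covariance ``R`` as the full 2x2 sample covariance of
  the paired GEP training residuals.

Reconstruction runs the Kalman recursion with the GEP outputs standing in
for the classical linear measurement: the observation already lives in state
space, so the measurement matrix is the identity.  The filter is re-initialized
(S0 = 0, P0 = I2) at the start of every trial.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np

from .gep import GepConfig, GepModel, run_gep
from .preprocessing import from_deltas, to_deltas
from .state_model import (
    KFState,
    StateModel,
    fit_bilr,
    kf_predict,
    kf_update,
)

N_CHANNELS = 7


def _as_trial_lists(features, trace):
    """Accept a single aligned (features, trace) pair or parallel lists."""
    if isinstance(features, np.ndarray) and features.ndim == 2:
        features = [features]
        trace = [trace]
    feats: List[np.ndarray] = [np.asarray(f, dtype=float) for f in features]
    traces: List[np.ndarray] = [np.asarray(t, dtype=float) for t in trace]
    if len(feats) != len(traces):
        raise ValueError(
            f"got {len(feats)} feature blocks but {len(traces)} traces"
        )
    for f, t in zip(feats, traces):
        if t.shape[0] < 4:
            raise ValueError("every trace needs at least 4 points")
        if f.shape != (t.shape[0] - 1, N_CHANNELS):
            raise ValueError(
                f"misaligned trial: features {f.shape} vs trace length "
                f"{t.shape[0]} (expected ({t.shape[0] - 1}, {N_CHANNELS}))"
            )
    return feats, traces


def _data_fingerprint(feats: Sequence[np.ndarray], traces: Sequence[np.ndarray]) -> str:
    h = hashlib.sha256()
    for f, t in zip(feats, traces):
        h.update(np.ascontiguousarray(f, dtype=float).tobytes())
        h.update(np.ascontiguousarray(t, dtype=float).tobytes())
    return h.hexdigest()[:16]


@dataclass
class KFGEPModel:
    """Trained bundle {A, Q, R, GEP_X, GEP_Y} plus training metadata."""

    state_model: StateModel
    R: np.ndarray
    gep_x: GepModel
    gep_y: GepModel
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float).reshape(2, 2)

    def observe(self, features: np.ndarray) -> np.ndarray:
        """GEP observations C_t for each feature row: (n, 2)."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        return np.column_stack([self.gep_x.predict(X), self.gep_y.predict(X)])

    def to_dict(self) -> dict:
        return {
            "state_model": self.state_model.to_dict(),
            "R": self.R.tolist(),
            "gep_x": self.gep_x.to_dict(),
            "gep_y": self.gep_y.to_dict(),
            "meta": self.meta,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "KFGEPModel":
        return cls(
            state_model=StateModel.from_dict(d["state_model"]),
            R=np.asarray(d["R"]),
            gep_x=GepModel.from_dict(d["gep_x"]),
            gep_y=GepModel.from_dict(d["gep_y"]),
            meta=d.get("meta", {}),
        )

    @classmethod
    def from_json(cls, s: str) -> "KFGEPModel":
        return cls.from_dict(json.loads(s))


def train(features, trace, gep_config: GepConfig | None = None) -> KFGEPModel:
    """Train the full decoder from aligned feature/trace data.

    ``features``/``trace`` may be one aligned pair (a (k, 7) matrix with a
    (k+1, 2) trace) or parallel sequences of such pairs; trials are pooled.
    """
    gep_config = gep_config or GepConfig()
    feats, traces = _as_trial_lists(features, trace)

    cur_rows, nxt_rows, rms_rows, dx_rows, dy_rows = [], [], [], [], []
    for f, t in zip(feats, traces):
        deltas, shifted = to_deltas(t)
        cur_rows.append(deltas[:-1])
        nxt_rows.append(shifted)
        rms_rows.append(f)
        dx_rows.append(deltas[:, 0])
        dy_rows.append(deltas[:, 1])
    state_model = fit_bilr(np.vstack(cur_rows), np.vstack(nxt_rows))

    X = np.vstack(rms_rows)
    dx = np.concatenate(dx_rows)
    dy = np.concatenate(dy_rows)
    gep_x, res_x = run_gep(X, dx, replace(gep_config, rng_seed=gep_config.rng_seed))
    gep_y, res_y = run_gep(X, dy, replace(gep_config, rng_seed=gep_config.rng_seed + 1))

    m = np.cov(np.vstack([res_x, res_y]), ddof=1)
    R = (np.atleast_2d(m) + np.atleast_2d(m).T) / 2.0

    meta = {
        "seed": int(gep_config.rng_seed),
        "config": gep_config.to_dict(),
        "data_fingerprint": _data_fingerprint(feats, traces),
        "n_trials": len(feats),
        "n_rows": int(X.shape[0]),
        "training_rmse_x": float(gep_x.training_rmse),
        "training_rmse_y": float(gep_y.training_rmse),
    }
    return KFGEPModel(state_model=state_model, R=R, gep_x=gep_x, gep_y=gep_y, meta=meta)


def _kf_recursion(
    observations: np.ndarray,
    state_model: StateModel,
    R: np.ndarray,
    origin,
) -> np.ndarray:
    state = KFState.initial()
    deltas = np.empty_like(observations)
    for t in range(observations.shape[0]):
        pred = kf_predict(state, state_model)
        state = kf_update(pred, observations[t], R)
        deltas[t] = state.S
    return from_deltas(deltas, origin)


def reconstruct(
    features: np.ndarray, model: KFGEPModel, origin=(0.0, 0.0)
) -> np.ndarray:
    """Fused KF-GEP reconstruction: (n + 1, 2) trace including the origin."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != N_CHANNELS:
        raise ValueError(f"features must have {N_CHANNELS} columns, got {X.shape[1]}")
    C = model.observe(X)
    if not np.isfinite(C).all():
        raise ValueError("non-finite GEP observation")
    return _kf_recursion(C, model.state_model, model.R, origin)


def reconstruct_gep_only(
    features: np.ndarray, model: KFGEPModel, origin=(0.0, 0.0)
) -> np.ndarray:
    """Unfiltered baseline: cumulative sum of the raw GEP predictions."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != N_CHANNELS:
        raise ValueError(f"features must have {N_CHANNELS} columns, got {X.shape[1]}")
    C = model.observe(X)
    if not np.isfinite(C).all():
        raise ValueError("non-finite GEP observation")
    return from_deltas(C, origin)


def reconstruct_kf_only(
    features: np.ndarray,
    state_model: StateModel,
    H: np.ndarray,
    R: np.ndarray,
    origin=(0.0, 0.0),
) -> np.ndarray:
    """Classical baseline: the same Kalman recursion with the multivariate
    linear observation C_t = H @ RMS_t."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    H = np.asarray(H, dtype=float)
    if H.shape != (2, X.shape[1]):
        raise ValueError(f"H must be (2, {X.shape[1]}), got {H.shape}")
    C = X @ H.T
    if not np.isfinite(C).all():
        raise ValueError("non-finite linear observation")
    return _kf_recursion(C, state_model, np.asarray(R, dtype=float), origin)
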