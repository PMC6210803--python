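"""Delimited-text dataset formats, model JSON, and run configuration.

Traces are CSV with header ``trial_id,t_index,x,y``; features are CSV with
header ``trial_id,t_index,T1..T7``.  One file holds a whole dataset;
``trial_id`` is ``<symbol>-<index>`` so trials pair up across the two files.
All files are UTF-8, comma-separated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import yaml

from .gep import GepConfig
from .hybrid import KFGEPModel
from .synthetic import SYMBOL_IDS, Trial

FEATURE_COLUMNS = [f"T{i}" for i in range(1, 8)]


class SchemaError(ValueError):
    """An input file does not match the expected column layout."""


def _trial_key(trial: Trial) -> str:
    return f"{trial.symbol_id}-{trial.trial_id:03d}"


def write_traces(path, trials: Sequence[Trial]) -> None:
    rows = []
    for tr in trials:
        for i, (x, y) in enumerate(tr.trace):
            rows.append((_trial_key(tr), i, x, y))
    pd.DataFrame(rows, columns=["trial_id", "t_index", "x", "y"]).to_csv(
        path, index=False
    )


def write_features(path, trials: Sequence[Trial]) -> None:
    rows = []
    for tr in trials:
        for i, feat in enumerate(tr.features):
            rows.append((_trial_key(tr), i, *feat))
    pd.DataFrame(rows, columns=["trial_id", "t_index", *FEATURE_COLUMNS]).to_csv(
        path, index=False
    )


def _check_columns(df: pd.DataFrame, required: List[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _split_key(key: str):
    sym, _, idx = key.rpartition("-")
    if not sym or not idx.isdigit():
        raise SchemaError(f"malformed trial_id {key!r}; expected '<symbol>-<index>'")
    return sym, int(idx)


def read_dataset(traces_path, features_path) -> List[Trial]:
    """Pair a trace file with a feature file into a list of trials."""
    tdf = pd.read_csv(traces_path)
    fdf = pd.read_csv(features_path)
    _check_columns(tdf, ["trial_id", "t_index", "x", "y"], traces_path)
    _check_columns(fdf, ["trial_id", "t_index", *FEATURE_COLUMNS], features_path)
    traces: Dict[str, np.ndarray] = {}
    for key, grp in tdf.groupby("trial_id", sort=False):
        grp = grp.sort_values("t_index")
        traces[str(key)] = grp[["x", "y"]].to_numpy(dtype=float)
    trials: List[Trial] = []
    for key, grp in fdf.groupby("trial_id", sort=False):
        key = str(key)
        if key not in traces:
            raise SchemaError(f"{features_path}: trial {key!r} has no trace")
        grp = grp.sort_values("t_index")
        feats = grp[FEATURE_COLUMNS].to_numpy(dtype=float)
        sym, idx = _split_key(key)
        trials.append(
            Trial(symbol_id=sym, trial_id=idx, trace=traces[key], features=feats)
        )
    return trials


def save_model(path, model: KFGEPModel) -> None:
    Path(path).write_text(model.to_json(indent=2), encoding="utf-8")


def load_model(path) -> KFGEPModel:
    return KFGEPModel.from_json(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Repo-wide run configuration; every random stage derives from ``seed``."""

    seed: int = 0
    symbols: List[str] = field(default_factory=lambda: list(SYMBOL_IDS))
    trials_per_symbol: int = 40
    n_points: int = 30
    scale: float = 100.0
    noise_sd: float = 1.0
    gep: GepConfig = field(default_factory=GepConfig)
    design: str = "between"
    methods: List[str] = field(default_factory=lambda: ["KF-GEP", "KF", "GEP"])
    n_splits: int = 1
    split_fraction: float = 0.7
    alternative: str = "greater"

    def validate(self) -> None:
        if self.trials_per_symbol < 1:
            raise ValueError("trials_per_symbol must be >= 1")
        unknown = set(self.symbols) - set(SYMBOL_IDS)
        if unknown:
            raise ValueError(f"unknown symbols: {sorted(unknown)}")
        self.gep.validate()

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "symbols": list(self.symbols),
            "trials_per_symbol": self.trials_per_symbol,
            "n_points": self.n_points,
            "scale": self.scale,
            "noise_sd": self.noise_sd,
            "gep": self.gep.to_dict(),
            "design": self.design,
            "methods": list(self.methods),
            "n_splits": self.n_splits,
            "split_fraction": self.split_fraction,
            "alternative": self.alternative,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "gep" in d and d["gep"] is not None:
            d["gep"] = GepConfig.from_dict(d["gep"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )


def config_hash(config: RunConfig) -> str:
    import hashlib

    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]
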