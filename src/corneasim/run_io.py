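"""Run configuration files, manifests and result serialization.

Config files are flat YAML key-value documents whose keys mirror
:class:`~corneasim.engine.ModelConfig` fields; unknown keys are rejected
with all violations reported at once. A run manifest (JSON) records the
fully resolved configuration, seed, stop reason and code version, and is
sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import ModelConfig, TissueState, Trajectory

_FIELDS = {f.name: f for f in dataclasses.fields(ModelConfig)}


def load_config(path: Union[str, Path]) -> ModelConfig:
    """Load and validate a ModelConfig from a flat YAML file.

    An empty file yields all defaults. Unknown keys and type errors are
    enumerated together in a single ``ValueError``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must be a flat mapping")
    problems = [f"unknown key {k!r}" for k in raw if k not in _FIELDS]
    clean = {k: v for k, v in raw.items() if k in _FIELDS}
    if "alpha" in clean and "rho" in clean and clean.get("rho") is not None \
            and clean.get("model_class", "coupled") == "coupled":
        problems.append("alpha and rho are mutually exclusive for the "
                        "coupled model (rho belongs to 'uncoupled')")
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    return ModelConfig(**clean)


def save_config(config: ModelConfig, path: Union[str, Path]) -> None:
    d = dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def manifest_dict(trajectory: Trajectory,
                  wall_time: Optional[float] = None) -> dict:
    cfg = dataclasses.asdict(trajectory.config)
    return {
        "config": cfg,
        "seed": trajectory.seed,
        "stop_reason": trajectory.stop_reason,
        "stalled": trajectory.stalled,
        "renewal_tau": (None if math.isnan(trajectory.renewal_tau)
                        else trajectory.renewal_tau),
        "code_version": __version__,
        "wall_time_s": wall_time,
    }


def write_manifest(trajectory: Trajectory, path: Union[str, Path],
                   wall_time: Optional[float] = None) -> None:
    Path(path).write_text(json.dumps(manifest_dict(trajectory, wall_time),
                                     indent=2))


def trajectory_frame(trajectory: Trajectory) -> pd.DataFrame:
    """Tidy observable series: time, normalized_time, observable, value."""
    return pd.DataFrame({
        "time": trajectory.times,
        "normalized_time": trajectory.taus,
        "observable": "renewed_fraction",
        "value": trajectory.renewed_frac,
    })


def state_frame(state: TissueState) -> pd.DataFrame:
    """Per-site snapshot table (joinable with the grid export)."""
    g = state.grid
    return pd.DataFrame({
        "site": np.arange(g.n_sites),
        "x": g.x, "y": g.y,
        "region": np.where(g.region == 1, "LIMBUS", "CORNEA"),
        "cell_type": np.choose(state.cell_type, ["S", "P_L", "P_C"]),
        "clone": state.clone,
        "divisions": state.divisions,
    })


def clone_matrix(state: TissueState) -> np.ndarray:
    """Dense clone-label matrix: -2 outside the tissue, -1 unlabeled."""
    g = state.grid
    off = g.index_map.shape[0] // 2
    mat = np.full(g.index_map.shape, -2, dtype=np.int32)
    mat[g.x + off, g.y + off] = state.clone
    return mat
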