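"""Serialization of analysis artifacts: CSV/JSON writers and the run manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Trajectory
from .ocp import OCSolution
from .protocols import PiecewiseProtocol

__all__ = [
    "write_trajectory_csv", "write_sweep_csv", "write_heatmap_csv",
    "write_mutation_sweep_csv", "save_solution", "load_solution",
    "save_protocol", "write_manifest",
]

_INF_LABEL = "inf"


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    """Trajectory as CSV with header ``t,N1,N2,K,u,v``."""
    path = Path(path)
    traj.to_dataframe().to_csv(path, index=False)
    return path


def _ts_column(df: pd.DataFrame) -> pd.Series:
    # render unreachable cells as a stable sentinel string
    return df["t_s"].map(lambda x: _INF_LABEL if np.isinf(x) else repr(float(x)))


def write_sweep_csv(sweep: pd.DataFrame, path: str | Path) -> Path:
    """Dose sweep as CSV ``u,t_s``."""
    path = Path(path)
    out = pd.DataFrame({"u": sweep["u"], "t_s": _ts_column(sweep)})
    out.to_csv(path, index=False)
    return path


def write_heatmap_csv(heatmap: pd.DataFrame, path: str | Path) -> Path:
    """Dose heatmap as long CSV ``u,v,t_s,reached``."""
    path = Path(path)
    out = heatmap.copy()
    out["t_s"] = _ts_column(out)
    out.to_csv(path, index=False, columns=["u", "v", "t_s", "reached"])
    return path


def write_mutation_sweep_csv(sweep: pd.DataFrame, path: str | Path) -> Path:
    """Mutation-rate sweep as CSV ``tau1,tau2,t_s_max,u_star``."""
    path = Path(path)
    out = sweep.copy()
    out["t_s_max"] = out["t_s_max"].map(
        lambda x: _INF_LABEL if np.isinf(x) else repr(float(x)))
    out.to_csv(path, index=False, columns=["tau1", "tau2", "t_s_max", "u_star"])
    return path


def save_solution(solution: OCSolution, path: str | Path) -> Path:
    """Solved schedule as JSON (lossless round trip via :func:`load_solution`)."""
    path = Path(path)
    path.write_text(json.dumps(solution.as_dict(), indent=1, sort_keys=True))
    return path


def load_solution(path: str | Path) -> OCSolution:
    return OCSolution.from_dict(json.loads(Path(path).read_text()))


def save_protocol(protocol: PiecewiseProtocol, path: str | Path) -> Path:
    """Piecewise protocol as JSON: switch times, levels, objective, gap."""
    payload = {
        "switch_times": list(protocol.switch_times),
        "levels": list(protocol.levels),
        "horizon": protocol.horizon,
        "v": protocol.v,
        "objective": protocol.objective.as_dict(),
        "gap_pct": protocol.gap_pct,
        "average_dose_pct": protocol.average_dose_pct,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def config_hash(config) -> str:
    """Stable short hash of a run configuration's content."""
    canonical = json.dumps(config.as_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(config, out_dir: str | Path, command: str,
                   extra: dict | None = None) -> Path:
    """Write the run manifest (config hash, seed, tool version, command)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "chemosched",
        "version": __version__,
        "command": command,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config.as_dict(),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return path
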