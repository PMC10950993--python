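"""CSV/JSON readers and writers for the package's tabular artifacts.

All schemas are plain CSV with fixed headers; readers validate headers and
basic invariants (monotone times, non-empty series) and raise ``ValueError``
on malformed input.  Floating-point columns are written with repr-level
precision so a write-read round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import GrowthSeries
from .moran import EnsembleSummary, Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_ensemble",
    "write_final_states",
    "write_growth_series",
    "read_growth_series",
    "write_json",
    "read_json",
]

_FLOAT_FMT = "%.17g"


def write_trajectory(
    traj, path, hours_per_division: float | None = None
) -> None:
    """Trajectory (stochastic or expected) to CSV."""
    traj.to_frame(hours_per_division).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    needed = {"division_index", "n_healthy", "n_cancer", "n_mutant"}
    if not needed.issubset(df.columns):
        raise ValueError(f"trajectory CSV needs columns {sorted(needed)}")
    states = df[["n_healthy", "n_cancer", "n_mutant"]].to_numpy()
    if np.issubdtype(states.dtype, np.floating) and np.allclose(states, np.round(states)):
        states = np.round(states).astype(np.int64)
    N = int(states[0].sum())
    return Trajectory(states=states, N=N, seed=(-1, -1), absorbed_at=None)


def write_ensemble(
    ens: EnsembleSummary, path, hours_per_division: float | None = None
) -> None:
    ens.to_frame(hours_per_division).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_final_states(ens: EnsembleSummary, path) -> None:
    ens.final_frame().to_csv(path, index=False)


def write_growth_series(series_list, path) -> None:
    """One or more growth series into a single long-format CSV."""
    if isinstance(series_list, GrowthSeries):
        series_list = [series_list]
    frames = [s.to_frame() for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_growth_series(path, label: str | None = None) -> GrowthSeries:
    df = pd.read_csv(path)
    needed = {"time_days", "size"}
    if not needed.issubset(df.columns):
        raise ValueError(f"growth series CSV needs columns {sorted(needed)}")
    if df.empty:
        raise ValueError("growth series CSV is empty")
    return GrowthSeries.from_frame(df, label=label)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
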