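"""Result and trajectory I/O with a documented, asserted CSV schema."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import FishState

__all__ = ["METRICS_SCHEMA", "TRAJECTORY_SCHEMA", "write_results",
           "write_trajectory", "read_trajectory"]

#: tidy per-hunt metrics table: one row per (model, hunt) or per start value
METRICS_SCHEMA = {
    "model": "controller kind (string)",
    "hunt": "hunt / start-value index (int)",
    "outcome": "strike | exhausted",
    "n_bouts": "bouts issued before termination (int)",
    "energy": "total mechanical energy of the hunt, joules",
}

#: trajectory CSV columns; fish columns present only when state is recorded
TRAJECTORY_SCHEMA = {
    "time_s": "sample time, s",
    "prey_x_mm": "prey x, mm (world frame)",
    "prey_y_mm": "prey y, mm",
    "prey_z_mm": "prey z, mm",
    "fish_x_mm": "fish x, mm (optional)",
    "fish_y_mm": "fish y, mm (optional)",
    "fish_z_mm": "fish z, mm (optional)",
    "yaw_deg": "fish yaw, degrees (optional)",
    "pitch_deg": "fish pitch, degrees (optional)",
}


def write_results(metrics: pd.DataFrame, summary: dict, out_dir) -> dict:
    """Write metrics.csv and summary.json; byte-identical for identical runs.

    Rows are sorted on the schema key columns and floats serialised at
    fixed precision so repeated runs diff clean.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    required = [c for c in METRICS_SCHEMA if c in metrics.columns]
    metrics = metrics.copy()
    sort_cols = [c for c in ("model", "hunt") if c in metrics.columns]
    if sort_cols:
        metrics = metrics.sort_values(sort_cols, kind="mergesort")
    csv_path = out / "metrics.csv"
    metrics.to_csv(csv_path, index=False, float_format="%.10g",
                   lineterminator="\n")
    json_path = out / "summary.json"
    json_path.write_text(json.dumps(summary, sort_keys=True, indent=2,
                                    default=_jsonify) + "\n")
    return {"metrics": csv_path, "summary": json_path, "columns": required}


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_trajectory(path, prey: np.ndarray, frame_rate: float = 62.5,
                     fish_states=None):
    """Write one trajectory CSV (see TRAJECTORY_SCHEMA)."""
    prey = np.asarray(prey, dtype=float)
    times = np.arange(len(prey)) / frame_rate
    data = {"time_s": times, "prey_x_mm": prey[:, 0],
            "prey_y_mm": prey[:, 1], "prey_z_mm": prey[:, 2]}
    if fish_states is not None:
        pos = np.array([s.position for s in fish_states])
        data.update(fish_x_mm=pos[:, 0], fish_y_mm=pos[:, 1],
                    fish_z_mm=pos[:, 2],
                    yaw_deg=[s.yaw for s in fish_states],
                    pitch_deg=[s.pitch for s in fish_states])
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g",
                              lineterminator="\n")


def read_trajectory(path):
    """Read a trajectory CSV; returns (times, prey, fish_states or None)."""
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "prey_x_mm", "prey_y_mm", "prey_z_mm")
               if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {missing}")
    prey = df[["prey_x_mm", "prey_y_mm", "prey_z_mm"]].to_numpy()
    fish = None
    if {"fish_x_mm", "yaw_deg", "pitch_deg"} <= set(df.columns):
        fish = [FishState(position=row[["fish_x_mm", "fish_y_mm",
                                        "fish_z_mm"]].to_numpy(dtype=float),
                          yaw=row.yaw_deg, pitch=row.pitch_deg)
                for _, row in df.iterrows()]
    return df["time_s"].to_numpy(), prey, fish
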