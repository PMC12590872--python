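"""File interfaces: velocity/dF-F/events/labels tables, configs, reports.

All on-disk formats are plain text (CSV, YAML, JSON) except the optional
HDF5 route for large dF/F matrices.  Velocity is rectified to unsigned
speed on load (encoders may report signed velocity)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


def write_velocity_csv(path, velocity: np.ndarray, frame_rate_hz: float) -> None:
    frames = np.arange(len(velocity))
    pd.DataFrame({
        "frame": frames,
        "time_s": frames / frame_rate_hz,
        "velocity_cm_s": np.asarray(velocity, float),
    }).to_csv(path, index=False)


def read_velocity_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return np.abs(df["velocity_cm_s"].to_numpy(float))


def write_dff(path, dff: np.ndarray, neuron_ids=None) -> None:
    """dF/F as frames x neurons CSV (header = neuron ids) or HDF5 by suffix."""
    path = Path(path)
    dff = np.asarray(dff, float)
    ids = neuron_ids if neuron_ids is not None else [f"n{i}" for i in range(len(dff))]
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("dff", data=dff.T)
            f.create_dataset("neuron_ids", data=np.asarray(ids, dtype="S"))
    else:
        pd.DataFrame(dff.T, columns=ids).to_csv(path, index=False)


def read_dff(path) -> tuple[np.ndarray, list[str]]:
    """Read dF/F; returns (neurons x frames, neuron ids)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            dff = f["dff"][()].T
            ids = [s.decode() for s in f["neuron_ids"][()]]
        return dff, ids
    df = pd.read_csv(path)
    return df.to_numpy(float).T, list(df.columns)


def write_events_csv(path, event_trains: list[np.ndarray], frame_rate_hz: float) -> None:
    rows = [(i, int(f), f / frame_rate_hz)
            for i, ev in enumerate(event_trains) for f in ev]
    pd.DataFrame(rows, columns=["neuron", "frame", "time_s"]).to_csv(path, index=False)


def read_events_csv(path, n_neurons: int) -> list[np.ndarray]:
    df = pd.read_csv(path)
    return [df.loc[df["neuron"] == i, "frame"].to_numpy(int)
            for i in range(n_neurons)]


def write_boutset_csv(path, boutset) -> None:
    rows = [("onset", int(f), f / boutset.frame_rate_hz) for f in boutset.onsets]
    rows += [("offset", int(f), f / boutset.frame_rate_hz) for f in boutset.offsets]
    rows.sort(key=lambda r: r[1])
    pd.DataFrame(rows, columns=["event_type", "frame", "time_s"]).to_csv(
        path, index=False)


def write_labels_csv(path, labels_by_day: dict[int, np.ndarray]) -> None:
    rows = [(i, day, lab) for day, labels in sorted(labels_by_day.items())
            for i, lab in enumerate(labels)]
    pd.DataFrame(rows, columns=["neuron", "day", "type"]).to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_config(path, config: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def save_report_json(path, report: dict) -> None:
    with open(path, "w") as f:
        json.dump(_jsonable(report), f, indent=1, allow_nan=False)
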