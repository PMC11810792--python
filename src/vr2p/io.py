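"""File exchange: HDF5 movies, CSV event/velocity logs, JSON ground truth."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .imaging_pipeline import ChessboardMovie
from .synthetic_data import GroundTruth, SessionLog, SimConfig

__all__ = [
    "save_movie_hdf5", "load_movie_hdf5",
    "save_session_csv", "load_session_csv",
    "save_ground_truth_json", "load_ground_truth_json",
]


def save_movie_hdf5(movie: ChessboardMovie, path: str | Path) -> None:
    """Write a chessboard movie as /subfields/<r>_<c>/frames plus /meta."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("subfields")
        for (r, c), stack in movie.frames.items():
            sub = grp.create_group(f"{r}_{c}")
            sub.create_dataset("frames", data=stack, compression="gzip")
            if (r, c) in movie.subfield_center_xyz:
                sub.create_dataset("center_xyz", data=movie.subfield_center_xyz[(r, c)])
        meta = f.create_group("meta")
        meta.attrs["grid_rows"], meta.attrs["grid_cols"] = movie.grid_shape
        meta.attrs["frame_rate"] = movie.frame_rate
        meta.attrs["fill_value"] = movie.fill_value


def load_movie_hdf5(path: str | Path) -> ChessboardMovie:
    with h5py.File(path, "r") as f:
        frames, centers = {}, {}
        for name, sub in f["subfields"].items():
            r, c = map(int, name.split("_"))
            frames[(r, c)] = sub["frames"][()]
            if "center_xyz" in sub:
                centers[(r, c)] = sub["center_xyz"][()]
        meta = f["meta"].attrs
        return ChessboardMovie(
            grid_shape=(int(meta["grid_rows"]), int(meta["grid_cols"])),
            frames=frames, frame_rate=float(meta["frame_rate"]),
            subfield_center_xyz=centers, fill_value=float(meta["fill_value"]),
        )


def save_session_csv(session: SessionLog, events_path: str | Path,
                     velocity_path: str | Path) -> None:
    """Events as (time, kind, zone) CSV; velocity/position as a second CSV."""
    session.events.to_csv(events_path, index=False)
    pd.DataFrame({
        "time": np.arange(len(session.velocity)) * session.dt,
        "velocity": session.velocity,
        "position": session.position,
    }).to_csv(velocity_path, index=False)


def load_session_csv(events_path: str | Path, velocity_path: str | Path,
                     config: SimConfig | None = None) -> SessionLog:
    events = pd.read_csv(events_path)
    vel = pd.read_csv(velocity_path)
    dt = float(vel.time.iloc[1] - vel.time.iloc[0])
    return SessionLog(
        events=events, velocity=vel.velocity.to_numpy(),
        position=vel.position.to_numpy(), dt=dt,
        duration=float(vel.time.iloc[-1]) + dt, config=config,
    )


def save_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {}
    for f in dataclasses.fields(truth):
        value = getattr(truth, f.name)
        if isinstance(value, np.ndarray):
            payload[f.name] = value.tolist()
        elif isinstance(value, dict):
            payload[f.name] = {str(k): v for k, v in value.items()}
        else:
            payload[f.name] = value
    Path(path).write_text(json.dumps(payload))


def load_ground_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    arrays = {
        name: np.asarray(payload[name])
        for name in ("on_amp", "ramp_amp_aver", "ramp_amp_ctrl",
                     "reinf_first_amp", "reinf_second_amp", "reinf_tau",
                     "locomotion_gain", "soma_xyz")
    }
    return GroundTruth(
        **arrays,
        hub_flag=np.asarray(payload["hub_flag"], dtype=bool),
        trial_class={int(k): v for k, v in payload["trial_class"].items()},
        planted_lead=float(payload["planted_lead"]),
        zone_pref=np.asarray(payload["zone_pref"]) if payload.get("zone_pref") is not None else None,
    )
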