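"""Session archives (HDF5) and plain-text exports (CSV).

The HDF5 layout mirrors the session record: /trajectory (time_s, x_cm, y_cm),
/goals, /spikes (neuron_id, time_ms), /da (per-frame concentration and gain),
/events (time_s, kind, info), /weights (snapshot times and vectors over the
fixed plastic-edge list), plus the seed and the JSON-encoded config as
attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .embodiment import Pose, SessionResult
from .netcore import SpikeRecord
from .workbench import Trajectory, trajectory_from_frame

__all__ = [
    "save_session",
    "load_session",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_spikes_csv",
    "write_weights_csv",
    "write_da_csv",
]


def save_session(result: SessionResult, path, config_dict: dict | None = None,
                 ee_pre: np.ndarray | None = None,
                 ee_post: np.ndarray | None = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.attrs["seed"] = result.seed
        h5.attrs["reward_count"] = result.reward_count
        if config_dict is not None:
            h5.attrs["config_json"] = json.dumps(config_dict)
        g = h5.create_group("trajectory")
        g.create_dataset("time_s", data=result.times_s)
        g.create_dataset("xy_cm", data=result.positions_cm)
        h5.create_dataset("goals/xy_cm", data=result.goals_cm)
        h5.create_dataset("da/concentration", data=result.da_trace)
        h5.create_dataset("da/nmda_gain", data=result.gain_trace)
        ev = h5.create_group("events")
        ev.create_dataset("time_s",
                          data=np.array([e[0] for e in result.events]))
        ev.create_dataset("kind", data=np.array(
            [e[1] for e in result.events], dtype=h5py.string_dtype()))
        ev.create_dataset("info", data=np.array(
            [json.dumps(e[2], default=float) for e in result.events],
            dtype=h5py.string_dtype()))
        if result.spikes is not None:
            h5.create_dataset("spikes/neuron_id", data=result.spikes.neuron_ids)
            h5.create_dataset("spikes/time_ms", data=result.spikes.times_ms)
        w = h5.create_group("weights")
        w.create_dataset("time_s", data=np.array(
            [s[0] for s in result.weight_snapshots]))
        w.create_dataset("ee_weights", data=np.stack(
            [s[1] for s in result.weight_snapshots]))
        if ee_pre is not None:
            w.create_dataset("ee_pre", data=ee_pre)
            w.create_dataset("ee_post", data=ee_post)
        fp = h5.create_group("final_pose")
        fp.attrs["x_cm"], fp.attrs["y_cm"] = map(float,
                                                 result.final_pose.position_cm)
        fp.attrs["heading_rad"] = result.final_pose.heading_rad
        fp.attrs["speed_cms"] = result.final_pose.speed_cms


def load_session(path) -> SessionResult:
    with h5py.File(path, "r") as h5:
        events = [(float(t), k.decode() if isinstance(k, bytes) else k,
                   json.loads(i))
                  for t, k, i in zip(h5["events/time_s"][:],
                                     h5["events/kind"][:],
                                     h5["events/info"][:])]
        spikes = None
        if "spikes" in h5:
            spikes = SpikeRecord(h5["spikes/neuron_id"][:],
                                 h5["spikes/time_ms"][:])
        snaps = list(zip(h5["weights/time_s"][:].tolist(),
                         list(h5["weights/ee_weights"][:])))
        fp = h5["final_pose"]
        pose = Pose(np.array([fp.attrs["x_cm"], fp.attrs["y_cm"]]),
                    float(fp.attrs["heading_rad"]),
                    float(fp.attrs["speed_cms"]))
        return SessionResult(
            times_s=h5["trajectory/time_s"][:],
            positions_cm=h5["trajectory/xy_cm"][:],
            goals_cm=h5["goals/xy_cm"][:],
            da_trace=h5["da/concentration"][:],
            gain_trace=h5["da/nmda_gain"][:],
            events=events,
            spikes=spikes,
            weight_snapshots=snaps,
            seed=int(h5.attrs["seed"]),
            final_pose=pose,
            reward_count=int(h5.attrs["reward_count"]),
        )


def write_trajectory_csv(obj, path) -> None:
    """Write a session or Trajectory as time_s,x_cm,y_cm,event CSV."""
    df = obj.trajectory_frame() if isinstance(obj, SessionResult) \
        else obj.to_frame()
    df.to_csv(path, index=False)


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path, keep_default_na=False)
    return trajectory_from_frame(df)


def write_spikes_csv(spikes: SpikeRecord, path) -> None:
    pd.DataFrame({"neuron_id": spikes.neuron_ids,
                  "time_ms": spikes.times_ms}).to_csv(path, index=False)


def write_weights_csv(ee_pre, ee_post, weights, path) -> None:
    pd.DataFrame({"pre": ee_pre, "post": ee_post,
                  "weight": weights}).to_csv(path, index=False)


def write_da_csv(times_s, concentration, path) -> None:
    pd.DataFrame({"time_ms": np.asarray(times_s) * 1000.0,
                  "concentration": concentration}).to_csv(path, index=False)
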