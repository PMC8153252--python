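"""Session persistence: HDF5 containers, CSV export, YAML configs."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .activity import PopulationActivity
from .behavior import BehaviorTraces

__all__ = ["save_session", "load_session", "export_behavior_csv",
           "export_activity_csv", "load_config"]

_BEHAVIOR_FIELDS = ("time", "state", "loco", "wmi", "phi", "wamp", "wsp",
                    "pupil")


def save_session(path, behavior: BehaviorTraces | None = None,
                 activity: PopulationActivity | None = None) -> None:
    """Write behavior and/or activity to an HDF5 session container.

    Layout: datasets /behavior/<channel>, /activity/rates,
    /activity/positions; attributes sampling_rate (behavior), bin and kind
    (activity).
    """
    with h5py.File(path, "w") as f:
        if behavior is not None:
            g = f.create_group("behavior")
            for name in _BEHAVIOR_FIELDS:
                g.create_dataset(name, data=np.asarray(getattr(behavior, name)))
            g.attrs["sampling_rate"] = behavior.sampling_rate
        if activity is not None:
            g = f.create_group("activity")
            g.create_dataset("rates", data=activity.rates)
            if activity.positions is not None:
                g.create_dataset("positions", data=activity.positions)
            g.attrs["bin"] = activity.bin
            g.attrs["kind"] = activity.kind


def load_session(path) -> tuple[BehaviorTraces | None, PopulationActivity | None]:
    """Read a session container written by :func:`save_session`."""
    behavior = activity = None
    with h5py.File(path, "r") as f:
        if "behavior" in f:
            g = f["behavior"]
            behavior = BehaviorTraces(
                **{name: g[name][()] for name in _BEHAVIOR_FIELDS},
                sampling_rate=float(g.attrs["sampling_rate"]),
            )
        if "activity" in f:
            g = f["activity"]
            activity = PopulationActivity(
                rates=g["rates"][()],
                positions=g["positions"][()] if "positions" in g else None,
                bin=float(g.attrs["bin"]),
                kind=str(g.attrs["kind"]),
            )
    return behavior, activity


def export_behavior_csv(behavior: BehaviorTraces, path) -> None:
    pd.DataFrame({n: getattr(behavior, n) for n in _BEHAVIOR_FIELDS}).to_csv(
        path, index=False)


def export_activity_csv(activity: PopulationActivity, path) -> None:
    df = pd.DataFrame(activity.rates.T,
                      columns=[f"cell_{i}" for i in range(activity.n_neurons)])
    df.insert(0, "time_s", (np.arange(activity.n_bins) + 0.5) * activity.bin)
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    """YAML configuration file -> dict (empty file -> empty dict)."""
    with open(path) as f:
        return yaml.safe_load(f) or {}


def ensure_parent(path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p
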