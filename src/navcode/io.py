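"""HDF5/CSV containers shared across stages.

The trace container mirrors Suite2p-style exports: datasets ``F_cell``,
``F_np`` (neurons x time, a.u.), scalar ``rate_hz`` and ``neuron_ids``.
Behavior travels as CSV with columns t_s, position_cm, speed_cm_s, lap_id.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .behavior_analysis import compute_speed, segment_laps
from .datatypes import BehaviorTrack, TraceSet

__all__ = [
    "write_traceset",
    "read_traceset",
    "write_behavior_csv",
    "read_behavior_csv",
]


def write_traceset(path, traces: TraceSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("F_cell", data=traces.F_cell)
        f.create_dataset("F_np", data=traces.F_np)
        f.create_dataset("rate_hz", data=traces.rate_hz)
        f.create_dataset("neuron_ids", data=np.asarray(traces.neuron_ids))


def read_traceset(path) -> TraceSet:
    with h5py.File(path, "r") as f:
        return TraceSet(
            F_cell=f["F_cell"][()],
            F_np=f["F_np"][()],
            rate_hz=float(f["rate_hz"][()]),
            neuron_ids=f["neuron_ids"][()] if "neuron_ids" in f else None,
        )


def write_behavior_csv(path, track: BehaviorTrack) -> None:
    pd.DataFrame(
        {
            "t_s": track.t,
            "position_cm": track.position_cm,
            "speed_cm_s": track.speed_cm_s,
            "lap_id": track.lap_id,
        }
    ).to_csv(path, index=False)


def read_behavior_csv(path, track_length_cm: float) -> BehaviorTrack:
    """Load behavior; speed and lap_id are recomputed when absent."""
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    pos = df["position_cm"].to_numpy()
    if "speed_cm_s" in df.columns:
        speed = df["speed_cm_s"].to_numpy()
    else:
        speed = compute_speed(t, pos, track_length_cm)
    if "lap_id" in df.columns:
        lap = df["lap_id"].to_numpy().astype(int)
    else:
        lap = segment_laps(pos, track_length_cm)
    return BehaviorTrack(
        t=t, position_cm=pos, speed_cm_s=speed, lap_id=lap,
        track_length_cm=track_length_cm,
    )
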