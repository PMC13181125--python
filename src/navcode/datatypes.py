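"""Shared in-memory containers for imaging sessions.

The containers are deliberately thin: arrays plus the metadata needed to
interpret them (sampling rate, track geometry).  Tabular data (stimulus
tables, ground truth, region counts) travel as pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TraceSet:
    """Per-neuron raw and neuropil fluorescence, neurons x time, in a.u."""

    F_cell: np.ndarray
    F_np: np.ndarray
    rate_hz: float
    neuron_ids: np.ndarray = None

    def __post_init__(self):
        self.F_cell = np.asarray(self.F_cell, dtype=float)
        self.F_np = np.asarray(self.F_np, dtype=float)
        if self.F_cell.shape != self.F_np.shape:
            raise ValueError(
                f"F_cell {self.F_cell.shape} and F_np {self.F_np.shape} "
                "must have congruent shapes"
            )
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.F_cell.shape[0])
        self.neuron_ids = np.asarray(self.neuron_ids)

    @property
    def n_neurons(self) -> int:
        return self.F_cell.shape[0]

    @property
    def n_samples(self) -> int:
        return self.F_cell.shape[1]


@dataclass
class DffSet:
    """Normalized fluorescence (dF/F0) with its baseline and validity flags."""

    dff: np.ndarray
    F0: np.ndarray
    valid: np.ndarray
    rate_hz: float


@dataclass
class EventSet:
    """Non-negative deconvolved event amplitudes (dF/F units per frame)."""

    events: np.ndarray
    gamma: float
    rate_hz: float

    def __post_init__(self):
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")


@dataclass
class BehaviorTrack:
    """Time-aligned treadmill behavior on a circular belt.

    position_cm lives on [0, track_length_cm); lap_id increments by one at
    each wrap of the belt.
    """

    t: np.ndarray
    position_cm: np.ndarray
    speed_cm_s: np.ndarray
    lap_id: np.ndarray
    track_length_cm: float
    cue_positions_cm: tuple = (50.0, 100.0)
    reward_position_cm: float = 0.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.position_cm = np.asarray(self.position_cm, dtype=float)
        self.speed_cm_s = np.asarray(self.speed_cm_s, dtype=float)
        self.lap_id = np.asarray(self.lap_id, dtype=int)
        n = len(self.t)
        if not (len(self.position_cm) == len(self.speed_cm_s) == len(self.lap_id) == n):
            raise ValueError("behavior arrays must share one length")

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def n_laps(self) -> int:
        """Number of belt wraps observed (completed laps)."""
        return int(self.lap_id.max()) if len(self.lap_id) else 0


@dataclass
class RunningEpochs:
    """Disjoint, sorted [start_s, end_s) running intervals plus a sample mask."""

    intervals: np.ndarray  # (n, 2) start/end in seconds
    mask: np.ndarray  # boolean per behavior sample

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.intervals.shape[0]

    def total_duration_s(self) -> float:
        if self.n_epochs == 0:
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))


@dataclass
class PixelMovie:
    """Widefield movie, frames x height x width."""

    frames: np.ndarray
    rate_hz: float
    stim_freq_hz: float
    n_trials: int = 1

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be time x height x width")
        if not self.stim_freq_hz < self.rate_hz / 2.0:
            raise ValueError("stimulus frequency must be below Nyquist")
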