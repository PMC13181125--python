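"""Treadmill behavior: running epochs, lap segmentation, occupancy, speed score.

Running epochs are maximal stretches with speed >= 5 cm/s; stretches closer
than 0.5 s are merged first and only merged epochs of at least 1 s survive.
Laps are belt wraps (position dropping by more than half the track between
consecutive samples).  Occupancy is time per position bin inside running
epochs, normalized to 1.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import pearsonr

from .datatypes import BehaviorTrack, RunningEpochs

__all__ = [
    "compute_speed",
    "detect_running_epochs",
    "segment_laps",
    "occupancy",
    "speed_score",
    "position_bins",
]

MIN_EPOCH_S = 1.0
MIN_SPEED_CM_S = 5.0
MERGE_GAP_S = 0.5
N_BINS = 100


def compute_speed(
    t: np.ndarray, position_cm: np.ndarray, track_length_cm: float, smooth_s: float = 0.5
) -> np.ndarray:
    """Speed from wrap-corrected position differences, boxcar-smoothed.

    Backward differences with the first sample copied from the second; the
    belt wrap is corrected by taking the smallest forward displacement.
    """
    t = np.asarray(t, dtype=float)
    pos = np.asarray(position_cm, dtype=float)
    if len(t) < 2:
        return np.zeros_like(pos)
    dpos = np.diff(pos)
    dpos = (dpos + track_length_cm / 2.0) % track_length_cm - track_length_cm / 2.0
    dt = np.diff(t)
    speed = np.empty_like(pos)
    speed[1:] = dpos / dt
    speed[0] = speed[1]
    rate = 1.0 / float(np.median(dt))
    width = max(1, int(round(smooth_s * rate)))
    if width > 1:
        kernel = np.ones(width) / width
        speed = np.convolve(speed, kernel, mode="same")
    return speed


def detect_running_epochs(
    track: BehaviorTrack,
    min_dur_s: float = MIN_EPOCH_S,
    min_speed: float = MIN_SPEED_CM_S,
    merge_gap_s: float = MERGE_GAP_S,
) -> RunningEpochs:
    """Find running epochs: merge sub-gap pauses, then keep epochs >= min_dur_s."""
    n = track.n_samples
    if n == 0:
        return RunningEpochs(intervals=np.empty((0, 2)), mask=np.zeros(0, dtype=bool))
    dt = 1.0 / track.rate_hz
    fast = track.speed_cm_s >= min_speed

    # maximal runs of fast samples as [start, end) sample indices
    edges = np.flatnonzero(np.diff(np.concatenate(([0], fast.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]

    # merge runs separated by less than merge_gap_s BEFORE the duration filter
    merged = []
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) * dt < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    mask = np.zeros(n, dtype=bool)
    intervals = []
    for s, e in merged:
        if (e - s) * dt >= min_dur_s:
            mask[s:e] = True
            intervals.append([track.t[s], track.t[s] + (e - s) * dt])
    return RunningEpochs(
        intervals=np.asarray(intervals, dtype=float).reshape(-1, 2), mask=mask
    )


def segment_laps(position_cm: np.ndarray, track_length_cm: float) -> np.ndarray:
    """Lap index per sample from monotone belt progress.

    Position differences are wrap-corrected with an L/2 hysteresis (a jump
    of more than half the track is read as a wrap), accumulated into total
    progress, and the lap index is the number of whole track lengths in the
    running maximum of that progress.  Back-and-forth jitter across the
    0 cm seam therefore never produces spurious laps: a full extra
    traversal is required for each increment, and lap_id is non-decreasing
    by construction.
    """
    pos = np.asarray(position_cm, dtype=float)
    if len(pos) == 0:
        return np.zeros(0, dtype=int)
    L = track_length_cm
    d = np.diff(pos)
    d = (d + L / 2.0) % L - L / 2.0
    progress = pos[0] + np.concatenate(([0.0], np.cumsum(d)))
    progress = np.maximum.accumulate(progress)
    lap = np.floor(progress / L).astype(int)
    return lap - lap[0]


def position_bins(position_cm: np.ndarray, track_length_cm: float, n_bins: int) -> np.ndarray:
    """Half-open 0-based bin index per sample; position exactly L maps to bin 0."""
    b = np.floor(np.asarray(position_cm) / track_length_cm * n_bins).astype(int)
    return b % n_bins


def occupancy(
    track: BehaviorTrack, epochs: RunningEpochs, n_bins: int = N_BINS
) -> np.ndarray:
    """Fraction of running time spent in each position bin; sums to 1."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    sel = epochs.mask
    if not np.any(sel):
        raise ValueError("no running time: occupancy undefined")
    bins = position_bins(track.position_cm[sel], track.track_length_cm, n_bins)
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    return counts / counts.sum()


def speed_score(events: np.ndarray, speed: np.ndarray) -> float:
    """Pearson correlation between instantaneous event amplitude and speed.

    Returns NaN for constant inputs (correlation undefined).
    """
    events = np.asarray(events, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if events.shape != speed.shape:
        raise ValueError("events and speed must be aligned")
    if len(events) < 2:
        raise ValueError("need at least 2 samples")
    if np.std(events) == 0 or np.std(speed) == 0:
        return float("nan")
    return float(pearsonr(events, speed)[0])
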