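"""Position tuning: occupancy-normalized maps, circular-shift shuffle test,
field detection, spatial information, and trial reliability.

The belt is divided into 100 position bins (1.5 cm at 150 cm).  Per trial
(lap) and bin, summed deconvolved activity is divided by the time spent in
the bin (running epochs only) and smoothed with a circular Gaussian
(SD = 3 bins).  A neuron is position-tuned when (a) the lower bound of its
trial-averaged map (mean - SEM) exceeds, in at least one bin, the per-bin
97.5th percentile of 200 maps recomputed after circular time shifts of its
activity, and (b) it has at least one field: a circularly contiguous region
above 30% of the peak-to-baseline range, 15-120 cm wide, present in more
than one third of trials.

Spatial information is the activity-weighted log-ratio
SI = sum_i p_i (f_i/f) log2(f_i/f) in bits per event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .behavior_analysis import position_bins
from .datatypes import BehaviorTrack, RunningEpochs

__all__ = [
    "TuningProfile",
    "TuningStats",
    "Field",
    "SessionBinning",
    "tuning_map",
    "shuffle_test",
    "detect_fields",
    "spatial_information",
    "trial_correlation",
    "classify_position_tuned",
    "analyze_position_tuning",
]

N_BINS = 100
SMOOTH_SD_BINS = 3.0
N_SHUFFLES = 200
MIN_SHIFT_S = 20.0
SHUFFLE_PCT = 97.5
FIELD_FRAC = 0.3
MIN_FIELD_CM = 15.0
MAX_FIELD_CM = 120.0
FIELD_PRESENCE = 1.0 / 3.0


@dataclass
class TuningProfile:
    """Occupancy-normalized activity maps for one neuron (events/s)."""

    per_trial_map: np.ndarray  # trials x bins, smoothed, NaN where unvisited
    mean_map: np.ndarray
    sem_map: np.ndarray
    p_occ: np.ndarray
    bin_size_cm: float

    @property
    def n_bins(self) -> int:
        return len(self.mean_map)

    @property
    def n_trials(self) -> int:
        return self.per_trial_map.shape[0]


@dataclass
class Field:
    """One detected tuning field on the circular belt."""

    peak_pos_cm: float
    width_cm: float
    bins: np.ndarray  # bin indices, circular order
    peak_rate: float
    presence_frac: float


@dataclass
class TuningStats:
    """Per-neuron position-tuning summary."""

    is_tuned: bool
    si_bits_per_event: float
    width_cm: float
    n_fields: int
    peak_pos_cm: float
    trial_corr: float
    peak_amp_pct: float


def _circular_gaussian_kernel(n_bins: int, sd_bins: float) -> np.ndarray:
    """n_bins x n_bins circular smoothing matrix; rows sum to 1."""
    idx = np.arange(n_bins)
    d = np.abs(idx[:, None] - idx[None, :])
    d = np.minimum(d, n_bins - d)
    k = np.exp(-(d**2) / (2.0 * sd_bins**2))
    return k / k.sum(axis=1, keepdims=True)


class SessionBinning:
    """Precomputed (trial, bin) assignment of running samples.

    Shuffle tests recompute maps hundreds of times; the behavior-side
    quantities (which sample falls in which trial and bin, time per cell,
    occupancy) never change, so they are computed once here.
    """

    def __init__(
        self,
        track: BehaviorTrack,
        epochs: RunningEpochs,
        n_bins: int = N_BINS,
        smooth_sd_bins: float = SMOOTH_SD_BINS,
    ):
        self.n_bins = n_bins
        self.bin_size_cm = track.track_length_cm / n_bins
        self.dt = 1.0 / track.rate_hz
        self.run_idx = np.flatnonzero(epochs.mask)
        if len(self.run_idx) == 0:
            raise ValueError("no running samples")
        laps = track.lap_id[self.run_idx]
        uniq, trial = np.unique(laps, return_inverse=True)
        self.n_trials = len(uniq)
        if self.n_trials < 2:
            raise ValueError("need at least 2 completed laps")
        bins = position_bins(
            track.position_cm[self.run_idx], track.track_length_cm, n_bins
        )
        self.cell = trial * n_bins + bins
        n_cells = self.n_trials * n_bins
        self.indicator = sparse.csr_matrix(
            (
                np.ones(len(self.cell)),
                (np.arange(len(self.cell)), self.cell),
            ),
            shape=(len(self.cell), n_cells),
        )
        time_flat = np.bincount(self.cell, minlength=n_cells) * self.dt
        self.time_map = time_flat.reshape(self.n_trials, n_bins)
        self.visited = self.time_map > 0
        total = self.time_map.sum(axis=0)
        self.p_occ = total / total.sum()
        self.kernel = _circular_gaussian_kernel(n_bins, smooth_sd_bins)
        # normalized-convolution denominator per trial (0 where undefined)
        self._denom = self.visited.astype(float) @ self.kernel
        self._n_valid = self.visited.sum(axis=0)  # trials visiting each bin

    def trial_maps(self, events_run: np.ndarray) -> np.ndarray:
        """Smoothed per-trial maps; events_run is (neurons, n_run_samples).

        Returns (neurons, trials, bins) with NaN where the normalized
        circular convolution is undefined (no visited bin nearby).
        """
        sums = np.asarray(events_run @ self.indicator).reshape(
            -1, self.n_trials, self.n_bins
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(self.visited, sums / np.where(self.visited, self.time_map, 1.0), 0.0)
        sm = raw @ self.kernel
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(self._denom > 1e-12, sm / self._denom, np.nan)
        # bins a trial never visited stay missing for that trial
        return np.where(self.visited, sm, np.nan)

    def mean_sem(self, trial_maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Across-trial mean and SEM (n-1 normalization), NaN-aware."""
        import warnings

        with warnings.catch_warnings(), np.errstate(invalid="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(trial_maps, axis=-2)
            n = np.sum(np.isfinite(trial_maps), axis=-2)
            sd = np.nanstd(trial_maps, axis=-2, ddof=1)
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
        return mean, sem


def tuning_map(
    events: np.ndarray,
    track: BehaviorTrack,
    epochs: RunningEpochs,
    n_bins: int = N_BINS,
    smooth_sd_bins: float = SMOOTH_SD_BINS,
    binning: SessionBinning | None = None,
) -> TuningProfile:
    """Occupancy-normalized, circularly smoothed tuning profile of one neuron."""
    events = np.asarray(events, dtype=float)
    if events.ndim != 1:
        raise ValueError("tuning_map takes one neuron's event train")
    if len(events) != track.n_samples:
        raise ValueError("events not aligned to track")
    b = binning or SessionBinning(track, epochs, n_bins, smooth_sd_bins)
    maps = b.trial_maps(events[None, b.run_idx])[0]
    mean, sem = b.mean_sem(maps)
    return TuningProfile(
        per_trial_map=maps,
        mean_map=mean,
        sem_map=sem,
        p_occ=b.p_occ,
        bin_size_cm=b.bin_size_cm,
    )


@dataclass
class ShuffleResult:
    """Outcome of the circular-shift significance test."""

    significant: np.ndarray  # per neuron
    lower_bound: np.ndarray  # neurons x bins, mean - SEM
    null_percentile: np.ndarray  # neurons x bins
    n_shuffles: int
    seed: int


def shuffle_test(
    events: np.ndarray,
    track: BehaviorTrack,
    epochs: RunningEpochs,
    n_shuffles: int = N_SHUFFLES,
    min_shift_s: float = MIN_SHIFT_S,
    pct: float = SHUFFLE_PCT,
    seed: int = 0,
    n_bins: int = N_BINS,
    smooth_sd_bins: float = SMOOTH_SD_BINS,
    binning: SessionBinning | None = None,
) -> ShuffleResult:
    """Circular-shift shuffle test for position selectivity.

    Each neuron's event train is circularly shifted in time by an amount
    drawn uniformly from [min_shift_s, T - min_shift_s] (independently per
    neuron and shuffle) and the trial-averaged map recomputed.  A neuron is
    significant when its observed mean - SEM exceeds the per-bin ``pct``-th
    percentile of the shuffled maps in at least one bin.  Shifting is a
    permutation, so each neuron's total event sum is preserved exactly.
    """
    events = np.atleast_2d(np.asarray(events, dtype=float))
    n_neurons, T = events.shape
    rate = track.rate_hz
    if T / rate <= 2 * min_shift_s:
        raise ValueError("session too short for the requested minimum shift")
    b = binning or SessionBinning(track, epochs, n_bins, smooth_sd_bins)
    rng = np.random.default_rng(seed)

    obs_maps = b.trial_maps(events[:, b.run_idx])
    mean, sem = b.mean_sem(obs_maps)
    lower = mean - sem

    lo = int(np.ceil(min_shift_s * rate))
    hi = int(np.floor(T - min_shift_s * rate))
    null = np.empty((n_shuffles, n_neurons, b.n_bins))
    row = np.arange(n_neurons)[:, None]
    for s in range(n_shuffles):
        shifts = rng.integers(lo, hi + 1, size=n_neurons)
        gather = (b.run_idx[None, :] - shifts[:, None]) % T
        shifted = events[row, gather]
        null[s] = b.mean_sem(b.trial_maps(shifted))[0]

    with np.errstate(invalid="ignore"):
        thresh = np.nanpercentile(null, pct, axis=0)
        exceed = lower > thresh
    significant = np.any(np.where(np.isfinite(lower) & np.isfinite(thresh), exceed, False), axis=1)
    return ShuffleResult(
        significant=significant,
        lower_bound=lower,
        null_percentile=thresh,
        n_shuffles=n_shuffles,
        seed=seed,
    )


def _circular_runs(supra: np.ndarray) -> list[np.ndarray]:
    """Maximal circularly contiguous runs of True, as index arrays."""
    n = len(supra)
    if supra.all():
        return [np.arange(n)]
    if not supra.any():
        return []
    # rotate so the sequence starts on a False sample, then scan linearly
    start = int(np.argmin(supra))
    rot = np.roll(supra, -start)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], rot.view(np.int8), [0]))))
    runs = []
    for s, e in zip(edges[::2], edges[1::2]):
        runs.append((np.arange(s, e) + start) % n)
    return runs


def detect_fields(
    profile: TuningProfile,
    frac: float = FIELD_FRAC,
    min_w_cm: float = MIN_FIELD_CM,
    max_w_cm: float = MAX_FIELD_CM,
    presence: float = FIELD_PRESENCE,
) -> list[Field]:
    """Detect tuning fields on the smoothed trial-averaged map.

    Threshold = baseline + frac*(peak - baseline), with baseline the map
    minimum.  Fields are circularly contiguous supra-threshold runs with
    width in [min_w_cm, max_w_cm] that are present (trial mean over the
    field span above the same threshold) in more than ``presence`` of
    trials.  Returned strongest-first.
    """
    m = profile.mean_map
    finite = np.isfinite(m)
    if not finite.any():
        return []
    baseline = np.nanmin(m)
    peak = np.nanmax(m)
    if not peak > baseline:
        return []
    thr = baseline + frac * (peak - baseline)
    supra = np.where(finite, m > thr, False)

    fields = []
    for run in _circular_runs(supra):
        width = len(run) * profile.bin_size_cm
        if not (min_w_cm <= width <= max_w_cm):
            continue
        span = profile.per_trial_map[:, run]
        any_def = np.isfinite(span).any(axis=1)
        per_trial = np.full(profile.n_trials, np.nan)
        if any_def.any():
            per_trial[any_def] = np.nanmean(span[any_def], axis=1)
        n_def = int(any_def.sum())
        if n_def == 0:
            continue
        pres = np.nansum(per_trial > thr) / profile.n_trials
        if pres <= presence:
            continue
        peak_bin = run[int(np.nanargmax(m[run]))]
        fields.append(
            Field(
                peak_pos_cm=(peak_bin + 0.5) * profile.bin_size_cm,
                width_cm=width,
                bins=run,
                peak_rate=float(m[peak_bin]),
                presence_frac=float(pres),
            )
        )
    fields.sort(key=lambda f: f.peak_rate, reverse=True)
    return fields


def spatial_information(p_occ: np.ndarray, mean_map: np.ndarray) -> float:
    """Skaggs spatial information in bits per event.

    SI = sum_i p_i (f_i/f) log2(f_i/f) with f = sum_i p_i f_i; bins with
    f_i = 0 contribute 0.  Returns NaN when the overall mean activity is 0.
    SI is a KL divergence, hence always >= 0 and invariant to scaling the
    map by a positive constant.
    """
    p = np.asarray(p_occ, dtype=float)
    m = np.asarray(mean_map, dtype=float)
    ok = np.isfinite(m) & (p > 0)
    p, m = p[ok], m[ok]
    p = p / p.sum()
    f = np.sum(p * m)
    if not f > 0:
        return float("nan")
    r = m / f
    pos = r > 0
    return float(np.sum(p[pos] * r[pos] * np.log2(r[pos])))


def trial_correlation(per_trial_map: np.ndarray) -> float:
    """Median pairwise Pearson correlation across trials.

    Each pair is correlated over bins valid in both trials; pairs with
    fewer than 2 shared bins or a constant map are skipped.  Returns NaN
    when every pair is skipped.
    """
    maps = np.asarray(per_trial_map, dtype=float)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trials")
    cors = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(maps[i]) & np.isfinite(maps[j])
            if ok.sum() < 2:
                continue
            a, b = maps[i, ok], maps[j, ok]
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            cors.append(np.corrcoef(a, b)[0, 1])
    if not cors:
        return float("nan")
    return float(np.median(cors))


def classify_position_tuned(
    significant: bool, fields: list[Field], max_reported_fields: int = 3
) -> tuple[bool, float, int, float]:
    """Combine shuffle significance with field criteria.

    Returns (is_tuned, width_cm, n_fields, peak_pos_cm); width is the widest
    field, peak position that of the strongest field, and the field count is
    capped at ``max_reported_fields`` for reporting.
    """
    tuned = bool(significant) and len(fields) > 0
    if not tuned:
        return False, float("nan"), 0, float("nan")
    width = max(f.width_cm for f in fields)
    n_fields = min(len(fields), max_reported_fields)
    return True, width, n_fields, fields[0].peak_pos_cm


def analyze_position_tuning(
    events: np.ndarray,
    dff: np.ndarray,
    track: BehaviorTrack,
    epochs: RunningEpochs,
    n_shuffles: int = N_SHUFFLES,
    seed: int = 0,
    n_bins: int = N_BINS,
    smooth_sd_bins: float = SMOOTH_SD_BINS,
):
    """Per-neuron tuning table for a whole session.

    Returns (DataFrame, list[TuningProfile], ShuffleResult).  The DataFrame
    has one row per neuron: is_tuned, si_bits_per_event, width_cm, n_fields,
    peak_pos_cm, trial_corr, peak_amp_pct.
    """
    import pandas as pd

    events = np.atleast_2d(events)
    dff = np.atleast_2d(dff)
    binning = SessionBinning(track, epochs, n_bins, smooth_sd_bins)
    shuffle = shuffle_test(
        events, track, epochs, n_shuffles=n_shuffles, seed=seed,
        n_bins=n_bins, smooth_sd_bins=smooth_sd_bins, binning=binning,
    )
    rows, profiles = [], []
    for i in range(events.shape[0]):
        prof = tuning_map(events[i], track, epochs, binning=binning)
        profiles.append(prof)
        fields = detect_fields(prof)
        tuned, width, n_fields, peak_pos = classify_position_tuned(
            shuffle.significant[i], fields
        )
        rows.append(
            {
                "neuron_id": i,
                "is_tuned": tuned,
                "si_bits_per_event": spatial_information(prof.p_occ, prof.mean_map),
                "width_cm": width,
                "n_fields": n_fields,
                "peak_pos_cm": peak_pos,
                "trial_corr": trial_correlation(prof.per_trial_map),
                "peak_amp_pct": 100.0 * float(np.nanpercentile(dff[i], 95)),
            }
        )
    return pd.DataFrame(rows), profiles, shuffle
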