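"""Bayesian position decoding from deconvolved population activity.

The encoding model is the position-binned expected activity per time bin,
f_i(pos), estimated from training laps (running epochs only).  Decoding
uses the independent-Poisson-form posterior

    P(pos | a) = C (prod_i f_i(pos)^{a_i}) exp(-tau sum_i f_i(pos)),

evaluated in the log domain, with tau the decode time-bin size (one imaging
frame by default) and a_i the neuron's non-negative activity in that time
bin.  The decoded position is the bin with maximal posterior (ties break to
the lowest bin index).  Chance level on the 150 cm belt is 50 bins (75 cm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior_analysis import position_bins
from .datatypes import BehaviorTrack, RunningEpochs

__all__ = [
    "EncodingModel",
    "DecodeResult",
    "fit_encoding",
    "decode",
    "cross_validate",
    "decoding_error",
    "confusion",
    "CHANCE_ERROR_CM",
]

N_BINS = 100
EPS_FRAC = 1e-3
CHANCE_ERROR_CM = 75.0  # 50 bins of 1.5 cm


@dataclass
class EncodingModel:
    """Expected activity per neuron and position bin (events/s), with the
    decode time-bin size tau_s."""

    f: np.ndarray  # neurons x bins, floored at eps > 0
    tau_s: float
    bin_size_cm: float

    @property
    def n_bins(self) -> int:
        return self.f.shape[1]

    def bin_centers_cm(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_size_cm


@dataclass
class DecodeResult:
    """Decoded test time bins with posterior, errors, and confusion matrix."""

    posterior: np.ndarray  # time x bins
    decoded_cm: np.ndarray
    actual_cm: np.ndarray
    error_cm: np.ndarray
    median_error_cm: float
    confusion: np.ndarray
    n_neurons: int


def fit_encoding(
    events: np.ndarray,
    track: BehaviorTrack,
    epochs: RunningEpochs,
    train_laps: np.ndarray | None = None,
    n_bins: int = N_BINS,
    tau_s: float | None = None,
    eps_frac: float = EPS_FRAC,
) -> EncodingModel:
    """Occupancy-normalized mean activity per time bin from training laps.

    ``f[i, b]`` is the event amplitude of neuron i per second while the
    animal runs through bin b (summed activity over the time spent there).
    Rows are floored at ``eps_frac`` times the grand-mean rate so the
    log-likelihood stays finite.
    """
    events = np.atleast_2d(np.asarray(events, dtype=float))
    sel = epochs.mask.copy()
    if train_laps is not None:
        sel &= np.isin(track.lap_id, train_laps)
    idx = np.flatnonzero(sel)
    if len(idx) == 0:
        raise ValueError("empty training set")
    bins = position_bins(track.position_cm[idx], track.track_length_cm, n_bins)
    dt = 1.0 / track.rate_hz
    time_in_bin = np.bincount(bins, minlength=n_bins).astype(float) * dt
    sums = np.zeros((events.shape[0], n_bins))
    np.add.at(sums.T, bins, events[:, idx].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(time_in_bin > 0, sums / np.maximum(time_in_bin, dt), 0.0)
    grand = f.mean()
    eps = eps_frac * grand if grand > 0 else eps_frac
    f = np.maximum(f, eps)
    if tau_s is None:
        tau_s = 1.0 / track.rate_hz
    return EncodingModel(f=f, tau_s=tau_s, bin_size_cm=track.track_length_cm / n_bins)


def decode(model: EncodingModel, activity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior over position bins for each time bin of activity.

    ``activity`` is (time x neurons) or (neurons,) for a single time bin;
    negative deconvolved values are clipped to 0.  Returns (posterior
    (time x bins), decoded bin indices).  Rows sum to 1 within 1e-9.
    """
    a = np.asarray(activity, dtype=float)
    single = a.ndim == 1
    a = np.atleast_2d(a)
    if not np.all(np.isfinite(a)):
        raise ValueError("activity must be finite")
    a = np.clip(a, 0.0, None)
    log_post = a @ np.log(model.f) - model.tau_s * model.f.sum(axis=0)[None, :]
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    decoded = np.argmax(post, axis=1)  # argmax ties -> lowest index
    if single:
        return post[0], decoded[0]
    return post, decoded


def decoding_error(
    decoded_cm: np.ndarray,
    actual_cm: np.ndarray,
    track_length_cm: float | None = None,
    circular: bool = False,
) -> tuple[np.ndarray, float]:
    """Absolute position error per time bin and its median.

    Linear |decoded - actual| by default; with ``circular=True`` the
    shorter way around the belt is used instead.
    """
    d = np.asarray(decoded_cm, dtype=float)
    a = np.asarray(actual_cm, dtype=float)
    if d.shape != a.shape:
        raise ValueError("decoded and actual sequences must be aligned")
    err = np.abs(d - a)
    if circular:
        if track_length_cm is None:
            raise ValueError("circular error needs track_length_cm")
        err = np.minimum(err, track_length_cm - err)
    return err, float(np.median(err)) if len(err) else float("nan")


def confusion(
    decoded_bins: np.ndarray, actual_bins: np.ndarray, n_bins: int = N_BINS
) -> np.ndarray:
    """Row-normalized confusion matrix: rows = actual bin, cols = predicted."""
    mat = np.zeros((n_bins, n_bins))
    np.add.at(mat, (np.asarray(actual_bins), np.asarray(decoded_bins)), 1.0)
    sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sums > 0, mat / np.maximum(sums, 1), 0.0)


def _fold_assignment(laps: np.ndarray, scheme: str):
    """Yield (train_laps, test_laps) per fold for the requested CV scheme."""
    laps = np.asarray(laps)
    if scheme == "odd_even":
        # laps numbered from 1: odd-numbered train, even-numbered test
        numbered = np.arange(1, len(laps) + 1)
        yield laps[numbered % 2 == 1], laps[numbered % 2 == 0]
    elif scheme == "kfold5":
        if len(laps) < 5:
            raise ValueError("fewer laps than folds")
        for part in np.array_split(laps, 5):
            yield laps[~np.isin(laps, part)], part
    else:
        raise ValueError(f"unknown scheme {scheme!r}")


def cross_validate(
    events: np.ndarray,
    track: BehaviorTrack,
    epochs: RunningEpochs,
    scheme: str = "odd_even",
    n_neurons: int | None = None,
    seed: int = 0,
    n_bins: int = N_BINS,
    tau_s: float | None = None,
    circular_error: bool = False,
) -> DecodeResult:
    """Lap-wise cross-validated decoding during running epochs.

    ``scheme`` is "odd_even" (odd-numbered laps train, even test) or
    "kfold5".  When ``n_neurons`` is given, that many neurons are sampled
    without replacement with the provided seed.
    """
    events = np.atleast_2d(np.asarray(events, dtype=float))
    laps = np.unique(track.lap_id[epochs.mask])
    if len(laps) < 4:
        raise ValueError("need at least 4 laps for cross-validation")
    if n_neurons is not None and n_neurons < events.shape[0]:
        rng = np.random.default_rng(seed)
        pick = rng.choice(events.shape[0], size=n_neurons, replace=False)
        events = events[pick]

    posts, decs, actuals = [], [], []
    for train_laps, test_laps in _fold_assignment(laps, scheme):
        model = fit_encoding(
            events, track, epochs, train_laps=train_laps, n_bins=n_bins, tau_s=tau_s
        )
        test_sel = epochs.mask & np.isin(track.lap_id, test_laps)
        idx = np.flatnonzero(test_sel)
        if len(idx) == 0:
            continue
        post, dec = decode(model, events[:, idx].T)
        posts.append(post)
        decs.append(dec)
        actuals.append(
            position_bins(track.position_cm[idx], track.track_length_cm, n_bins)
        )
    posterior = np.concatenate(posts)
    decoded_bins = np.concatenate(decs)
    actual_bins = np.concatenate(actuals)
    bin_size = track.track_length_cm / n_bins
    decoded_cm = (decoded_bins + 0.5) * bin_size
    actual_cm = (actual_bins + 0.5) * bin_size
    err, med = decoding_error(
        decoded_cm, actual_cm, track.track_length_cm, circular=circular_error
    )
    return DecodeResult(
        posterior=posterior,
        decoded_cm=decoded_cm,
        actual_cm=actual_cm,
        error_cm=err,
        median_error_cm=med,
        confusion=confusion(decoded_bins, actual_bins, n_bins),
        n_neurons=events.shape[0],
    )
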