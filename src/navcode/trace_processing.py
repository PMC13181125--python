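"""Fluorescence preprocessing: neuropil correction, dF/F0, deconvolution,
and task-active classification.

The processing chain follows the standard two-photon pipeline: subtract
scaled neuropil (coefficient 0.7), estimate a transient-robust baseline with
a 60 s rolling minimum-then-maximum filter followed by Gaussian smoothing
(sigma = 10 samples), normalize to dF/F0, then invert a fixed single-
exponential calcium kernel (1.5 s decay) with a non-negative least-squares
pool-adjacent-violators solver to obtain per-frame event amplitudes.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import gaussian_filter1d, maximum_filter1d, minimum_filter1d

from .datatypes import DffSet, EventSet, TraceSet

__all__ = [
    "neuropil_correct",
    "estimate_baseline",
    "compute_dff",
    "deconvolve",
    "deconvolve_trace",
    "significant_transients",
    "lap_reliability",
    "classify_active",
    "preprocess",
]

NEUROPIL_COEFF = 0.7
DECAY_S = 1.5
ACTIVE_THRESHOLD = 0.3


def neuropil_correct(traces: TraceSet, coeff: float = NEUROPIL_COEFF) -> np.ndarray:
    """Subtract scaled neuropil: F_corr = F_cell - coeff * F_np."""
    if not 0.0 <= coeff <= 1.0:
        raise ValueError("neuropil coefficient must lie in [0, 1]")
    return traces.F_cell - coeff * traces.F_np


def estimate_baseline(
    F_corr: np.ndarray,
    rate_hz: float,
    window_s: float = 60.0,
    smooth_sigma_samples: float = 10.0,
) -> np.ndarray:
    """Transient-robust baseline: rolling min, rolling max, Gaussian smooth.

    The opening (min then max, both over ``window_s``) removes positive
    transients shorter than the window while tracking slow drift; edges use
    nearest-sample padding.  Translation-equivariant: baseline(x + c) =
    baseline(x) + c.
    """
    F_corr = np.atleast_2d(np.asarray(F_corr, dtype=float))
    size = max(3, int(round(window_s * rate_hz)))
    lo = minimum_filter1d(F_corr, size=size, axis=-1, mode="nearest")
    f0 = maximum_filter1d(lo, size=size, axis=-1, mode="nearest")
    if smooth_sigma_samples > 0:
        f0 = gaussian_filter1d(f0, sigma=smooth_sigma_samples, axis=-1, mode="nearest")
    return f0


def compute_dff(
    F_corr: np.ndarray, F0: np.ndarray, rate_hz: float, eps_frac: float = 1e-6
) -> DffSet:
    """Normalize to dF/F0 = (F_corr - F0) / F0; flag neurons with F0 <= eps.

    Invalidity is a per-neuron flag, never an exception: a neuron whose
    baseline dips to or below ``eps_frac`` times the median baseline (or is
    non-finite anywhere) is flagged and its dff set to NaN.
    """
    F_corr = np.atleast_2d(np.asarray(F_corr, dtype=float))
    F0 = np.atleast_2d(np.asarray(F0, dtype=float))
    med = np.nanmedian(F0)
    eps = eps_frac * abs(med) if np.isfinite(med) and med != 0 else eps_frac
    valid = np.all(np.isfinite(F0) & (F0 > eps), axis=-1) & np.all(
        np.isfinite(F_corr), axis=-1
    )
    dff = np.full_like(F_corr, np.nan)
    dff[valid] = (F_corr[valid] - F0[valid]) / F0[valid]
    return DffSet(dff=dff, F0=F0, valid=valid, rate_hz=rate_hz)


def deconvolve_trace(y: np.ndarray, gamma: float) -> np.ndarray:
    """Non-negative AR(1) deconvolution of one trace (lambda = 0).

    Finds c minimizing ||c - y||^2 subject to c[t] >= gamma*c[t-1] and
    c >= 0, by pool-adjacent-violators, and returns the event train
    s[t] = c[t] - gamma*c[t-1].  Exact inverse of the forward recursion on
    noise-free inputs.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 0:
        return y.copy()
    # pools: value numerator v, weight w, start index t, length l
    v = np.empty(n)
    w = np.empty(n)
    t0 = np.empty(n, dtype=np.int64)
    ln = np.empty(n, dtype=np.int64)
    m = 0  # number of pools
    for t in range(n):
        v[m] = y[t]
        w[m] = 1.0
        t0[m] = t
        ln[m] = 1
        m += 1
        while m > 1:
            g = gamma ** ln[m - 2]
            if v[m - 1] / w[m - 1] >= g * v[m - 2] / w[m - 2]:
                break
            v[m - 2] += g * v[m - 1]
            w[m - 2] += g * g * w[m - 1]
            ln[m - 2] += ln[m - 1]
            m -= 1
    c = np.empty(n)
    for i in range(m):
        val = max(v[i] / w[i], 0.0)
        for k in range(ln[i]):
            c[t0[i] + k] = val
            val *= gamma
    s = np.empty(n)
    s[0] = c[0]
    s[1:] = c[1:] - gamma * c[:-1]
    # clamp tiny negatives from floating-point roundoff
    np.clip(s, 0.0, None, out=s)
    return s


def deconvolve(dff: DffSet, decay_s: float = DECAY_S) -> EventSet:
    """Deconvolve every valid neuron with gamma = exp(-1/(rate*decay))."""
    if not decay_s > 0:
        raise ValueError("decay_s must be positive")
    gamma = math.exp(-1.0 / (dff.rate_hz * decay_s))
    events = np.zeros_like(dff.dff)
    for i in range(dff.dff.shape[0]):
        if dff.valid[i]:
            events[i] = deconvolve_trace(dff.dff[i], gamma)
    return EventSet(events=events, gamma=gamma, rate_hz=dff.rate_hz)


def significant_transients(dff: np.ndarray, n_sd: float = 3.0) -> np.ndarray:
    """Flag samples exceeding the baseline by more than ``n_sd`` noise SDs.

    The noise scale is a per-neuron MAD estimate (1.4826 * median absolute
    deviation from the median) so transients themselves do not inflate it.
    Zero-variance traces yield an empty mask.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    med = np.nanmedian(dff, axis=-1, keepdims=True)
    sigma = 1.4826 * np.nanmedian(np.abs(dff - med), axis=-1, keepdims=True)
    mask = np.zeros(dff.shape, dtype=bool)
    ok = (sigma > 0).ravel()
    with np.errstate(invalid="ignore"):
        mask[ok] = dff[ok] > n_sd * sigma[ok]
    return mask


def lap_reliability(transient_mask: np.ndarray, lap_ids: np.ndarray) -> np.ndarray:
    """Fraction of laps containing at least one significant transient.

    Operates per neuron on a (neurons x time) mask; returns one value per
    neuron in [0, 1].
    """
    transient_mask = np.atleast_2d(np.asarray(transient_mask, dtype=bool))
    lap_ids = np.asarray(lap_ids)
    laps = np.unique(lap_ids)
    if len(laps) == 0:
        raise ValueError("no laps in input")
    hits = np.zeros((transient_mask.shape[0], len(laps)), dtype=bool)
    for j, lap in enumerate(laps):
        sel = lap_ids == lap
        hits[:, j] = transient_mask[:, sel].any(axis=1)
    return hits.mean(axis=1)


def classify_active(
    lap_rel=None, visual_rel=None, threshold: float = ACTIVE_THRESHOLD
):
    """Task-active iff lap reliability > threshold OR visual reliability > threshold.

    Both comparisons are strict.  Either metric may be absent (None or NaN)
    for sessions lacking that block; both absent is an error.
    """
    if lap_rel is None and visual_rel is None:
        raise ValueError("at least one reliability metric required")

    def _gt(x):
        if x is None:
            return False
        x = np.asarray(x, dtype=float)
        with np.errstate(invalid="ignore"):
            return np.where(np.isnan(x), False, x > threshold)

    a, b = _gt(lap_rel), _gt(visual_rel)
    if lap_rel is not None and visual_rel is not None:
        both_nan = np.isnan(np.asarray(lap_rel, dtype=float)) & np.isnan(
            np.asarray(visual_rel, dtype=float)
        )
        if np.any(both_nan):
            raise ValueError("both reliability metrics missing for some neurons")
    out = np.logical_or(a, b)
    return bool(out) if np.ndim(out) == 0 else out


def preprocess(
    traces: TraceSet,
    np_coeff: float = NEUROPIL_COEFF,
    decay_s: float = DECAY_S,
    window_s: float = 60.0,
    smooth_sigma_samples: float = 10.0,
) -> tuple[DffSet, EventSet]:
    """Full chain: neuropil correction -> baseline -> dF/F0 -> deconvolution."""
    f_corr = neuropil_correct(traces, np_coeff)
    f0 = estimate_baseline(f_corr, traces.rate_hz, window_s, smooth_sigma_samples)
    dff = compute_dff(f_corr, f0, traces.rate_hz)
    events = deconvolve(dff, decay_s)
    return dff, events
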