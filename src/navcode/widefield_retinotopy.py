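"""Fourier retinotopy from periodic-stimulus widefield movies.

Pixels are normalized to their pre-stimulation baseline, contrast-enhanced
with a rolling min-max filter, trial-averaged, and Fourier-transformed along
time.  The complex coefficient at the stimulus frequency gives each pixel's
response amplitude (modulus, normalized to the per-pixel temporal mean) and
phase (argument; by this package's sign convention a larger positive phase
means a later response).  Maps are rendered as HSV images with hue = phase,
value = normalized amplitude, saturation = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .datatypes import PixelMovie

__all__ = [
    "RetinotopyMap",
    "minmax_contrast",
    "fourier_map",
    "hsv_encode",
    "baseline_normalize",
]

MINMAX_WINDOW_S = 10.0  # not specified by the acquisition; configurable


@dataclass
class RetinotopyMap:
    """Per-pixel response amplitude (>= 0) and phase in [-pi, pi)."""

    amplitude: np.ndarray
    phase: np.ndarray
    stim_freq_hz: float
    phase_convention: str = "positive = later response"


def baseline_normalize(movie: PixelMovie, n_baseline_frames: int) -> PixelMovie:
    """Divide each pixel by its mean over the pre-stimulation frames."""
    base = movie.frames[:n_baseline_frames].mean(axis=0)
    base = np.where(np.abs(base) > 1e-12, base, 1.0)
    return PixelMovie(
        frames=movie.frames / base,
        rate_hz=movie.rate_hz,
        stim_freq_hz=movie.stim_freq_hz,
        n_trials=movie.n_trials,
    )


def minmax_contrast(
    movie: PixelMovie, window_s: float = MINMAX_WINDOW_S, delta: float = 1e-9
) -> PixelMovie:
    """Temporal contrast enhancement: (x - rollmin)/(rollmax - rollmin + delta).

    Constant pixels map to 0 (the delta guard); scaled copies of a pixel
    produce identical enhanced traces up to the delta regularization.
    """
    size = max(3, int(round(window_s * movie.rate_hz)))
    x = movie.frames
    lo = minimum_filter1d(x, size=size, axis=0, mode="nearest")
    hi = maximum_filter1d(x, size=size, axis=0, mode="nearest")
    out = (x - lo) / (hi - lo + delta)
    return PixelMovie(
        frames=out,
        rate_hz=movie.rate_hz,
        stim_freq_hz=movie.stim_freq_hz,
        n_trials=movie.n_trials,
    )


def fourier_map(movie: PixelMovie, stim_freq_hz: float | None = None) -> RetinotopyMap:
    """Pixel-wise DFT coefficient at the stimulus frequency.

    For a pixel b + A*cos(2*pi*f*t - phi) the recovered amplitude is A
    normalized by the per-pixel temporal mean and the recovered phase is
    phi.  If the movie does not cover an integer number of stimulus cycles
    a Hann window is applied (with a warning) to limit leakage.
    """
    f = stim_freq_hz if stim_freq_hz is not None else movie.stim_freq_hz
    x = movie.frames
    n = x.shape[0]
    t = np.arange(n) / movie.rate_hz
    cycles = f * n / movie.rate_hz
    w = np.ones(n)
    if abs(cycles - round(cycles)) > 1e-6:
        warnings.warn(
            "movie does not cover an integer number of stimulus cycles; "
            "applying a Hann window"
        )
        w = np.hanning(n)
    basis = w * np.exp(-2j * np.pi * f * t)
    coef = np.tensordot(basis, x, axes=([0], [0])) / w.sum()
    mean = np.tensordot(w, x, axes=([0], [0])) / w.sum()
    amp = 2.0 * np.abs(coef)
    denom = np.where(np.abs(mean) > 1e-12, np.abs(mean), 1.0)
    amp_norm = amp / denom
    # x ~ A cos(wt - phi) => coefficient (A/2) e^{-i phi}; recover phi
    phase = np.angle(np.conj(coef))
    phase = (phase + np.pi) % (2 * np.pi) - np.pi
    return RetinotopyMap(amplitude=amp_norm, phase=phase, stim_freq_hz=f)


def hsv_encode(rmap: RetinotopyMap) -> np.ndarray:
    """HSV rendering: hue = phase (circular), value = normalized amplitude."""
    hue = ((rmap.phase + np.pi) / (2 * np.pi)) % 1.0
    amax = rmap.amplitude.max()
    value = rmap.amplitude / amax if amax > 0 else np.zeros_like(rmap.amplitude)
    sat = np.ones_like(hue)
    return hsv_to_rgb(np.stack([hue, sat, value], axis=-1))
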