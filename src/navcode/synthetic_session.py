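"""Seeded synthetic imaging sessions with known ground truth.

Emulates the study conditions every downstream stage is tested against: a
150 cm circular treadmill (cues at 50 and 100 cm, reward at 0 cm), position-
tuned neurons whose Poisson events are convolved with a 1.5 s single-
exponential calcium kernel and contaminated by shared neuropil plus Gaussian
noise, a pseudo-randomized drifting-grating protocol (12 directions x 3
spatial x 2 temporal frequencies, 3 s on / 2 s gray), periodic widefield
movies, and multinomial retrograde-label tables with configurable
anterior/posterior input biases.

All randomness flows from ``SimConfig.seed`` (or an explicit ``seed``
argument) through ``numpy.random.default_rng``; identical seeds reproduce
every output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .datatypes import BehaviorTrack, PixelMovie, TraceSet

__all__ = [
    "SimConfig",
    "StimulusParams",
    "simulate_behavior",
    "simulate_place_cells",
    "simulate_visual_session",
    "simulate_widefield_movie",
    "simulate_anatomy_counts",
    "direction_tuning_curve",
    "volumetric_config",
    "high_snr_config",
]

DIRECTIONS_DEG = tuple(range(0, 360, 30))
SPATIAL_FREQS_CPD = (0.04, 0.08, 0.16)
TEMPORAL_FREQS_HZ = (1.0, 4.0)


@dataclass
class SimConfig:
    """Session-level simulation parameters.

    Rates are event rates in events/s; ``field_width_cm`` is the SD of the
    circular-Gaussian tuning field; ``event_amplitude_dff`` scales one
    deconvolved event into dF/F units.
    """

    duration_s: float = 600.0
    rate_hz: float = 30.0
    track_length_cm: float = 150.0
    cue_positions_cm: tuple = (50.0, 100.0)
    reward_position_cm: float = 0.0
    n_neurons: int = 100
    frac_tuned: float = 0.4
    field_width_cm: float = 10.0
    field_amplitude_hz: float = 2.0
    baseline_rate_hz: float = 0.2
    decay_s: float = 1.5
    neuropil_gain: float = 0.7
    noise_sd: float = 0.05
    event_amplitude_dff: float = 1.0
    f0_au: float = 100.0
    # run/pause Markov bout model; pause_dwell_s = 0 disables pauses
    mean_run_speed_cm_s: float = 15.0
    speed_sd_cm_s: float = 3.0
    run_dwell_s: float = 30.0
    pause_dwell_s: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if not self.track_length_cm > 0:
            raise ValueError("track_length_cm must be positive")
        if not 0.0 <= self.frac_tuned <= 1.0:
            raise ValueError("frac_tuned must lie in [0, 1]")
        if not self.decay_s > 0:
            raise ValueError("decay_s must be positive")
        if not 0.0 <= self.neuropil_gain < 1.0:
            raise ValueError("neuropil_gain must lie in [0, 1)")


def volumetric_config(**overrides) -> SimConfig:
    """Preset mirroring the slower volumetric acquisition mode (7.5 Hz)."""
    overrides.setdefault("rate_hz", 7.5)
    return SimConfig(**overrides)


def high_snr_config(**overrides) -> SimConfig:
    """Strongly driven, low-noise preset for ground-truth recovery checks.

    Peak event rate 10 events/s against the 0.2 events/s baseline, with
    minimal fluorescence noise: tuning is limited by Poisson sampling, not
    by the imaging model.
    """
    overrides.setdefault("field_amplitude_hz", 10.0)
    overrides.setdefault("noise_sd", 0.02)
    return SimConfig(**overrides)


def _rng_streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(config: SimConfig, rng: np.random.Generator | None = None) -> BehaviorTrack:
    """Simulate treadmill behavior with run/pause bouts on a circular belt.

    The speed profile is a two-state (run/pause) Markov chain; running speed
    fluctuates slowly around ``mean_run_speed_cm_s``.  Position at sample k
    is the distance integrated over the first k+1 frames, wrapped to
    [0, L); the lap index increments exactly at each wrap.
    """
    if rng is None:
        rng = _rng_streams(config.seed, 4)[0]
    dt = 1.0 / config.rate_hz
    n = int(round(config.duration_s * config.rate_hz))
    if n < 1:
        raise ValueError("duration too short for one sample")
    t = np.arange(n) * dt

    if config.pause_dwell_s > 0:
        p_stop = min(1.0, dt / config.run_dwell_s)
        p_go = min(1.0, dt / config.pause_dwell_s)
        u = rng.random(n)
        running = np.empty(n, dtype=bool)
        state = True
        for k in range(n):
            if state:
                state = u[k] >= p_stop
            else:
                state = u[k] < p_go
            running[k] = state
    else:
        running = np.ones(n, dtype=bool)

    if config.speed_sd_cm_s > 0:
        wobble = rng.standard_normal(n)
        wobble = gaussian_filter1d(wobble, sigma=config.rate_hz)  # ~1 s smoothing
        sd = np.std(wobble)
        wobble = wobble / sd if sd > 0 else wobble
        speed = config.mean_run_speed_cm_s + config.speed_sd_cm_s * wobble
    else:
        speed = np.full(n, config.mean_run_speed_cm_s)
    speed = np.clip(speed, 0.0, None)
    speed[~running] = 0.0

    distance = np.cumsum(speed * dt)
    position = (config.reward_position_cm + distance) % config.track_length_cm
    lap_id = np.floor((config.reward_position_cm + distance) / config.track_length_cm).astype(int)

    return BehaviorTrack(
        t=t,
        position_cm=position,
        speed_cm_s=speed,
        lap_id=lap_id,
        track_length_cm=config.track_length_cm,
        cue_positions_cm=tuple(config.cue_positions_cm),
        reward_position_cm=config.reward_position_cm,
    )


# ---------------------------------------------------------------------------
# calcium synthesis shared by place-cell and visual sessions
# ---------------------------------------------------------------------------

def _events_to_calcium(events: np.ndarray, gamma: float) -> np.ndarray:
    """Forward AR(1) recursion c[t] = gamma*c[t-1] + s[t] along axis 1."""
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -gamma], events, axis=-1)


def _fluorescence_from_events(events, config: SimConfig, rng) -> TraceSet:
    """Convolve events with the calcium kernel and add neuropil + noise."""
    n_neurons, n = events.shape
    gamma = math.exp(-1.0 / (config.rate_hz * config.decay_s))
    signal = _events_to_calcium(events * config.event_amplitude_dff, gamma)

    # one shared slow neuropil trace per session, small per-neuron jitter
    np_slow = gaussian_filter1d(rng.standard_normal(n), sigma=2.0 * config.rate_hz)
    sd = np.std(np_slow)
    np_slow = np_slow / sd if sd > 0 else np_slow
    f_np_base = 0.2 * config.f0_au
    F_np = f_np_base * (1.0 + 0.1 * np_slow)[None, :] + 0.01 * f_np_base * rng.standard_normal(
        (n_neurons, n)
    )

    noise = config.noise_sd * config.f0_au * rng.standard_normal((n_neurons, n))
    F_cell = config.f0_au * (1.0 + signal) + config.neuropil_gain * F_np + noise
    return TraceSet(F_cell=F_cell, F_np=F_np, rate_hz=config.rate_hz)


def _circular_distance(a, b, length):
    d = np.abs(a - b) % length
    return np.minimum(d, length - d)


def simulate_place_cells(
    behavior: BehaviorTrack, config: SimConfig, centers: np.ndarray | None = None
) -> tuple[TraceSet, pd.DataFrame]:
    """Simulate position-tuned and untuned neurons on a behavior track.

    Tuned neurons fire inhomogeneous-Poisson events at
    ``baseline + amplitude * exp(-d^2 / (2 sd^2))`` of the circular distance
    to their field center; untuned neurons fire at the baseline rate
    everywhere.  Events are convolved with the exponential calcium kernel
    and wrapped in fluorescence with shared neuropil and Gaussian noise.

    Returns the trace set and a ground-truth table (one row per neuron).
    """
    n = behavior.n_samples
    if abs(behavior.rate_hz - config.rate_hz) / config.rate_hz > 0.01:
        raise ValueError("behavior and config disagree on rate_hz")
    rng_truth, rng_events, rng_fluo = _rng_streams(config.seed + 1, 3)

    n_tuned = int(round(config.frac_tuned * config.n_neurons))
    is_tuned = np.zeros(config.n_neurons, dtype=bool)
    is_tuned[:n_tuned] = True
    if centers is None:
        centers = rng_truth.uniform(0.0, config.track_length_cm, size=config.n_neurons)
    else:
        centers = np.asarray(centers, dtype=float).copy()
        if len(centers) != config.n_neurons:
            raise ValueError("centers must have one entry per neuron")
    centers[~is_tuned] = np.nan

    dt = 1.0 / config.rate_hz
    rates = np.full((config.n_neurons, n), config.baseline_rate_hz)
    if n_tuned:
        d = _circular_distance(
            behavior.position_cm[None, :], centers[:n_tuned, None], config.track_length_cm
        )
        rates[:n_tuned] += config.field_amplitude_hz * np.exp(
            -(d**2) / (2.0 * config.field_width_cm**2)
        )
    events = rng_events.poisson(rates * dt).astype(float)

    traces = _fluorescence_from_events(events, config, rng_fluo)
    truth = pd.DataFrame(
        {
            "neuron_id": np.arange(config.n_neurons),
            "is_tuned": is_tuned,
            "field_center_cm": centers,
            "field_width_cm": np.where(is_tuned, config.field_width_cm, np.nan),
            "peak_rate_hz": np.where(
                is_tuned, config.baseline_rate_hz + config.field_amplitude_hz, config.baseline_rate_hz
            ),
        }
    )
    traces._true_events = events  # noqa: SLF001 - exposed for tests
    return traces, truth


# ---------------------------------------------------------------------------
# visual sessions
# ---------------------------------------------------------------------------

@dataclass
class StimulusParams:
    """Drifting-grating protocol: 72 conditions, pseudo-randomized per block."""

    directions_deg: tuple = DIRECTIONS_DEG
    sfs_cpd: tuple = SPATIAL_FREQS_CPD
    tfs_hz: tuple = TEMPORAL_FREQS_HZ
    n_rep: int = 5
    stim_s: float = 3.0
    gray_s: float = 2.0
    kappa: float = 4.0
    secondary_sf_tf_gain: float = 0.25
    null_frac_range: tuple = (0.0, 0.6)

    @property
    def n_conditions(self) -> int:
        return len(self.directions_deg) * len(self.sfs_cpd) * len(self.tfs_hz)


def direction_tuning_curve(pref_dir_deg, kappa, null_frac, directions_deg=DIRECTIONS_DEG):
    """Bimodal von-Mises direction curve, peak 1 at the preferred direction.

    ``null_frac`` is the relative response in the opposite (null) direction;
    for sharp tuning the direction selectivity index is (1-null_frac)/(1+null_frac).
    """
    theta = np.deg2rad(np.asarray(directions_deg, dtype=float))
    d = theta - np.deg2rad(pref_dir_deg)
    curve = np.exp(kappa * (np.cos(d) - 1.0)) + null_frac * np.exp(
        kappa * (np.cos(d - np.pi) - 1.0)
    )
    return curve / curve.max()


def _true_osi_dsi(curve, directions_deg=DIRECTIONS_DEG):
    """Evaluate the selectivity indices on an ideal 12-point rate curve."""
    directions = np.asarray(directions_deg)
    p = int(np.argmax(curve))
    r_p = curve[p]
    null_dir = (directions[p] + 180) % 360
    r_null = curve[directions == null_dir][0]
    ortho = [(directions[p] + 90) % 360, (directions[p] + 270) % 360]
    r_ortho = np.mean([curve[directions == o][0] for o in ortho])
    dsi = (r_p - r_null) / (r_p + r_null) if (r_p + r_null) > 0 else np.nan
    osi = (r_p - r_ortho) / (r_p + r_ortho) if (r_p + r_ortho) > 0 else np.nan
    return osi, dsi


def simulate_visual_session(
    config: SimConfig, stim_params: StimulusParams | None = None
) -> tuple[TraceSet, pd.DataFrame, pd.DataFrame]:
    """Simulate a grating session: traces, stimulus table, ground truth.

    Each repetition block presents every condition exactly once in a fresh
    seeded random order.  Visually tuned neurons respond with von-Mises
    direction tuning scaled by an SF/TF preference surface.
    """
    stim = stim_params or StimulusParams()
    if stim.n_rep < 2:
        raise ValueError("at least 2 repetitions required (reliability undefined)")
    rng_order, rng_truth, rng_events, rng_fluo = _rng_streams(config.seed + 2, 4)

    conditions = [
        (d, sf, tf)
        for d in stim.directions_deg
        for sf in stim.sfs_cpd
        for tf in stim.tfs_hz
    ]
    rows = []
    trial_len = stim.stim_s + stim.gray_s
    t0 = stim.gray_s  # lead-in gray so pre-stimulus frames exist
    i = 0
    for rep in range(stim.n_rep):
        order = rng_order.permutation(len(conditions))
        for idx in order:
            d, sf, tf = conditions[idx]
            rows.append(
                {
                    "onset_s": t0 + i * trial_len,
                    "direction_deg": d,
                    "sf_cpd": sf,
                    "tf_hz": tf,
                    "repetition": rep,
                }
            )
            i += 1
    table = pd.DataFrame(rows)

    duration = t0 + len(table) * trial_len + stim.gray_s
    n = int(round(duration * config.rate_hz))
    dt = 1.0 / config.rate_hz

    n_vis = int(round(config.frac_tuned * config.n_neurons))
    is_visual = np.zeros(config.n_neurons, dtype=bool)
    is_visual[:n_vis] = True
    pref_dir = rng_truth.choice(stim.directions_deg, size=config.n_neurons)
    combos = [(sf, tf) for sf in stim.sfs_cpd for tf in stim.tfs_hz]
    pref_combo = rng_truth.integers(0, len(combos), size=config.n_neurons)
    null_frac = rng_truth.uniform(*stim.null_frac_range, size=config.n_neurons)

    osi_true = np.full(config.n_neurons, np.nan)
    dsi_true = np.full(config.n_neurons, np.nan)
    rates = np.full((config.n_neurons, n), config.baseline_rate_hz)
    frame_of = lambda s: int(round(s * config.rate_hz))  # noqa: E731
    stim_frames = frame_of(stim.stim_s)

    curves = {}
    for j in range(n_vis):
        curve = direction_tuning_curve(pref_dir[j], stim.kappa, null_frac[j], stim.directions_deg)
        curves[j] = dict(zip(stim.directions_deg, curve))
        osi_true[j], dsi_true[j] = _true_osi_dsi(curve, stim.directions_deg)

    for _, row in table.iterrows():
        k0 = frame_of(row.onset_s)
        combo_idx = combos.index((row.sf_cpd, row.tf_hz))
        for j in range(n_vis):
            gain = 1.0 if combo_idx == pref_combo[j] else stim.secondary_sf_tf_gain
            r = curves[j][row.direction_deg]
            rates[j, k0 : k0 + stim_frames] += config.field_amplitude_hz * gain * r

    events = rng_events.poisson(rates * dt).astype(float)
    traces = _fluorescence_from_events(events, config, rng_fluo)

    truth = pd.DataFrame(
        {
            "neuron_id": np.arange(config.n_neurons),
            "is_visual": is_visual,
            "preferred_direction_deg": np.where(is_visual, pref_dir, np.nan),
            "preferred_sf_cpd": [combos[c][0] if v else np.nan for c, v in zip(pref_combo, is_visual)],
            "preferred_tf_hz": [combos[c][1] if v else np.nan for c, v in zip(pref_combo, is_visual)],
            "osi_true": np.where(is_visual, osi_true, np.nan),
            "dsi_true": np.where(is_visual, dsi_true, np.nan),
        }
    )
    return traces, table, truth


# ---------------------------------------------------------------------------
# widefield movies
# ---------------------------------------------------------------------------

def simulate_widefield_movie(
    shape: tuple,
    n_frames: int,
    rate_hz: float,
    stim_freq_hz: float,
    phase_map: np.ndarray,
    amplitude_map: np.ndarray,
    baseline: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_trials: int = 1,
) -> PixelMovie:
    """Periodic-response movie: pixel(t) = baseline + A*cos(2*pi*f*t - phase) + noise."""
    phase_map = np.asarray(phase_map, dtype=float)
    amplitude_map = np.asarray(amplitude_map, dtype=float)
    if phase_map.shape != tuple(shape) or amplitude_map.shape != tuple(shape):
        raise ValueError("phase_map and amplitude_map must match the pixel grid")
    if not stim_freq_hz < rate_hz / 2.0:
        raise ValueError("stim_freq_hz must be below the Nyquist frequency")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / rate_hz
    frames = baseline + amplitude_map[None] * np.cos(
        2.0 * np.pi * stim_freq_hz * t[:, None, None] - phase_map[None]
    )
    if noise_sd > 0:
        frames = frames + noise_sd * rng.standard_normal(frames.shape)
    return PixelMovie(frames=frames, rate_hz=rate_hz, stim_freq_hz=stim_freq_hz, n_trials=n_trials)


# ---------------------------------------------------------------------------
# retrograde-label tables
# ---------------------------------------------------------------------------

def simulate_anatomy_counts(
    regions: list,
    totals_per_target: dict,
    bias_map: dict,
    seed: int = 0,
    dv_map: dict | None = None,
) -> pd.DataFrame:
    """Draw multinomial retrograde-label tables per injection target.

    ``bias_map[target]`` gives the fractional composition over ``regions``
    (must sum to 1 within 1e-9).  Optional ``dv_map[(target, region)] =
    (mean_mm, sd_mm)`` attaches Gaussian dorsoventral coordinates.  Returns
    one row per labeled cell: cell_id, acronym, injection_target, dv_mm.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cell_id = 0
    for target, total in totals_per_target.items():
        fracs = np.array([bias_map[target][r] for r in regions], dtype=float)
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions for target {target!r} must sum to 1")
        if total == 0:
            continue
        counts = rng.multinomial(total, fracs)
        for region, c in zip(regions, counts):
            if c == 0:
                continue
            if dv_map is not None and (target, region) in dv_map:
                mu, sd = dv_map[(target, region)]
                dv = rng.normal(mu, sd, size=c)
            else:
                dv = np.full(c, np.nan)
            for v in dv:
                rows.append(
                    {
                        "cell_id": cell_id,
                        "acronym": region,
                        "injection_target": target,
                        "dv_mm": v,
                    }
                )
                cell_id += 1
    columns = ["cell_id", "acronym", "injection_target", "dv_mm"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns)
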