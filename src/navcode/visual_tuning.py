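"""Grating responses: de-randomization, reliability, SF/TF preference, OSI/DSI.

Trials are re-grouped into the canonical condition order (direction
ascending, then spatial frequency, then temporal frequency) and each
snippet is baseline-corrected by the median of the five frames preceding
stimulus onset.  The visual reliability index is the 75th percentile of
pairwise Pearson correlations between the condition-ordered repetition
time courses; a neuron is visually responsive when r > 0.3 (strict).

Orientation and direction selectivity follow
OSI = (R_p - R_ortho)/(R_p + R_ortho), DSI = (R_p - R_null)/(R_p + R_null),
with R_p the response at the preferred direction, R_null 180 degrees away,
R_ortho the mean of the two orthogonal directions; neurons with an index
above 0.33 are selective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VisualProfile",
    "derandomize",
    "reliability_index",
    "classify_visual",
    "sf_tf_preference",
    "osi_dsi",
    "peak_amplitude",
    "analyze_visual_session",
]

VISUAL_THRESHOLD = 0.3
SELECTIVITY_THRESHOLD = 0.33
PRE_FRAMES = 5
RELIABILITY_PCT = 75.0


@dataclass
class VisualProfile:
    """Per-neuron de-randomized grating responses and derived indices."""

    resp: np.ndarray  # conditions x repetitions x frames, baseline-corrected
    conditions: pd.DataFrame  # canonical order: direction_deg, sf_cpd, tf_hz
    cond_mean: np.ndarray  # conditions, scalar response per condition
    r_index: float = float("nan")
    osi: float = float("nan")
    dsi: float = float("nan")
    pref_dir_deg: float = float("nan")
    pref_ori_deg: float = float("nan")
    pref_sf_cpd: float = float("nan")
    pref_tf_hz: float = float("nan")
    is_visual: bool = False
    peak_amp_pct: float = float("nan")


def _canonical_conditions(stim: pd.DataFrame) -> pd.DataFrame:
    conds = (
        stim[["direction_deg", "sf_cpd", "tf_hz"]]
        .drop_duplicates()
        .sort_values(["direction_deg", "sf_cpd", "tf_hz"])
        .reset_index(drop=True)
    )
    return conds


def derandomize(
    dff: np.ndarray,
    stim: pd.DataFrame,
    rate_hz: float,
    pre_frames: int = PRE_FRAMES,
    stim_window_s: float = 3.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Group trials by condition and baseline-correct each snippet.

    ``dff`` is (neurons x time).  Returns (resp, conditions): resp is
    (neurons, conditions, repetitions, frames) where frames cover the
    stimulus window, each snippet corrected by its own ``pre_frames``
    pre-stimulus median.  Trials whose onset leaves no room for the
    pre-stimulus frames are dropped with a warning.
    """
    import warnings

    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    n_neurons, T = dff.shape
    conds = _canonical_conditions(stim)
    key_to_idx = {
        (r.direction_deg, r.sf_cpd, r.tf_hz): i for i, r in conds.iterrows()
    }
    win = int(round(stim_window_s * rate_hz))
    n_rep = int(stim.groupby(["direction_deg", "sf_cpd", "tf_hz"]).size().max())
    resp = np.full((n_neurons, len(conds), n_rep, win), np.nan)
    rep_counter = np.zeros(len(conds), dtype=int)
    dropped = 0
    for _, row in stim.sort_values("onset_s").iterrows():
        k0 = int(round(row.onset_s * rate_hz))
        ci = key_to_idx[(row.direction_deg, row.sf_cpd, row.tf_hz)]
        if k0 - pre_frames < 0 or k0 + win > T:
            dropped += 1
            rep_counter[ci] += 1
            continue
        base = np.median(dff[:, k0 - pre_frames : k0], axis=1, keepdims=True)
        resp[:, ci, rep_counter[ci], :] = dff[:, k0 : k0 + win] - base
        rep_counter[ci] += 1
    if dropped:
        warnings.warn(f"dropped {dropped} trials without full pre/post windows")
    return resp, conds


def reliability_index(resp: np.ndarray, pct: float = RELIABILITY_PCT) -> float:
    """75th percentile of pairwise correlations between repetition traces.

    ``resp`` is (conditions, repetitions, frames) for one neuron.  Each
    repetition's condition-ordered time course is concatenated; pairs with a
    constant or empty trace are skipped.  NaN when all pairs are skipped.
    """
    resp = np.asarray(resp, dtype=float)
    if resp.ndim != 3:
        raise ValueError("resp must be conditions x repetitions x frames")
    n_rep = resp.shape[1]
    if n_rep < 2:
        raise ValueError("need at least 2 repetitions")
    traces = resp.transpose(1, 0, 2).reshape(n_rep, -1)
    cors = []
    for i in range(n_rep):
        for j in range(i + 1, n_rep):
            ok = np.isfinite(traces[i]) & np.isfinite(traces[j])
            if ok.sum() < 2:
                continue
            a, b = traces[i, ok], traces[j, ok]
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            cors.append(np.corrcoef(a, b)[0, 1])
    if not cors:
        return float("nan")
    return float(np.percentile(cors, pct))


def classify_visual(r: float, threshold: float = VISUAL_THRESHOLD) -> bool:
    """Visually responsive iff r > threshold (strict)."""
    return bool(np.isfinite(r) and r > threshold)


def condition_means(resp: np.ndarray) -> np.ndarray:
    """Mean baseline-corrected response over the stimulus window, per condition."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(resp, axis=(-2, -1))


def sf_tf_preference(
    cond_mean: np.ndarray, conditions: pd.DataFrame
) -> tuple[float, float, bool]:
    """Preferred SF/TF combination: argmax of the direction-averaged response.

    Returns (pref_sf, pref_tf, tied); ties break to the lowest (sf, tf) in
    canonical order and are flagged.
    """
    df = conditions.copy()
    df["resp"] = np.asarray(cond_mean, dtype=float)
    by_combo = (
        df.groupby(["sf_cpd", "tf_hz"])["resp"].mean().reset_index()
        .sort_values(["sf_cpd", "tf_hz"])
        .reset_index(drop=True)
    )
    best = by_combo["resp"].max()
    winners = by_combo[by_combo["resp"] == best]
    tied = len(winners) > 1
    row = winners.iloc[0]
    return float(row.sf_cpd), float(row.tf_hz), tied


def osi_dsi(direction_curve: np.ndarray, directions_deg: np.ndarray):
    """Selectivity indices from a 12-point direction response curve.

    Negative responses are rectified to 0 first, keeping both indices in
    [0, 1].  Returns (osi, dsi, pref_dir_deg, pref_ori_deg); indices are
    NaN when their denominator is 0.  Both are invariant to positive
    scaling of the curve.
    """
    curve = np.clip(np.asarray(direction_curve, dtype=float), 0.0, None)
    directions = np.asarray(directions_deg)
    if len(curve) != len(directions):
        raise ValueError("curve and directions must align")
    p = int(np.argmax(curve))
    pref_dir = float(directions[p])
    r_p = curve[p]
    r_null = curve[np.argmin(np.abs(((directions - (pref_dir + 180)) % 360)))]
    ortho = [(pref_dir + 90) % 360, (pref_dir + 270) % 360]
    r_ortho = np.mean(
        [curve[np.argmin(np.abs((directions - o) % 360))] for o in ortho]
    )
    dsi = (r_p - r_null) / (r_p + r_null) if (r_p + r_null) > 0 else float("nan")
    osi = (r_p - r_ortho) / (r_p + r_ortho) if (r_p + r_ortho) > 0 else float("nan")
    return float(osi), float(dsi), pref_dir, pref_dir % 180.0


def peak_amplitude(trial_snippets: np.ndarray, pct: float = 95.0) -> float:
    """95th percentile of per-trial maxima, in percent dF/F.

    ``trial_snippets`` is (trials, frames) or any array whose leading axis
    indexes trials.
    """
    snip = np.asarray(trial_snippets, dtype=float)
    if snip.size == 0:
        return float("nan")
    flat = np.atleast_2d(snip.reshape(-1, snip.shape[-1]))
    any_finite = np.isfinite(flat).any(axis=1)
    maxima = np.nanmax(flat[any_finite], axis=1) if any_finite.any() else np.empty(0)
    if len(maxima) == 0:
        return float("nan")
    return float(np.percentile(maxima, pct) * 100.0)


def analyze_visual_session(
    dff: np.ndarray,
    stim: pd.DataFrame,
    rate_hz: float,
    pre_frames: int = PRE_FRAMES,
    stim_window_s: float = 3.0,
) -> tuple[pd.DataFrame, list[VisualProfile]]:
    """Per-neuron visual characterization for a whole session.

    Returns a DataFrame (neuron_id, r_index, is_visual, pref_sf_cpd,
    pref_tf_hz, osi, dsi, pref_dir_deg, pref_ori_deg, peak_amp_pct) and the
    per-neuron profiles.  OSI/DSI are computed on the direction curve at
    the preferred SF/TF combination only.
    """
    resp, conds = derandomize(dff, stim, rate_hz, pre_frames, stim_window_s)
    rows, profiles = [], []
    directions = np.sort(conds["direction_deg"].unique())
    for i in range(resp.shape[0]):
        cm = condition_means(resp[i])
        r = reliability_index(resp[i])
        visual = classify_visual(r)
        sf, tf, _tied = sf_tf_preference(cm, conds)
        sel = (conds["sf_cpd"] == sf) & (conds["tf_hz"] == tf)
        curve_df = conds[sel].assign(resp=cm[sel.to_numpy()])
        curve = (
            curve_df.sort_values("direction_deg")["resp"].to_numpy()
        )
        osi, dsi, pref_dir, pref_ori = osi_dsi(curve, directions)
        amp = peak_amplitude(resp[i])
        profiles.append(
            VisualProfile(
                resp=resp[i],
                conditions=conds,
                cond_mean=cm,
                r_index=r,
                osi=osi,
                dsi=dsi,
                pref_dir_deg=pref_dir,
                pref_ori_deg=pref_ori,
                pref_sf_cpd=sf,
                pref_tf_hz=tf,
                is_visual=visual,
                peak_amp_pct=amp,
            )
        )
        rows.append(
            {
                "neuron_id": i,
                "r_index": r,
                "is_visual": visual,
                "pref_sf_cpd": sf,
                "pref_tf_hz": tf,
                "osi": osi,
                "dsi": dsi,
                "pref_dir_deg": pref_dir,
                "pref_ori_deg": pref_ori,
                "peak_amp_pct": amp,
            }
        )
    return pd.DataFrame(rows), profiles
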