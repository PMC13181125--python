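"""End-to-end session runs, session summaries, and group comparisons.

A session is one imaging field of view.  ``run_session`` chains the stages
(preprocess -> behavior -> position tuning -> decoding, optionally a
visual block) on a synthetic session and returns one summary row plus the
per-neuron tables.  Group comparisons follow the study's convention:
two-sided Mann-Whitney U on per-session scalar summaries, two-sample
Kolmogorov-Smirnov on pooled per-neuron distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior_analysis as ba
from . import bayesian_decoding as bd
from . import position_tuning as pt
from . import trace_processing as tp
from . import visual_tuning as vt
from .synthetic_session import SimConfig, StimulusParams, simulate_behavior, \
    simulate_place_cells, simulate_visual_session

__all__ = [
    "SessionSummary",
    "GroupComparison",
    "run_session",
    "run_cohort",
    "mannwhitney_u",
    "ks_two_sample",
    "compare_groups",
    "significance_stars",
]


@dataclass
class SessionSummary:
    """One row of session-level metrics (NaN where a block was not run)."""

    session_id: str
    subregion: str
    n_neurons: int
    frac_position_tuned: float = float("nan")
    frac_visual: float = float("nan")
    median_decode_error_cm: float = float("nan")
    mean_si_bits_per_event: float = float("nan")
    mean_width_cm: float = float("nan")
    mean_trial_corr: float = float("nan")
    field_count_fractions: dict = field(default_factory=dict)
    sf_tf_fractions: dict = field(default_factory=dict)
    seed: int = 0

    def to_row(self) -> dict:
        row = {
            "session_id": self.session_id,
            "subregion": self.subregion,
            "n_neurons": self.n_neurons,
            "frac_position_tuned": self.frac_position_tuned,
            "frac_visual": self.frac_visual,
            "median_decode_error_cm": self.median_decode_error_cm,
            "mean_si_bits_per_event": self.mean_si_bits_per_event,
            "mean_width_cm": self.mean_width_cm,
            "mean_trial_corr": self.mean_trial_corr,
            "seed": self.seed,
        }
        for k, v in self.field_count_fractions.items():
            row[f"frac_{k}_fields"] = v
        for (sf, tf), v in self.sf_tf_fractions.items():
            row[f"frac_sf{sf}_tf{tf}"] = v
        return row


def run_session(
    sim: SimConfig,
    session_id: str = "session",
    subregion: str = "anterior",
    stages: tuple = ("position", "decode"),
    stim_params: StimulusParams | None = None,
    n_shuffles: int = pt.N_SHUFFLES,
    decode_scheme: str = "odd_even",
    decode_n_neurons: int | None = None,
) -> dict:
    """Run a full synthetic session and summarize it.

    Returns a dict with keys ``summary`` (SessionSummary), ``tuning``
    (per-neuron DataFrame or None), ``visual`` (per-neuron DataFrame or
    None), ``decode`` (DecodeResult or None), and ``truth`` tables.  All
    randomness derives from ``sim.seed``.
    """
    out = {"summary": None, "tuning": None, "visual": None, "decode": None,
           "truth": {}}
    summary = SessionSummary(
        session_id=session_id, subregion=subregion, n_neurons=sim.n_neurons,
        seed=sim.seed,
    )

    if "position" in stages or "decode" in stages:
        behavior = simulate_behavior(sim)
        traces, truth = simulate_place_cells(behavior, sim)
        out["truth"]["position"] = truth
        dff, events = tp.preprocess(traces)
        epochs = ba.detect_running_epochs(behavior)

        if "position" in stages:
            table, _profiles, _shuffle = pt.analyze_position_tuning(
                events.events, dff.dff, behavior, epochs,
                n_shuffles=n_shuffles, seed=sim.seed + 101,
            )
            out["tuning"] = table
            tuned = table[table["is_tuned"]]
            summary.frac_position_tuned = float(table["is_tuned"].mean())
            if len(tuned):
                summary.mean_si_bits_per_event = float(tuned["si_bits_per_event"].mean())
                summary.mean_width_cm = float(tuned["width_cm"].mean())
                summary.mean_trial_corr = float(tuned["trial_corr"].mean())
                counts = tuned["n_fields"].value_counts(normalize=True)
                summary.field_count_fractions = {
                    int(k): float(v) for k, v in counts.items()
                }

        if "decode" in stages:
            result = bd.cross_validate(
                events.events, behavior, epochs, scheme=decode_scheme,
                n_neurons=decode_n_neurons, seed=sim.seed + 202,
            )
            out["decode"] = result
            summary.median_decode_error_cm = result.median_error_cm

    if "visual" in stages:
        vtraces, stim_table, vtruth = simulate_visual_session(sim, stim_params)
        out["truth"]["visual"] = vtruth
        vdff, _vevents = tp.preprocess(vtraces)
        vtable, _profiles = vt.analyze_visual_session(
            vdff.dff, stim_table, sim.rate_hz
        )
        out["visual"] = vtable
        summary.frac_visual = float(vtable["is_visual"].mean())
        responsive = vtable[vtable["is_visual"]]
        if len(responsive):
            combo = responsive.groupby(["pref_sf_cpd", "pref_tf_hz"]).size()
            summary.sf_tf_fractions = {
                (float(sf), float(tf)): float(n / len(responsive))
                for (sf, tf), n in combo.items()
            }

    out["summary"] = summary
    return out


def run_cohort(
    n_sessions: int,
    subregion: str,
    base_seed: int,
    stages: tuple = ("position",),
    n_shuffles: int = pt.N_SHUFFLES,
    **sim_overrides,
) -> pd.DataFrame:
    """Run ``n_sessions`` seeded synthetic sessions and stack their summaries."""
    rows = []
    for k in range(n_sessions):
        sim = SimConfig(seed=base_seed + 1000 * k, **sim_overrides)
        res = run_session(
            sim,
            session_id=f"{subregion}-{k}",
            subregion=subregion,
            stages=stages,
            n_shuffles=n_shuffles,
        )
        rows.append(res["summary"].to_row())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def mannwhitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for sample x versus y.

    U counts pairs where x beats y (ties half).  The exact null
    distribution is used for small tie-free samples (min n <= 8); otherwise
    the tie-corrected normal approximation.  Identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: D = sup |ECDF_x - ECDF_y|, asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("samples must have at least 2 values")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """Session-level (U) and optional pooled (KS) comparison of one metric."""

    metric: str
    groups: tuple
    values: dict
    u_statistic: float
    u_pvalue: float
    stars: str
    means: dict
    sems: dict
    n: dict
    ks_statistic: float = float("nan")
    ks_pvalue: float = float("nan")


def compare_groups(
    summaries: pd.DataFrame,
    metric: str,
    group_col: str = "subregion",
    pooled: dict | None = None,
) -> GroupComparison:
    """Compare one session-level metric between two groups.

    ``summaries`` holds one row per session.  ``pooled``, when given, maps
    group label -> pooled neuron-level values compared by KS.  Order of the
    input rows never affects the result.
    """
    if metric not in summaries.columns:
        raise ValueError(f"unknown metric {metric!r}")
    groups = tuple(sorted(summaries[group_col].unique()))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    values = {
        g: summaries.loc[summaries[group_col] == g, metric].dropna().to_numpy()
        for g in groups
    }
    u, p = mannwhitney_u(values[groups[0]], values[groups[1]])
    means = {g: float(np.mean(v)) for g, v in values.items()}
    sems = {
        g: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
        for g, v in values.items()
    }
    comp = GroupComparison(
        metric=metric,
        groups=groups,
        values=values,
        u_statistic=u,
        u_pvalue=p,
        stars=significance_stars(p),
        means=means,
        sems=sems,
        n={g: int(len(v)) for g, v in values.items()},
    )
    if pooled is not None:
        ks_d, ks_p = ks_two_sample(pooled[groups[0]], pooled[groups[1]])
        comp.ks_statistic, comp.ks_pvalue = ks_d, ks_p
    return comp
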