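"""Retrograde-tracing quantification: hierarchical aggregation, input
fractions, volume-normalized densities, bias index, and dorsoventral
profiles.

Labeled-cell tables carry one row per cell (acronym, injection target
anterior/posterior, optional coordinates).  Cells are aggregated up a
rooted region ontology, fractions are computed per injection target, and
the anterior/posterior bias of a region is the log2 ratio of its posterior
to anterior input fractions (positive = posterior-biased).  A synthetic
ontology fixture (~40 regions with nominal volumes) ships with the package;
a full atlas-derived CSV with the same columns can be supplied instead.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import ks_2samp

__all__ = [
    "RegionOntology",
    "default_ontology",
    "aggregate_counts",
    "input_fractions",
    "volume_density",
    "group_fractions",
    "bias_index",
    "bias_index_table",
    "dv_profile",
    "injection_density",
]

TARGETS = ("anterior", "posterior")


class RegionOntology:
    """Rooted region tree with group labels and leaf volumes.

    Built from a CSV with columns region_id, acronym, parent_id, group,
    volume_mm3 (volumes may be empty for non-leaf regions).
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table.copy()
        self._by_acronym = {r.acronym: r for r in table.itertuples()}
        self._by_id = {r.region_id: r for r in table.itertuples()}
        roots = table[table["parent_id"].isna()]
        if len(roots) != 1:
            raise ValueError("ontology must have exactly one root")
        self.root = roots.iloc[0]["acronym"]
        self._check_acyclic()

    @classmethod
    def from_csv(cls, path) -> "RegionOntology":
        t = pd.read_csv(path)
        return cls(t)

    def _check_acyclic(self):
        for acr in self._by_acronym:
            seen = set()
            cur = acr
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in ontology at {cur!r}")
                seen.add(cur)
                cur = self.parent(cur)

    def __contains__(self, acronym: str) -> bool:
        return acronym in self._by_acronym

    def parent(self, acronym: str) -> str | None:
        row = self._by_acronym[acronym]
        if pd.isna(row.parent_id):
            return None
        return self._by_id[int(row.parent_id)].acronym

    def ancestors(self, acronym: str) -> list:
        """acronym itself, then each parent up to the root."""
        out = [acronym]
        cur = acronym
        while (cur := self.parent(cur)) is not None:
            out.append(cur)
        return out

    def children(self, acronym: str) -> list:
        rid = self._by_acronym[acronym].region_id
        return list(self.table[self.table["parent_id"] == rid]["acronym"])

    def leaves(self, acronym: str) -> list:
        kids = self.children(acronym)
        if not kids:
            return [acronym]
        out = []
        for k in kids:
            out.extend(self.leaves(k))
        return out

    def group(self, acronym: str) -> str:
        return self._by_acronym[acronym].group

    def volume(self, acronym: str) -> float:
        """Volume of a region = sum of its leaf volumes (NaN if any missing)."""
        vols = [self._by_acronym[l].volume_mm3 for l in self.leaves(acronym)]
        if any(pd.isna(v) for v in vols):
            return float("nan")
        return float(np.sum(vols))

    def level_regions(self, level) -> list:
        """Resolve a named level ('major' = children of the root, 'group' =
        distinct group labels with members) or pass through an explicit list."""
        if isinstance(level, str):
            if level == "major":
                return self.children(self.root)
            if level == "group":
                return sorted(set(self.table["group"]) - {self.root})
            raise ValueError(f"unknown level {level!r}")
        return list(level)


def default_ontology() -> RegionOntology:
    """The bundled synthetic ontology fixture (nominal volumes)."""
    ref = importlib.resources.files("navcode.data") / "ontology.csv"
    with importlib.resources.as_file(ref) as path:
        return RegionOntology.from_csv(path)


def aggregate_counts(
    cells: pd.DataFrame, ontology: RegionOntology, level
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts per (level region x injection target), plus a rejects report.

    Each cell is assigned to its ancestor among the requested level regions;
    cells whose acronym is unresolvable, or has no ancestor at the level,
    are listed in the rejects table and excluded from totals.
    """
    regions = ontology.level_regions(level)
    region_set = set(regions)
    assigned = []
    rejects = []
    for row in cells.itertuples():
        if row.acronym not in ontology:
            rejects.append({"cell_id": row.cell_id, "acronym": row.acronym,
                            "reason": "unknown acronym"})
            continue
        hit = next((a for a in ontology.ancestors(row.acronym) if a in region_set), None)
        if hit is None:
            rejects.append({"cell_id": row.cell_id, "acronym": row.acronym,
                            "reason": "no ancestor at level"})
            continue
        assigned.append({"region": hit, "injection_target": row.injection_target})
    targets = sorted(cells["injection_target"].unique()) if len(cells) else list(TARGETS)
    counts = pd.DataFrame(0, index=pd.Index(regions, name="region"),
                          columns=pd.Index(targets, name="injection_target"))
    if assigned:
        tab = pd.DataFrame(assigned).value_counts().unstack(fill_value=0)
        counts = counts.add(tab.reindex(index=regions, columns=targets, fill_value=0),
                            fill_value=0).astype(int)
    rej = pd.DataFrame(rejects, columns=["cell_id", "acronym", "reason"])
    return counts, rej


def input_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each target's total inputs per region; columns sum to 1."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero total inputs for target(s) {bad}")
    return counts / totals


def volume_density(counts: pd.DataFrame, ontology: RegionOntology) -> pd.DataFrame:
    """Cells per mm^3 of the aggregated region; NaN where volume is missing."""
    vols = np.array([ontology.volume(r) for r in counts.index])
    with np.errstate(invalid="ignore", divide="ignore"):
        return counts.div(pd.Series(vols, index=counts.index), axis=0)


def group_fractions(
    cells: pd.DataFrame, ontology: RegionOntology, group: str
) -> pd.DataFrame:
    """Within-group fractions: each subregion over the group total, per target.

    Sub-regions are the children of ``group``; columns sum to 1 for targets
    with any labeled cell in the group, and are NaN otherwise.
    """
    subs = ontology.children(group)
    if not subs:
        subs = [group]
    counts, _ = aggregate_counts(cells, ontology, subs)
    totals = counts.sum(axis=0)
    out = counts.astype(float)
    for c in counts.columns:
        out[c] = counts[c] / totals[c] if totals[c] > 0 else np.nan
    return out


def bias_index(f_posterior: float, f_anterior: float) -> float:
    """log2(f_posterior / f_anterior); positive = posterior-biased.

    Exactly antisymmetric under swapping the targets.  NaN when either
    fraction is non-positive (use a count-stage pseudocount upstream).
    """
    if not (f_posterior > 0 and f_anterior > 0):
        return float("nan")
    return float(np.log2(f_posterior / f_anterior))


def bias_index_table(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.Series:
    """Per-region bias index from a counts table with anterior/posterior columns.

    When any count is zero, ``pseudocount`` cells are added to every
    region x target entry before fractions are formed, keeping the log
    finite; raw counts are unaffected.
    """
    for t in TARGETS:
        if t not in counts.columns:
            raise ValueError(f"counts must have an {t!r} column")
    work = counts[list(TARGETS)].astype(float)
    if (work.to_numpy() == 0).any():
        work = work + pseudocount
    frac = work / work.sum(axis=0)
    return pd.Series(
        np.log2(frac["posterior"] / frac["anterior"]),
        index=counts.index,
        name="bias_index",
    )


def dv_profile(
    cells: pd.DataFrame,
    ontology: RegionOntology,
    region: str = "SUB",
    coord_col: str = "dv_mm",
):
    """Dorsoventral CDFs per injection target within one region, plus a KS test.

    Cells outside the region or missing the coordinate are excluded (their
    count is reported).  Returns a dict with per-target sorted coordinates,
    the two-sample KS statistic, p-value, and exclusion count.
    """
    region_set = set(ontology.leaves(region)) | {region}
    in_region = cells["acronym"].isin(region_set)
    sub = cells[in_region]
    excluded = int(sub[coord_col].isna().sum())
    sub = sub.dropna(subset=[coord_col])
    samples = {}
    for target, grp in sub.groupby("injection_target"):
        samples[target] = np.sort(grp[coord_col].to_numpy())
    if len(samples) != 2 or any(len(v) < 2 for v in samples.values()):
        raise ValueError("need >= 2 coordinate-bearing cells per target in region")
    (t1, x), (t2, y) = sorted(samples.items())
    ks = ks_2samp(x, y)
    return {
        "samples": samples,
        "ks_statistic": float(ks.statistic),
        "p_value": float(ks.pvalue),
        "n_excluded": excluded,
    }


def injection_density(
    image: np.ndarray,
    background_mask: np.ndarray | None = None,
    percentile: float = 90.0,
    smooth_sigma_px: float = 2.0,
) -> dict:
    """Normalized fluorescence-density summary of an injection-site image.

    Smooth -> percentile-normalize (99th) -> subtract the background
    estimate -> rescale to [0, 1]; reports the requested percentile contour
    level and its supra-threshold mask.  Scaling the raw intensities leaves
    the output unchanged.  A constant image is degenerate and flagged.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if np.ptp(img) == 0:
        return {"normalized": np.zeros_like(img), "level": float("nan"),
                "mask": np.zeros(img.shape, dtype=bool), "degenerate": True}
    sm = gaussian_filter(img, smooth_sigma_px)
    hi = np.percentile(sm, 99.0)
    sm = sm / hi if hi != 0 else sm
    if background_mask is not None:
        bg = float(np.median(sm[np.asarray(background_mask, dtype=bool)]))
    else:
        bg = float(np.median(sm))
    sm = sm - bg
    lo, top = sm.min(), sm.max()
    norm = (sm - lo) / (top - lo)
    level = float(np.percentile(norm, percentile))
    return {"normalized": norm, "level": level, "mask": norm >= level,
            "degenerate": False}
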