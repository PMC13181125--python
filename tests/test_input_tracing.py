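"""Ontology aggregation, fractions, densities, bias index, DV profiles."""

import numpy as np
import pandas as pd
import pytest

from navcode.input_tracing import (
    aggregate_counts,
    bias_index,
    bias_index_table,
    default_ontology,
    dv_profile,
    group_fractions,
    injection_density,
    input_fractions,
    volume_density,
)
from navcode.synthetic_session import simulate_anatomy_counts


@pytest.fixture(scope="module")
def onto():
    return default_ontology()


def cells_df(rows):
    return pd.DataFrame(rows, columns=["cell_id", "acronym",
                                       "injection_target", "dv_mm"])


class TestAggregation:
    def test_visual_subregions_roll_up(self, onto):
        cells = cells_df([
            (0, "VISp", "anterior", np.nan),
            (1, "VISpm", "anterior", np.nan),
            (2, "SUB", "anterior", np.nan),
        ])
        counts, rej = aggregate_counts(cells, onto, ["VIS", "RHP"])
        assert counts.loc["VIS", "anterior"] == 2
        assert counts.loc["RHP", "anterior"] == 1
        assert len(rej) == 0

    def test_empty_table_gives_zero_counts(self, onto):
        counts, rej = aggregate_counts(cells_df([]), onto, "major")
        assert (counts.to_numpy() == 0).all() and len(rej) == 0

    def test_conservation_with_rejects(self, onto):
        cells = cells_df([
            (0, "VISp", "anterior", np.nan),
            (1, "NOPE", "anterior", np.nan),  # unknown acronym
            (2, "AM", "posterior", np.nan),
            (3, "ENT", "posterior", np.nan),
        ])
        counts, rej = aggregate_counts(cells, onto, "major")
        assert counts.to_numpy().sum() == len(cells) - len(rej)
        assert list(rej["acronym"]) == ["NOPE"]

    def test_level_consistency(self, onto):
        # totals are conserved between a coarse and a fine antichain
        cells = simulate_anatomy_counts(
            ["VISp", "VISpm", "SUB", "ENT", "AM"], {"anterior": 500},
            {"anterior": dict(zip(["VISp", "VISpm", "SUB", "ENT", "AM"],
                                  [0.2, 0.2, 0.2, 0.2, 0.2]))}, seed=3,
        )
        coarse, _ = aggregate_counts(cells, onto, "major")
        fine, _ = aggregate_counts(cells, onto, ["VIS", "RHP", "ATN"])
        assert coarse.to_numpy().sum() == fine.to_numpy().sum() == 500


class TestFractions:
    def test_closed_forms(self):
        counts = pd.DataFrame({"anterior": [300, 700]}, index=["A", "B"])
        f = input_fractions(counts)
        np.testing.assert_allclose(f["anterior"], [0.3, 0.7])
        single = pd.DataFrame({"anterior": [42]}, index=["A"])
        assert input_fractions(single).iloc[0, 0] == 1.0
        with pytest.raises(ValueError):
            input_fractions(pd.DataFrame({"anterior": [0, 0]}, index=["A", "B"]))

    def test_multinomial_recovery_within_3_binomial_sd(self, onto):
        bias = {"anterior": {"VISp": 0.3, "SUB": 0.7}}
        cells = simulate_anatomy_counts(["VISp", "SUB"], {"anterior": 10000},
                                        bias, seed=5)
        counts, _ = aggregate_counts(cells, onto, ["VISp", "SUB"])
        f = input_fractions(counts)["anterior"]
        for r, p in bias["anterior"].items():
            sd = np.sqrt(p * (1 - p) / 10000)
            assert abs(f[r] - p) <= 3 * sd


class TestVolumeDensity:
    def test_cells_per_cubic_mm(self, onto):
        counts = pd.DataFrame({"anterior": [100]}, index=["SUB"])  # 1.1 mm3
        d = volume_density(counts, onto)
        assert d.loc["SUB", "anterior"] == pytest.approx(100 / 1.1)

    def test_aggregated_volume_is_leaf_sum(self, onto):
        leaf_sum = sum(onto.volume(l) for l in onto.leaves("VIS"))
        assert onto.volume("VIS") == pytest.approx(leaf_sum)
        counts = pd.DataFrame({"anterior": [0]}, index=["VIS"])
        assert volume_density(counts, onto).iloc[0, 0] == 0.0


class TestGroupFractions:
    def test_single_labeled_subregion(self, onto):
        cells = cells_df([(0, "VISp", "anterior", np.nan)] * 5)
        gf = group_fractions(cells, onto, "VIS")
        assert gf.loc["VISp", "anterior"] == 1.0

    def test_equal_split(self, onto):
        rows = []
        for i, r in enumerate(["VISp", "VISpm", "VISam", "VISal"] * 3):
            rows.append((i, r, "anterior", np.nan))
        gf = group_fractions(cells_df(rows), onto, "VIS")
        for r in ["VISp", "VISpm", "VISam", "VISal"]:
            assert gf.loc[r, "anterior"] == pytest.approx(0.25)

    def test_sums_to_one_on_random_tables(self, onto, rng):
        regions = ["SUB", "ENT", "POST", "PRE"]
        p = rng.random(4)
        p /= p.sum()
        cells = simulate_anatomy_counts(
            regions, {"anterior": 400, "posterior": 300},
            {t: dict(zip(regions, p)) for t in ("anterior", "posterior")},
            seed=int(rng.integers(1 << 30)),
        )
        gf = group_fractions(cells, onto, "RHP")
        np.testing.assert_allclose(gf.sum(axis=0), 1.0, atol=1e-12)


class TestBiasIndex:
    def test_closed_forms_and_antisymmetry(self):
        assert bias_index(0.25, 0.25) == 0.0
        assert bias_index(0.4, 0.1) == pytest.approx(2.0)
        assert bias_index(0.1, 0.4) == pytest.approx(-2.0)
        assert np.isnan(bias_index(0.0, 0.0))

    def test_table_antisymmetric_under_target_swap(self, rng):
        counts = pd.DataFrame(
            {"anterior": rng.integers(0, 50, 6),
             "posterior": rng.integers(0, 50, 6)},
            index=list("ABCDEF"),
        )
        b = bias_index_table(counts)
        swapped = counts.rename(columns={"anterior": "posterior",
                                         "posterior": "anterior"})
        np.testing.assert_allclose(bias_index_table(swapped), -b, atol=1e-12)

    def test_pseudocount_keeps_log_finite(self):
        counts = pd.DataFrame({"anterior": [0, 10], "posterior": [5, 5]},
                              index=["A", "B"])
        b = bias_index_table(counts)
        assert np.isfinite(b).all()


class TestDvProfile:
    def _cells(self, a_coords, p_coords):
        rows = []
        for i, v in enumerate(a_coords):
            rows.append((i, "SUB", "anterior", v))
        for j, v in enumerate(p_coords):
            rows.append((1000 + j, "SUB", "posterior", v))
        return cells_df(rows)

    def test_identical_sets_give_zero(self, onto):
        x = np.linspace(0.5, 2.5, 20)
        prof = dv_profile(self._cells(x, x), onto)
        assert prof["ks_statistic"] == 0.0

    def test_disjoint_supports_give_one(self, onto):
        prof = dv_profile(self._cells(np.linspace(0, 1, 10),
                                      np.linspace(2, 3, 10)), onto)
        assert prof["ks_statistic"] == 1.0

    def test_matches_brute_force_cdf_scan(self, onto, rng):
        x = rng.normal(1.0, 0.3, 200)
        y = rng.normal(1.4, 0.3, 150)
        prof = dv_profile(self._cells(x, y), onto)
        grid = np.sort(np.concatenate([x, y]))
        fx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
        fy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
        assert prof["ks_statistic"] == pytest.approx(
            np.max(np.abs(fx - fy)), abs=1e-12)


class TestInjectionDensity:
    def _disc_image(self, scale=1.0):
        yy, xx = np.mgrid[0:60, 0:60]
        img = np.full((60, 60), 10.0)
        img[(yy - 30) ** 2 + (xx - 30) ** 2 < 64] = 100.0
        return scale * img

    def test_contour_encloses_bright_disc(self):
        out = injection_density(self._disc_image())
        assert not out["degenerate"]
        assert out["mask"][30, 30]
        assert not out["mask"][5, 5]

    def test_intensity_scale_invariance(self):
        a = injection_density(self._disc_image())
        b = injection_density(self._disc_image(scale=10.0))
        np.testing.assert_allclose(a["normalized"], b["normalized"], atol=1e-9)
        assert a["level"] == pytest.approx(b["level"], abs=1e-9)

    def test_level_matches_sort_based_percentile(self, rng):
        img = rng.random((40, 40))
        out = injection_density(img, smooth_sigma_px=1.0)
        assert out["level"] == pytest.approx(
            np.percentile(np.sort(out["normalized"].ravel()), 90), abs=1e-9)

    def test_constant_image_degenerate(self):
        out = injection_density(np.ones((10, 10)))
        assert out["degenerate"] and np.isnan(out["level"])
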