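"""Tuning maps, shuffle test, field detection, SI, trial reliability."""

import numpy as np
import pytest

from navcode.position_tuning import (
    Field,
    TuningProfile,
    classify_position_tuned,
    detect_fields,
    shuffle_test,
    spatial_information,
    trial_correlation,
    tuning_map,
)


def profile_from_map(mean_map, n_trials=6, bin_size=1.5, p_occ=None):
    """TuningProfile with identical trials built directly from a mean map."""
    mean_map = np.asarray(mean_map, dtype=float)
    n = len(mean_map)
    maps = np.tile(mean_map, (n_trials, 1))
    return TuningProfile(
        per_trial_map=maps,
        mean_map=mean_map.copy(),
        sem_map=np.zeros(n),
        p_occ=np.full(n, 1.0 / n) if p_occ is None else p_occ,
        bin_size_cm=bin_size,
    )


class TestTuningMap:
    def test_localized_events_and_linearity(self, small_tuned_session):
        s = small_tuned_session
        ev = s.events.events[0]
        prof = tuning_map(ev, s.behavior, s.epochs)
        prof2 = tuning_map(2.0 * ev, s.behavior, s.epochs)
        np.testing.assert_allclose(prof2.mean_map, 2.0 * prof.mean_map,
                                   atol=1e-9, equal_nan=True)
        assert prof.p_occ.sum() == pytest.approx(1.0)
        assert np.nanmin(prof.mean_map) >= 0.0

    def test_peak_recovers_ground_truth_center(self, small_tuned_session):
        s = small_tuned_session
        tuned_ids = np.flatnonzero(s.truth.is_tuned.to_numpy())
        hits = 0
        for i in tuned_ids:
            prof = tuning_map(s.events.events[i], s.behavior, s.epochs)
            peak_cm = (np.nanargmax(prof.mean_map) + 0.5) * prof.bin_size_cm
            d = abs(peak_cm - s.truth.field_center_cm.iloc[i])
            if min(d, 150 - d) <= 3.0:  # within 2 bins
                hits += 1
        assert hits >= 0.9 * len(tuned_ids)

    def test_too_few_laps_rejected(self, small_tuned_session):
        s = small_tuned_session
        import copy

        from navcode.datatypes import BehaviorTrack, RunningEpochs

        n = 100
        short = BehaviorTrack(
            t=s.behavior.t[:n], position_cm=s.behavior.position_cm[:n],
            speed_cm_s=s.behavior.speed_cm_s[:n], lap_id=np.zeros(n, int),
            track_length_cm=150.0,
        )
        ep = RunningEpochs(intervals=np.array([[0.0, n / 30.0]]),
                           mask=np.ones(n, bool))
        with pytest.raises(ValueError):
            tuning_map(s.events.events[0][:n], short, ep)


class TestShuffleTest:
    def test_recovers_tuned_and_rejects_untuned(self, small_tuned_session):
        s = small_tuned_session
        res = shuffle_test(s.events.events, s.behavior, s.epochs,
                           n_shuffles=100, seed=42)
        truth = s.truth.is_tuned.to_numpy()
        assert res.significant[truth].mean() >= 0.9
        assert res.significant[~truth].mean() <= 0.2

    def test_deterministic_given_seed(self, small_tuned_session):
        s = small_tuned_session
        ev = s.events.events[:4]
        r1 = shuffle_test(ev, s.behavior, s.epochs, n_shuffles=30, seed=5)
        r2 = shuffle_test(ev, s.behavior, s.epochs, n_shuffles=30, seed=5)
        np.testing.assert_array_equal(r1.significant, r2.significant)
        np.testing.assert_allclose(r1.null_percentile, r2.null_percentile,
                                   equal_nan=True)

    def test_session_too_short_rejected(self, small_tuned_session):
        s = small_tuned_session
        with pytest.raises(ValueError):
            shuffle_test(s.events.events[:1], s.behavior, s.epochs,
                         min_shift_s=200.0)


class TestDetectFields:
    def test_gaussian_bump_width_matches_analytic_crossing(self):
        # 30% crossing of exp(-d^2/(2 sd^2)) sits at d = sd*sqrt(2 ln(1/0.3))
        sd_bins = 8.0
        bins = np.arange(100)
        d = np.minimum(np.abs(bins - 50), 100 - np.abs(bins - 50))
        bump = np.exp(-(d**2) / (2 * sd_bins**2))
        fields = detect_fields(profile_from_map(bump))
        assert len(fields) == 1
        analytic_span_bins = 2.0 * sd_bins * np.sqrt(2.0 * np.log(1.0 / 0.3))
        assert abs(fields[0].width_cm / 1.5 - analytic_span_bins) <= 1.0
        assert abs(fields[0].peak_pos_cm - 50.5 * 1.5) <= 1.5

    def test_narrow_bump_discarded(self):
        m = np.zeros(100)
        m[48:54] = 1.0  # 9 cm span, below the 15 cm minimum
        assert detect_fields(profile_from_map(m)) == []

    def test_two_separated_bumps(self):
        m = np.zeros(100)
        m[10:25] = 1.0
        m[60:75] = 1.0
        assert len(detect_fields(profile_from_map(m))) == 2

    def test_flat_map_has_no_fields(self):
        assert detect_fields(profile_from_map(np.ones(100))) == []

    def test_field_straddling_the_seam(self):
        m = np.zeros(100)
        m[:8] = 1.0
        m[-8:] = 1.0  # one circular field across 0 cm
        fields = detect_fields(profile_from_map(m))
        assert len(fields) == 1
        assert fields[0].width_cm == pytest.approx(16 * 1.5)

    def test_presence_criterion_filters_unreliable_fields(self):
        m = np.zeros(100)
        m[40:60] = 1.0
        prof = profile_from_map(m, n_trials=9)
        prof.per_trial_map[3:] = 0.0  # present in only 3 of 9 trials
        assert detect_fields(prof) == []  # 1/3 is not strictly more


class TestSpatialInformation:
    def test_uniform_map_is_zero(self):
        si = spatial_information(np.full(100, 0.01), np.full(100, 3.3))
        assert si == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 10, 100])
    def test_single_bin_activity_gives_log2_n(self, n):
        m = np.zeros(n)
        m[n // 2] = 5.0
        si = spatial_information(np.full(n, 1.0 / n), m)
        assert si == pytest.approx(np.log2(n), abs=1e-9)

    def test_matches_termwise_summation_oracle(self, rng):
        p = rng.random(100)
        p /= p.sum()
        m = rng.random(100) * 4.0
        f = np.sum(p * m)
        expected = sum(
            p[i] * (m[i] / f) * np.log2(m[i] / f) for i in range(100) if m[i] > 0
        )
        assert spatial_information(p, m) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_and_scale_invariant(self, rng):
        for _ in range(200):
            p = rng.random(50)
            p /= p.sum()
            m = rng.random(50) * rng.uniform(0.1, 10)
            si = spatial_information(p, m)
            assert si >= -1e-12
            assert spatial_information(p, 7.3 * m) == pytest.approx(si, abs=1e-9)

    def test_zero_activity_is_nan(self):
        assert np.isnan(spatial_information(np.full(10, 0.1), np.zeros(10)))


class TestTrialCorrelation:
    def test_identical_and_negated(self, rng):
        base = rng.random(100)
        assert trial_correlation(np.tile(base, (4, 1))) == pytest.approx(1.0)
        assert trial_correlation(np.stack([base, -base])) == pytest.approx(-1.0)

    def test_matches_pairwise_enumeration_oracle(self, rng):
        template = rng.random(100)
        maps = template[None, :] + 0.3 * rng.standard_normal((4, 100))
        cors = []
        for i in range(4):
            for j in range(i + 1, 4):
                cors.append(np.corrcoef(maps[i], maps[j])[0, 1])
        assert trial_correlation(maps) == pytest.approx(np.median(cors), abs=1e-12)

    def test_constant_pairs_skipped(self):
        maps = np.stack([np.ones(10), np.ones(10)])
        assert np.isnan(trial_correlation(maps))


class TestClassifyPositionTuned:
    def _field(self, width, peak=50.0):
        return Field(peak_pos_cm=peak, width_cm=width,
                     bins=np.arange(int(width / 1.5)), peak_rate=1.0,
                     presence_frac=1.0)

    def test_significant_with_valid_field(self):
        tuned, width, n, peak = classify_position_tuned(True, [self._field(45.0)])
        assert tuned and width == 45.0 and n == 1 and peak == 50.0

    def test_not_tuned_without_significance_or_field(self):
        assert not classify_position_tuned(False, [self._field(45.0)])[0]
        assert not classify_position_tuned(True, [])[0]

    def test_field_count_capped_at_three(self):
        fields = [self._field(20.0, p) for p in (10, 40, 80, 120)]
        _, _, n, _ = classify_position_tuned(True, fields)
        assert n == 3
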