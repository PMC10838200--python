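"""R-R cleaning, even resampling, HRV-in-bpm and the active-sleep rule."""

import numpy as np
import pytest

from neorsa import (
    EpochRejectionError,
    ObservationRecord,
    Tachogram,
    beat_times_from_heart_period,
    classify_active_sleep,
    clean_rr,
    hrv_bpm_range,
    resample_tachogram,
    scenario_a,
    simulate_heart_period,
)


def _constant_tachogram(n=60, rr=375.0):
    beats = rr / 1000.0 * np.arange(1, n + 1)
    return Tachogram(beat_times=beats, rr_ms=np.full(n, rr))


class TestCleanRR:
    def test_clean_series_untouched(self):
        t = _constant_tachogram()
        out = clean_rr(t)
        assert np.array_equal(out.rr_ms, t.rr_ms)
        assert not out.artifact_flags.any()

    def test_missed_beat_flagged_and_repaired(self):
        t = _constant_tachogram()
        rr = t.rr_ms.copy()
        rr[30] = 750.0  # a missed beat doubles one interval
        corrupted = Tachogram(beat_times=t.beat_times, rr_ms=rr)
        out = clean_rr(corrupted)
        assert out.artifact_flags.sum() == 1
        assert out.artifact_flags[30]
        assert out.rr_ms[30] == pytest.approx(375.0, abs=1.0)

    def test_too_many_artifacts_rejects_epoch(self):
        t = _constant_tachogram(n=100)
        rr = t.rr_ms.copy()
        rr[::10] = 900.0  # 10% corrupted
        with pytest.raises(EpochRejectionError):
            clean_rr(Tachogram(beat_times=t.beat_times, rr_ms=rr))

    def test_idempotence(self):
        rng = np.random.default_rng(4)
        t = _constant_tachogram(n=80)
        rr = t.rr_ms + rng.normal(0, 5, 80)
        rr[10] = 760.0
        once = clean_rr(Tachogram(beat_times=t.beat_times, rr_ms=rr))
        twice = clean_rr(once)
        assert np.array_equal(once.rr_ms, twice.rr_ms)

    def test_needs_ten_intervals(self):
        with pytest.raises(ValueError):
            clean_rr(_constant_tachogram(n=5))


class TestResample:
    def test_constant_series_resamples_constant(self):
        out = resample_tachogram(_constant_tachogram())
        assert np.allclose(out.resampled.values, 375.0)
        assert np.allclose(np.diff(out.resampled.times), 0.25)

    def test_tracks_latent_sinusoid(self):
        cfg = scenario_a(seed=6, noise_sd=0.0)
        proc = simulate_heart_period(cfg)
        beats = beat_times_from_heart_period(proc)
        t = Tachogram(beat_times=beats[1:], rr_ms=np.diff(beats) * 1000.0)
        out = resample_tachogram(t, rate=4.0)
        # each interval is anchored at its ending beat, so the resampled
        # series lags the latent process by about half a heart period
        lag = np.mean(t.rr_ms) / 2000.0
        latent = np.interp(out.resampled.times - lag, proc.grid_times, proc.rr_values)
        r = np.corrcoef(out.resampled.values, latent)[0, 1]
        assert r >= 0.99

    def test_sample_count_45s_at_4hz(self):
        cfg = scenario_a(seed=8)
        beats = beat_times_from_heart_period(simulate_heart_period(cfg))
        t = Tachogram(beat_times=beats[1:], rr_ms=np.diff(beats) * 1000.0)
        n = resample_tachogram(t, rate=4.0).resampled.values.size
        assert 170 <= n <= 180

    def test_preserves_mean_heart_period(self):
        cfg = scenario_a(seed=9, noise_sd=0.0)
        beats = beat_times_from_heart_period(simulate_heart_period(cfg))
        t = Tachogram(beat_times=beats[1:], rr_ms=np.diff(beats) * 1000.0)
        out = resample_tachogram(t)
        assert np.mean(out.resampled.values) == pytest.approx(
            np.mean(t.rr_ms), abs=1.0
        )

    def test_short_span_rejected(self):
        with pytest.raises(EpochRejectionError):
            resample_tachogram(_constant_tachogram(n=12))


class TestHRVRange:
    def test_constant_rr_zero_range(self):
        assert hrv_bpm_range(_constant_tachogram()) == 0.0

    def test_alternating_series_hand_value(self):
        # rr alternating 350/400 ms: HR alternates 171.43/150 bpm and the
        # centered 3-beat median keeps the alternation, so the range is
        # 60000/350 - 60000/400
        rr = np.tile([350.0, 400.0], 20)
        beats = np.cumsum(rr) / 1000.0
        t = Tachogram(beat_times=beats, rr_ms=rr)
        expected = 60000.0 / 350.0 - 60000.0 / 400.0
        assert hrv_bpm_range(t) == pytest.approx(expected, abs=1e-9)

    def test_scenario_a_satisfies_criterion(self):
        cfg = scenario_a(seed=10)
        beats = beat_times_from_heart_period(simulate_heart_period(cfg))
        t = Tachogram(beat_times=beats[1:], rr_ms=np.diff(beats) * 1000.0)
        assert hrv_bpm_range(t) < 10.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        rr = 375.0 + rng.normal(0, 5, 60)
        beats = np.cumsum(rr) / 1000.0
        a = hrv_bpm_range(Tachogram(beat_times=beats, rr_ms=rr))
        b = hrv_bpm_range(Tachogram(beat_times=beats + 100.0, rr_ms=rr))
        assert a == b

    def test_monotone_in_modulation_depth(self):
        ranges = []
        for amp in (0.0, 5.0, 10.0, 20.0):
            cfg = scenario_a(seed=3, resp_amp=amp, noise_sd=0.0)
            beats = beat_times_from_heart_period(simulate_heart_period(cfg))
            t = Tachogram(beat_times=beats[1:], rr_ms=np.diff(beats) * 1000.0)
            ranges.append(hrv_bpm_range(t))
        assert all(b >= a for a, b in zip(ranges, ranges[1:]))

    def test_window_longer_than_record_rejected(self):
        with pytest.raises(ValueError):
            hrv_bpm_range(_constant_tachogram(n=20), window=100.0)


def _obs(pattern="irregular_shallow", eyes=True, movement=False):
    return ObservationRecord(
        subject_id="S1", rater_id="R1", pattern=pattern,
        eyes_closed=eyes, gross_movement=movement,
    )


class TestActiveSleep:
    @pytest.mark.parametrize(
        "pattern,eyes,movement,hrv,expected",
        [
            ("irregular_shallow", True, False, 8.0, True),
            ("irregular_shallow", True, False, 10.0, False),  # strict '<'
            ("irregular_shallow", True, False, 9.999, True),
            ("regular_deep", True, False, 8.0, False),
            ("irregular_shallow", False, False, 8.0, False),
            ("irregular_shallow", True, True, 8.0, False),
        ],
    )
    def test_truth_table(self, pattern, eyes, movement, hrv, expected):
        res = classify_active_sleep(_obs(pattern, eyes, movement), hrv)
        assert res.active_sleep is expected

    def test_missing_annotation_is_indeterminate(self):
        res = classify_active_sleep(_obs(eyes=None), 8.0)
        assert res.active_sleep is None
        assert res.criteria["eyes_closed"] is None

    def test_result_is_conjunction_of_criteria(self):
        res = classify_active_sleep(_obs(), 8.0)
        assert res.active_sleep == all(res.criteria.values())
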