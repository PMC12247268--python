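"""Energy ratios, threshold summaries, sliding windows, phase detection."""

import numpy as np
import pytest
from scipy import signal as sps

import svdc
from svdc.energy import EnergyTrace
from svdc.errors import ParameterError

from conftest import FS, make_tone


class TestSegmentEnergy:
    def test_constant(self):
        x = np.full(4, 2.0)
        assert svdc.segment_energy(x, fs=1.0, t0=0, t1=4) == 16.0

    def test_zero(self):
        assert svdc.segment_energy(np.zeros(100), fs=10.0, t0=0, t1=10) == 0.0

    def test_unit_sine_integer_periods(self):
        x = make_tone(4.0, 2.0, fs=100.0)
        e = svdc.segment_energy(x, fs=100.0, t0=0, t1=2)
        assert e == pytest.approx(x.size / 2, rel=0.01)

    def test_additive_over_disjoint_windows(self, rng):
        x = rng.normal(0, 1, 1000)
        total = svdc.segment_energy(x, 100.0, 0, 10)
        parts = sum(
            svdc.segment_energy(x, 100.0, a, a + 2.5) for a in (0, 2.5, 5.0, 7.5)
        )
        assert parts == pytest.approx(total, rel=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ParameterError):
            svdc.segment_energy(np.zeros(10), 10.0, 1.0, 1.0)


def _band_recording(tones, dur=240.0, fs=FS):
    x = sum(make_tone(f, dur, fs, amp) for f, amp in tones)
    rec = svdc.Recording(x[None, :], fs=fs, labels=["A1"])
    return rec


class TestEnergyRatio:
    def test_slow_tone_dominates_svdc(self):
        rec = _band_recording([(0.1, 1.0)])
        s = svdc.energy_ratio(rec, svdc.decompose(rec), 0, 240)
        assert s.per_lead.ratio_svdc[0] >= 0.95

    def test_fast_tone_leaves_svdc_empty(self):
        rec = _band_recording([(100.0, 1.0)], dur=60.0)
        s = svdc.energy_ratio(rec, svdc.decompose(rec), 0, 60)
        sos = sps.butter(2, 0.5, "lowpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[100.0], fs=FS)
        assert s.per_lead.ratio_svdc[0] <= max(0.02, 10 * float(np.abs(h[0]) ** 4))
        assert s.per_lead.ratio_svdc[0] <= 0.02

    def test_equal_rms_mixture_splits_evenly(self):
        # Parseval: two equal-RMS tones, one per band, split the total 50/50
        rec = _band_recording([(0.1, 1.0), (100.0, 1.0)])
        s = svdc.energy_ratio(rec, svdc.decompose(rec), 20, 220)
        assert s.per_lead.ratio_svdc[0] == pytest.approx(0.5, abs=0.05)
        assert s.per_lead.ratio_hf[0] == pytest.approx(0.5, abs=0.05)

    def test_zero_total_energy_reported_missing(self):
        rec = svdc.Recording(np.zeros((1, 8192)), fs=FS, labels=["A1"])
        s = svdc.energy_ratio(rec, svdc.decompose(rec), 0, 8)
        assert np.isnan(s.per_lead.ratio_svdc[0])

    def test_ratios_sum_near_unity_on_band_limited_signal(self):
        rec = _band_recording([(0.1, 2.0), (10.0, 1.0), (100.0, 0.5)])
        s = svdc.energy_ratio(rec, svdc.decompose(rec), 20, 220)
        total = float(
            s.per_lead.ratio_svdc[0] + s.per_lead.ratio_lf[0] + s.per_lead.ratio_hf[0]
        )
        assert 0.8 <= total <= 1.1


class TestIctalWindow:
    def test_default_four_minutes(self):
        assert svdc.ictal_window(300.0) == (180.0, 420.0)

    def test_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clip"):
            t0, t1 = svdc.ictal_window(60.0, record_duration=600.0)
        assert (t0, t1) == (0.0, 180.0)

    def test_negative_onset_rejected(self):
        with pytest.raises(ParameterError):
            svdc.ictal_window(-5.0)


class TestThresholdSummary:
    def test_reported_lead_fractions_reproduced(self):
        # the published seizure-level counts: 5140 and 2589 of 6360 leads
        ratios = np.concatenate(
            [np.full(2589, 0.95), np.full(5140 - 2589, 0.75), np.full(1220, 0.30)]
        )
        df = svdc.threshold_summary(ratios, thresholds=(0.6, 0.9))
        assert df.loc[df.threshold == 0.6, "count"].item() == 5140
        assert round(100 * df.loc[df.threshold == 0.6, "fraction"].item(), 2) == 80.82
        assert round(100 * df.loc[df.threshold == 0.9, "fraction"].item(), 2) == 40.71

    def test_all_ones(self):
        df = svdc.threshold_summary(np.ones(10))
        assert (df.fraction == 1.0).all()

    def test_fractions_non_increasing_and_inclusive(self, rng):
        ratios = rng.uniform(0, 1, 500)
        ratios[:5] = 0.6  # exactly at threshold counts as >=
        df = svdc.threshold_summary(ratios, thresholds=(0.3, 0.6, 0.9))
        fr = df.sort_values("threshold").fraction.to_numpy()
        assert (np.diff(fr) <= 0).all()
        assert df.loc[df.threshold == 0.6, "count"].item() == int(
            np.sum(ratios >= 0.6)
        )


class TestSlidingEnergy:
    def test_constant_signal(self):
        tr = svdc.sliding_energy(np.ones(600), fs=10.0, window_s=6.0)
        np.testing.assert_allclose(tr.values, 60.0)

    def test_impulse_localised(self):
        x = np.zeros(600)
        x[95] = 3.0
        tr = svdc.sliding_energy(x, fs=10.0, window_s=6.0)
        assert tr.values[1] == 9.0
        assert np.sum(tr.values) == 9.0

    def test_quadratic_scaling(self, rng):
        x = rng.normal(0, 1, 1200)
        a = svdc.sliding_energy(x, 10.0, 6.0).values
        b = svdc.sliding_energy(2 * x, 10.0, 6.0).values
        np.testing.assert_allclose(b, 4 * a, rtol=1e-12)


class TestActivePhases:
    def _trace(self, values, window=6.0):
        values = np.asarray(values, dtype=float)
        times = np.arange(values.size) * window
        return EnergyTrace(times=times, values=values, window_s=window, hop_s=window)

    def test_flat_trace_all_stable(self):
        ph = svdc.detect_active_phases(self._trace(np.ones(50)), baseline=1.0)
        assert ph.active == []
        assert ph.stable == [(0.0, 300.0)]

    def test_plateau_recovered_exactly(self):
        v = np.ones(50)
        v[10:15] = 2.5  # 30 s plateau at 2.5x baseline
        ph = svdc.detect_active_phases(
            self._trace(v), baseline=1.0, min_dur_s=12.0
        )
        assert ph.active == [(60.0, 90.0)]

    def test_exact_doubling_is_active(self):
        ph = svdc.detect_active_phases(self._trace(np.full(10, 2.0)), baseline=1.0)
        assert ph.active == [(0.0, 60.0)]
        assert ph.stable == []

    def test_short_bursts_dropped_and_gaps_merged(self):
        v = np.ones(60)
        v[10] = 5.0  # 6 s: shorter than min_dur -> dropped
        v[20:23] = 5.0
        v[23] = 1.0  # 6 s gap < merge_gap? (equal -> kept separate)
        v[24:27] = 5.0
        ph = svdc.detect_active_phases(
            self._trace(v), baseline=1.0, min_dur_s=12.0, merge_gap_s=12.0
        )
        assert ph.active == [(120.0, 162.0)]

    def test_bad_baseline_rejected(self):
        with pytest.raises(ParameterError):
            svdc.detect_active_phases(self._trace(np.ones(5)), baseline=0.0)


class TestBaseline:
    def test_constant_signal_baseline(self):
        x = np.ones(12000)
        b = svdc.preceding_hour_baseline(
            x, fs=10.0, t_obs=1000.0, window_s=6.0, history_s=600.0
        )
        assert b == pytest.approx(60.0)

    def test_short_history_clips_with_warning(self):
        x = np.ones(18000)
        with pytest.warns(UserWarning, match="clip"):
            b = svdc.preceding_hour_baseline(x, fs=10.0, t_obs=1800.0)
        assert b == pytest.approx(60.0)

    def test_no_history_rejected(self):
        with pytest.raises(ParameterError):
            svdc.preceding_hour_baseline(np.ones(100), fs=10.0, t_obs=0.0)


class TestComparePhaseEnergy:
    def test_identical_samples_null(self, rng):
        x = rng.normal(10, 1, 200)
        res = svdc.compare_phase_energy(x, x)
        assert res.pvalue > 0.9
        assert abs(res.statistic) < 0.1

    def test_shifted_sample_detected_vs_permutation_oracle(self, rng):
        stable = rng.normal(10, 1, 50)
        active = stable + 25.0
        res = svdc.compare_phase_energy(stable, active)
        assert res.active_higher and res.pvalue < 1e-3
        # permutation oracle on the same samples
        pooled = np.concatenate([stable, active])
        obs = active.mean() - stable.mean()
        perm = np.empty(2000)
        for i in range(2000):
            rng.shuffle(pooled)
            perm[i] = pooled[50:].mean() - pooled[:50].mean()
        p_perm = (np.sum(np.abs(perm) >= abs(obs)) + 1) / 2001
        assert p_perm < 0.01

    def test_direction_flag_antisymmetric(self, rng):
        a = rng.normal(0, 1, 30)
        b = a + 5.0
        assert svdc.compare_phase_energy(a, b).active_higher
        assert not svdc.compare_phase_energy(b, a).active_higher

    def test_tiny_sample_gives_missing_p(self, rng):
        with pytest.warns(UserWarning):
            res = svdc.compare_phase_energy([1.0, 2.0], [3.0, 4.0, 5.0])
        assert np.isnan(res.pvalue)
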