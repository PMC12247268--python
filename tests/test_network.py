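"""Autocorrelation, cross-correlation, instantaneous phase, and PLV."""

import numpy as np
import pytest

import svdc
from svdc.errors import ParameterError
from svdc.network import stage_summaries

from conftest import make_tone


def naive_autocorrelation(x, lag):
    n = len(x)
    num = sum(x[i] * x[i + lag] for i in range(n - abs(lag)))
    den = sum(v * v for v in x)
    return num / den


def naive_cross_correlation(x, y):
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


class TestAutocorrelation:
    def test_zero_lag_is_one(self, rng):
        x = rng.normal(0, 1, 500)
        assert svdc.autocorrelation(x, 0.0, fs=100.0) == 1.0

    def test_half_period_antiphase(self):
        # the overlapping-support sum is normalized by the *full* signal
        # energy, so a half-period lag gives -(1 - lag/N) ~ -1 for small lags
        x = make_tone(2.0, 100.0, fs=100.0)
        rho = svdc.autocorrelation(x, 0.25, fs=100.0)  # half of a 0.5 s period
        assert rho == pytest.approx(-1.0, abs=0.02)

    def test_matches_naive_double_loop(self, rng):
        x = rng.normal(0, 1, 1000)
        for lag in (0, 1, 7, 100):
            got = svdc.autocorrelation(x, lag / 100.0, fs=100.0)
            assert got == pytest.approx(naive_autocorrelation(list(x), lag), abs=1e-10)

    def test_zero_energy_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(svdc.autocorrelation(np.zeros(100), 0.1, fs=100.0))


class TestCrossCorrelation:
    def test_self_is_one(self, rng):
        x = rng.normal(0, 1, 300)
        assert svdc.cross_correlation(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_negative_affine_is_minus_one(self, rng):
        x = rng.normal(0, 1, 300)
        assert svdc.cross_correlation(x, -3.0 * x + 7.0) == pytest.approx(
            -1.0, abs=1e-12
        )

    def test_matches_naive_formula(self, rng):
        x = rng.normal(0, 1, 1000)
        y = rng.normal(0, 1, 1000)
        assert svdc.cross_correlation(x, y) == pytest.approx(
            naive_cross_correlation(list(x), list(y)), abs=1e-10
        )

    def test_constant_input_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(svdc.cross_correlation(np.ones(10), np.arange(10.0)))


class TestStagedCrossCorrelation:
    def test_identical_signals_all_stages_one(self, rng):
        x = rng.normal(0, 1, 3000)
        ss = svdc.staged_cross_correlation(x, x, fs=100.0, seizure_span=(0, 30))
        assert all(v == pytest.approx(1.0, abs=1e-12) for v in ss.values)

    def test_independent_noise_near_zero(self, rng):
        # Monte-Carlo null: long independent stages stay near zero
        for _ in range(20):
            x = rng.normal(0, 1, 3000)
            y = rng.normal(0, 1, 3000)
            ss = svdc.staged_cross_correlation(x, y, 100.0, (0, 30))
            assert all(abs(v) < 0.2 for v in ss.values)

    def test_volume_mode_seizure_rises_to_near_one(self):
        cfg = svdc.SimConfig(seed=11)
        cfg.seizure.propagation = "volume"
        rec, truth = svdc.generate_ictal(cfg)
        band = svdc.extract_band(rec, 0.5, 300.0)
        span = (truth.seizure_onset_s, truth.seizure_onset_s + cfg.seizure.duration_s)
        ss = svdc.staged_cross_correlation(band[0], band[5], rec.fs, span)
        assert all(b >= a - 1e-6 for a, b in zip(ss.values, ss.values[1:]))
        assert ss.values[-1] >= 0.9


class TestInstantaneousPhase:
    def test_phase_slope_matches_frequency(self):
        fs, f = 1000.0, 7.0
        x = np.cos(2 * np.pi * f * np.arange(int(4 * fs)) / fs)
        ph = np.unwrap(svdc.instantaneous_phase(x))
        slope = np.polyfit(np.arange(ph.size) / fs, ph, 1)[0]
        assert slope == pytest.approx(2 * np.pi * f, rel=0.01)

    def test_quadrature_offset(self):
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        ps = svdc.instantaneous_phase(np.sin(2 * np.pi * 5 * t))
        pc = svdc.instantaneous_phase(np.cos(2 * np.pi * 5 * t))
        d = np.angle(np.exp(1j * (pc - ps)))
        interior = d[500:-500]
        assert np.abs(interior - np.pi / 2).max() < 0.05

    def test_negation_shifts_phase_by_pi(self, rng):
        x = make_tone(5.0, 4.0, fs=1000.0)
        d = np.angle(
            np.exp(1j * (svdc.instantaneous_phase(-x) - svdc.instantaneous_phase(x)))
        )
        assert np.abs(np.abs(d[500:-500]) - np.pi).max() < 0.05


class TestPlv:
    def test_identical_phases_give_exactly_one(self):
        ph = svdc.instantaneous_phase(make_tone(5.0, 2.0, fs=500.0))
        assert svdc.plv(ph, ph.copy()) == pytest.approx(1.0, abs=1e-15)

    def test_constant_offset_still_one(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 1000)
        assert svdc.plv(ph, ph + 1.234) == pytest.approx(1.0, abs=1e-12)

    def test_independent_phases_near_zero(self, rng):
        # E[PLV] ~ N^(-1/2) for independent phases
        p1 = rng.uniform(-np.pi, np.pi, 10000)
        p2 = rng.uniform(-np.pi, np.pi, 10000)
        assert svdc.plv(p1, p2) <= 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            svdc.plv(np.zeros(5), np.zeros(6))


class TestPlvMatrix:
    def test_duplicated_leads_all_ones(self):
        x = np.tile(make_tone(10.0, 4.0, fs=500.0), (3, 1))
        m = svdc.plv_matrix(x, ["A1", "A2", "A3"])
        np.testing.assert_allclose(m.values, 1.0, atol=1e-9)

    def test_symmetric_with_unit_diagonal(self, rng):
        x = rng.normal(0, 1, (4, 4000))
        m = svdc.plv_matrix(x, list("ABCD"))
        np.testing.assert_array_equal(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 1.0)

    def test_independent_noise_low_offdiag(self, rng):
        x = rng.normal(0, 1, (3, 60000))
        m = svdc.plv_matrix(x, ["A1", "A2", "A3"])
        off = m.values[~np.eye(3, dtype=bool)]
        assert off.max() <= 0.1


class TestStagedPlv:
    def test_identical_leads_all_stages_one(self):
        x = np.tile(make_tone(10.0, 30.0, fs=200.0), (3, 1))
        ss = svdc.staged_plv(x, ["A1", "A2", "A3"], fs=200.0, seizure_span=(0, 30))
        assert all(s == pytest.approx(1.0, abs=1e-9) for s in stage_summaries(ss))

    def test_interictal_noise_stays_low(self, rng):
        x = rng.normal(0, 1, (4, 30000))
        ss = svdc.staged_plv(x, list("ABCD"), fs=100.0, seizure_span=(0, 300))
        assert max(stage_summaries(ss)) <= 0.2

    def test_pathway_seizure_late_stage_more_synchronous(self):
        higher = 0
        for seed in range(5):
            cfg = svdc.SimConfig(seed=seed)
            rec, truth = svdc.generate_ictal(cfg)
            lf = svdc.extract_band(rec, 0.5, 40.0)
            span = (
                truth.seizure_onset_s,
                truth.seizure_onset_s + cfg.seizure.duration_s,
            )
            s = stage_summaries(
                svdc.staged_plv(lf, rec.labels, rec.fs, span, band="lf")
            )
            higher += s[-1] > s[0]
        assert higher >= 4
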