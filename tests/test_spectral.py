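"""Periodogram, period/amplitude, secondary peak, and Hilbert phase."""

import numpy as np
import pytest

from dropclock.spectral import (
    average_periodogram,
    extract_period_amplitude,
    hilbert_phase,
    periodogram,
    periodogram_set,
    secondary_peak,
)
from dropclock.tables import TrajectorySet


def tone(freq_per_h, n=480, dt=0.5, amp=1.0, phase=0.0):
    t = np.arange(n) * dt
    return amp * np.cos(2 * np.pi * freq_per_h * t + phase)


class TestPeriodogram:
    @pytest.mark.parametrize("l0", [5, 10, 33])
    def test_grid_tone_concentrates_all_power(self, l0):
        L, dt = 480, 0.5
        f0 = l0 / (L * dt)
        f, p = periodogram(tone(f0, n=L, dt=dt))
        assert p[l0 - 1] == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_normalizes_to_one(self):
        x = np.random.default_rng(0).normal(size=400)
        _, p = periodogram(x - x.mean())
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)

    def test_constant_series_bare_zero_normalized_error(self):
        _, p = periodogram(np.full(64, 3.0), normalized=False)
        assert np.allclose(p, 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            periodogram(np.full(64, 3.0))

    def test_nonfinite_rejected(self):
        x = np.ones(64)
        x[3] = np.nan
        with pytest.raises(ValueError):
            periodogram(x)

    def test_parseval(self):
        # sum of bare power over positive freqs (+ symmetric half + Nyquist
        # bookkeeping) equals L * variance for a mean-subtracted series
        rng = np.random.default_rng(2)
        for L in (400, 401):
            x = rng.normal(size=L)
            x -= x.mean()
            _, p = periodogram(x, normalized=False)
            total = 2 * p.sum()
            if L % 2 == 0:
                total -= p[-1]  # Nyquist bin is not doubled
            assert total == pytest.approx(L * np.sum(x**2), rel=1e-9)


class TestPeriodAmplitude:
    def test_peak_at_21h(self):
        f, p = periodogram(tone(1 / 21.0, n=420))  # 21 h on the 420-frame grid
        period, amp, tie = extract_period_amplitude(f, p)
        assert period == pytest.approx(21.0)
        assert amp == pytest.approx(1.0, abs=1e-6)
        assert not tie

    def test_tie_breaks_to_longer_period(self):
        f = np.array([0.01, 0.02, 0.03])
        p = np.array([0.4, 0.2, 0.4])
        period, _, tie = extract_period_amplitude(f, p)
        assert period == pytest.approx(100.0)
        assert tie

    def test_amplitude_is_sqrt_of_max_power(self):
        f = np.array([0.01, 0.02])
        p = np.array([0.36, 0.64])
        _, amp, _ = extract_period_amplitude(f, p)
        assert amp == pytest.approx(0.8)


class TestSecondaryPeak:
    def test_two_tone_2_to_1(self):
        L, dt = 480, 0.5
        x = 2 * tone(10 / (L * dt), n=L) + 1 * tone(33 / (L * dt), n=L)
        f, p = periodogram(x)
        sec = secondary_peak(f, p)
        assert sec is not None
        period, power = sec
        assert period == pytest.approx(1 / (33 / (L * dt)))
        # power ratio ~ amplitude ratio squared
        _, amp_max, _ = extract_period_amplitude(f, p)
        assert power / amp_max**2 == pytest.approx(0.25, abs=0.01)

    def test_single_tone_has_no_secondary(self):
        f, p = periodogram(tone(10 / 240.0, n=480))
        assert secondary_peak(f, p) is None

    def test_equal_twin_peaks_consistent_with_tie_rule(self):
        f = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        p = np.array([0.1, 0.35, 0.1, 0.35, 0.1])
        primary, _, tie = extract_period_amplitude(f, p)
        sec = secondary_peak(f, p)
        assert tie
        assert primary == pytest.approx(1 / 0.02)
        assert sec[0] == pytest.approx(1 / 0.04)


class TestHilbertPhase:
    def test_pure_tone_cycle_count(self):
        # 85 h window of a 21 h tone: 85/21 ~ 4.05 cycles
        t = np.arange(480) * 0.5
        x = np.sin(2 * np.pi * t / 21.0)
        cycles = hilbert_phase(x, t0_frame=60, t1_frame=230)
        assert cycles == pytest.approx(85.0 / 21.0, rel=0.02)

    def test_time_reversal_preserves_cycle_count(self):
        # the analytic-signal construction keeps only positive frequencies,
        # so a reversed real oscillation still accumulates positive phase;
        # reversal preserves the number of cycles in a stationary signal
        t = np.arange(480) * 0.5
        x = np.sin(2 * np.pi * t / 21.0) + 0.3 * np.sin(2 * np.pi * t / 10.0)
        fwd = hilbert_phase(x, 100, 300)
        rev = hilbert_phase(x[::-1], 100, 300)
        assert rev == pytest.approx(fwd, abs=0.1)
        # antisymmetry of the analytic argument itself: conjugation negates
        from scipy.signal import hilbert as _h
        phi = np.unwrap(np.angle(_h(x - x.mean())))
        phi_conj = np.unwrap(np.angle(np.conj(_h(x - x.mean()))))
        assert phi_conj[300] - phi_conj[100] == pytest.approx(-(phi[300] - phi[100]), abs=1e-9)

    def test_constant_series_zero_cycles(self):
        assert hilbert_phase(np.full(480, 2.0), 60, 230) == 0.0

    def test_window_outside_series_rejected(self):
        with pytest.raises(ValueError):
            hilbert_phase(np.sin(np.arange(100.0)), 60, 230)

    @pytest.mark.parametrize("period", [18.0, 21.0, 24.0])
    def test_phase_period_consistency(self, period):
        # for pure tones, cycles * period / window = 1 within 2%
        t = np.arange(480) * 0.5
        x = np.sin(2 * np.pi * t / period)
        cycles = hilbert_phase(x, 60, 230)
        window_h = (230 - 60) * 0.5
        assert cycles * period / window_h == pytest.approx(1.0, rel=0.02)


class TestAveragePeriodogram:
    def make_set(self, rows):
        rows = np.atleast_2d(rows)
        return periodogram_set(
            TrajectorySet(
                values=rows,
                cell_ids=[f"c{i}" for i in range(rows.shape[0])],
                droplet_ids=[f"d{i}" for i in range(rows.shape[0])],
            )
        )

    def test_identical_rows(self):
        t = np.arange(200) * 0.5
        x = np.sin(2 * np.pi * t / 20.0)
        ps = self.make_set(np.vstack([x, x, x]))
        avg = average_periodogram(ps)
        assert np.allclose(avg.mean, ps.power[0])
        assert np.allclose(avg.var, 0.0)
        assert avg.mean.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_rows_variance_is_half_squared_difference(self):
        t = np.arange(200) * 0.5
        a = np.sin(2 * np.pi * t / 20.0)
        b = np.sin(2 * np.pi * t / 25.0)
        ps = self.make_set(np.vstack([a, b]))
        avg = average_periodogram(ps)
        expected = 0.5 * (ps.power[0] - ps.power[1]) ** 2
        assert np.allclose(avg.var, expected)

    def test_single_cell_rejected(self):
        t = np.arange(200) * 0.5
        ps = self.make_set(np.sin(2 * np.pi * t / 20.0))
        with pytest.raises(ValueError):
            average_periodogram(ps)
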