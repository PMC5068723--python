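"""Cosinor fitting and the χ²-periodogram."""

import numpy as np
import pytest

import entrainkit as ek
from conftest import make_binned


def cosine_series(schedule, mesor=10.0, amplitude=3.0, acrophase=18.0,
                  hours=72.0, epoch_seconds=300.0, period=24.0, noise=None):
    dt = epoch_seconds / 3600.0
    t = np.arange(0.0, hours, dt)
    y = mesor + amplitude * np.cos(2 * np.pi * (t - acrophase) / period)
    if noise is not None:
        y = y + noise
    return make_binned(y, schedule, epoch_seconds)


def grid_search_cosinor(t, y, tau):
    """Independent brute-force oracle: scan acrophase densely, solve the
    conditional linear problem, refine around the best grid point."""
    def sse_and_params(phi):
        design = np.column_stack(
            [np.ones_like(t), np.cos(2 * np.pi * (t - phi) / tau)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return float(resid @ resid), float(coef[0]), float(coef[1])

    grid = np.arange(0.0, tau, 0.002)
    sses = [sse_and_params(p)[0] for p in grid]
    best = grid[int(np.argmin(sses))]
    lo, hi = best - 0.002, best + 0.002
    for _ in range(40):  # bisection-style refinement
        mids = np.linspace(lo, hi, 9)
        vals = [sse_and_params(m)[0] for m in mids]
        j = int(np.argmin(vals))
        lo, hi = mids[max(j - 1, 0)], mids[min(j + 1, 8)]
    phi = 0.5 * (lo + hi)
    _, mesor, amp = sse_and_params(phi)
    if amp < 0:
        amp, phi = -amp, (phi + tau / 2) % tau
    return mesor, amp, phi % 24.0


class TestCosinor:
    def test_noiseless_cosine_machine_precision(self, ld3):
        b = cosine_series(ld3)
        fit = ek.cosinor_fit(b, 24.0)
        assert fit.mesor == pytest.approx(10.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(3.0, abs=1e-9)
        assert fit.acrophase_zt_hours == pytest.approx(18.0, abs=1e-9)
        assert fit.percent_rhythm == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_amplitude_zero_acrophase_undefined(self, ld3):
        b = make_binned(np.full(864, 7.0), ld3)
        fit = ek.cosinor_fit(b, 24.0)
        assert fit.mesor == pytest.approx(7.0)
        assert fit.amplitude == 0.0
        assert not fit.acrophase_defined

    def test_matches_grid_search_oracle(self, ld3):
        rng = np.random.default_rng(11)
        noise = rng.normal(0.0, 1.0, 864)
        b = cosine_series(ld3, noise=noise)
        fit = ek.cosinor_fit(b, 24.0)
        m, a, phi = grid_search_cosinor(
            np.arange(864) / 12.0, b.counts.astype(float), 24.0)
        assert fit.mesor == pytest.approx(m, abs=1e-6)
        assert fit.amplitude == pytest.approx(a, abs=1e-6)
        assert fit.acrophase_zt_hours == pytest.approx(phi, abs=1e-6)

    def test_time_translation_shifts_acrophase_only(self, ld3):
        """Amplitude is translation-invariant; the acrophase shifts by
        exactly the translation (mod τ)."""
        y = 10 + 3 * np.cos(2 * np.pi * (np.arange(864) / 12.0 - 18.0) / 24.0)
        fit0 = ek.cosinor_fit((np.arange(864) / 12.0, y), 24.0)
        for shift in (1.0, 5.5, 23.0):
            fit = ek.cosinor_fit((np.arange(864) / 12.0 + shift, y), 24.0)
            assert fit.amplitude == pytest.approx(fit0.amplitude, abs=1e-9)
            expected = (fit0.acrophase_zt_hours + shift) % 24.0
            assert fit.acrophase_zt_hours == pytest.approx(expected, abs=1e-9)

    def test_residuals_orthogonal_to_regressors(self, ld3):
        rng = np.random.default_rng(5)
        b = cosine_series(ld3, noise=rng.normal(0, 2, 864))
        fit = ek.cosinor_fit(b, 24.0)
        t = np.arange(864) / 12.0
        omega = 2 * np.pi / 24.0
        resid = (b.counts.astype(float) - fit.mesor
                 - fit.amplitude * np.cos(
                     omega * (t - fit.acrophase_zt_hours)))
        for reg in (np.ones_like(t), np.cos(omega * t), np.sin(omega * t)):
            assert abs(resid @ reg) < 1e-8 * len(t)

    def test_too_few_points_rejected(self):
        with pytest.raises(ek.FitError):
            ek.cosinor_fit((np.array([0.0, 6.0, 12.0]),
                            np.array([1.0, 2.0, 1.0])), 24.0)

    def test_insufficient_phase_coverage_rejected(self):
        t = np.array([0.0, 24.0, 48.0, 72.0, 12.0])  # only 2 phases
        with pytest.raises(ek.FitError):
            ek.cosinor_fit((t, np.ones(5)), 24.0)

    def test_per_cycle_fits(self, ld3):
        b = cosine_series(ld3)
        fits = ek.cosinor_per_cycle(b, 24.0)
        assert len(fits) == 3
        for f in fits:
            assert f.acrophase_zt_hours == pytest.approx(18.0, abs=1e-6)


class TestPeriodogram:
    def test_square_wave_peak_exact(self, ld6):
        """Pure 24-h square wave over 6 days peaks at exactly 24.00 h."""
        zt = np.atleast_1d(ld6.zt_of(np.arange(1728) / 12.0))
        y = np.where(zt >= 12.0, 10.0, 0.0)
        pg = ek.chi_square_periodogram(make_binned(y, ld6))
        assert pg.peak_period_hours == 24.0

    def test_offgrid_cosine_finds_own_period(self):
        """A noiseless 23.5-h cosine over 7 days peaks at 23.50 h, and
        the whole curve matches a direct fold-variance oracle."""
        sched = ek.LightSchedule.standard_ld(7)
        t = np.arange(2016) / 12.0
        y = 10 + 4 * np.cos(2 * np.pi * t / 23.5)
        b = make_binned(y, sched)
        pg = ek.chi_square_periodogram(b)
        assert pg.peak_period_hours == 23.5

        # independent oracle: plain-python fold at a few trial periods
        for p_hours in (23.0, 23.5, 24.0):
            p = int(p_hours * 12)
            cols = [[] for _ in range(p)]
            for i, v in enumerate(y):
                cols[i % p].append(v)
            grand = sum(y) / len(y)
            num = sum(len(c) * (sum(c) / len(c) - grand) ** 2 for c in cols)
            den = sum((v - grand) ** 2 for v in y)
            qp = len(y) * num / den
            j = int(np.argmin(np.abs(pg.trial_periods_hours - p_hours)))
            assert pg.qp_values[j] == pytest.approx(qp, rel=1e-10)

    def test_scale_offset_invariance(self, ld6):
        zt = np.atleast_1d(ld6.zt_of(np.arange(1728) / 12.0))
        rng = np.random.default_rng(2)
        y = np.where(zt >= 12.0, 10.0, 2.0) + rng.normal(0, 0.5, 1728)
        qp1 = ek.chi_square_periodogram(make_binned(y, ld6)).qp_values
        qp2 = ek.chi_square_periodogram(make_binned(3 * y + 100, ld6)).qp_values
        np.testing.assert_allclose(qp1, qp2, rtol=1e-10)

    def test_grid_covers_20_to_25h_at_5min(self, ld6, control_streams_6d):
        b = ek.bin_events(control_streams_6d[0], 300, (0.0, 144.0), ld6)
        pg = ek.chi_square_periodogram(b)
        assert len(pg.trial_periods_hours) == 61
        assert pg.trial_periods_hours[0] == 20.0
        assert pg.trial_periods_hours[-1] == 25.0
        assert np.all(pg.df_per_period == pg.trial_periods_hours * 12 - 1)

    def test_whole_cycle_variant_agrees_on_strong_signal(self, ld6):
        zt = np.atleast_1d(ld6.zt_of(np.arange(1728) / 12.0))
        y = np.where(zt >= 12.0, 10.0, 0.0)
        pg = ek.chi_square_periodogram(make_binned(y, ld6), whole_cycles=True)
        assert pg.peak_period_hours == 24.0

    def test_short_series_rejected(self, ld3):
        b = make_binned(np.arange(400.0), ld3)
        with pytest.raises(ek.ParameterError):
            ek.chi_square_periodogram(b)

    def test_constant_series_rejected(self, ld6):
        b = make_binned(np.full(1728, 3.0), ld6)
        with pytest.raises(ek.DegenerateInputError):
            ek.chi_square_periodogram(b)
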