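"""Active-phase detection: smoothing, classification, gap merging."""

import numpy as np
import pytest

import entrainkit as ek
from conftest import make_binned


def box_series(schedule, hours=72.0, high=10.0, low=0.0, epoch_seconds=300.0):
    """Noiseless activity box aligned to the dark phase (ZT 12–24)."""
    dt = epoch_seconds / 3600.0
    t = np.arange(0.0, hours, dt)
    zt = np.atleast_1d(schedule.zt_of(t))
    return make_binned(np.where(zt >= 12.0, high, low), schedule,
                       epoch_seconds)


def mask_from(schedule, pattern):
    """Build a smoothed-series shell around a hand-written epoch pattern."""
    b = make_binned(np.asarray(pattern, dtype=float), schedule)
    return ek.SmoothedSeries(
        animal_id=b.animal_id, epoch_seconds=b.epoch_seconds,
        start_hours=b.start_hours, values=b.counts.astype(float),
        zt_hours=b.zt_hours, regime=b.regime, span_hours=4.0,
        sigma_hours=1.0)


class TestGaussianSmooth:
    def test_constant_series_unchanged(self, ld3):
        b = make_binned(np.full(864, 5.0), ld3)
        sm = ek.gaussian_smooth(b)
        np.testing.assert_allclose(sm.values, 5.0, atol=1e-12)

    def test_impulse_reproduces_kernel(self, ld3):
        x = np.zeros(864)
        x[432] = 1.0
        sm = ek.gaussian_smooth(make_binned(x, ld3))
        vals = sm.values
        assert np.argmax(vals) == 432
        np.testing.assert_allclose(vals[432 - 24: 432 + 25],
                                   vals[432 + 24: 432 - 25: -1], atol=1e-12)
        assert vals[432 - 25] == 0.0  # truncation at ±2 h (2σ)
        assert vals.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_convolution_oracle(self, ld3):
        """Hand-computed weighted average on a short series, including
        edge renormalization."""
        x = np.array([1.0, 4, 2, 8, 5, 7, 0, 3, 6, 2])
        b = make_binned(x, ld3, epoch_seconds=3600.0)  # 1-h epochs
        sm = ek.gaussian_smooth(b, span_hours=4.0)
        sigma = 1.0
        offsets = np.arange(-2, 3)
        w = np.exp(-0.5 * (offsets / sigma) ** 2)
        expected = []
        for i in range(10):
            num = den = 0.0
            for o, wt in zip(offsets, w):
                j = i + o
                if 0 <= j < 10:
                    num += wt * x[j]
                    den += wt
            expected.append(num / den)
        np.testing.assert_allclose(sm.values, expected, atol=1e-12)

    def test_restarts_at_regime_boundary(self, dd_protocol_schedule):
        sched = dd_protocol_schedule
        dt = 1 / 12
        n = int(24 / dt * 8)  # 6 LD days + 2 DD days
        x = np.zeros(n)
        x[int(6 * 24 / dt)] = 1.0  # impulse at the first DD epoch
        sm = ek.gaussian_smooth(make_binned(x, sched))
        # no leakage into the LD side of the boundary
        assert np.all(sm.values[: int(6 * 24 / dt)] == 0.0)

    def test_bad_span_rejected(self, ld3):
        b = make_binned(np.ones(864), ld3)
        with pytest.raises(ek.ParameterError):
            ek.gaussian_smooth(b, span_hours=0.1)


class TestClassification:
    def test_square_wave_mask_is_high_half(self, ld3):
        sm = ek.gaussian_smooth(box_series(ld3, low=1.0))
        mask, threshold = ek.classify_active_epochs(sm)
        zt = sm.zt_hours
        expected = zt >= 12.0
        # smoothing blurs the transitions by at most half the kernel span
        disagreement = np.mean(mask != expected)
        assert disagreement < 0.1
        assert mask[zt == 18.0].all() and not mask[zt == 6.0].any()

    def test_scale_equivariance(self, ld3):
        rng = np.random.default_rng(4)
        x = rng.poisson(5, 864).astype(float)
        m1, _ = ek.classify_active_epochs(
            ek.gaussian_smooth(make_binned(x, ld3)))
        m2, _ = ek.classify_active_epochs(
            ek.gaussian_smooth(make_binned(10 * x, ld3)))
        np.testing.assert_array_equal(m1, m2)

    def test_zero_variance_warns_all_inactive(self, ld3):
        sm = ek.gaussian_smooth(make_binned(np.full(864, 3.0), ld3))
        with pytest.warns(UserWarning):
            mask, threshold = ek.classify_active_epochs(sm)
        assert not mask.any()
        assert threshold == pytest.approx(3.0)


class TestGapMerging:
    def test_45min_gap_merges(self, ld3):
        pattern = np.zeros(864)
        pattern[144:168] = 1  # 2 h active
        pattern[177:201] = 1  # 45-min gap (9 epochs), then 2 h active
        sm = mask_from(ld3, pattern)
        phases = ek.detect_active_phases(pattern > 0, sm, ld3)
        assert len([p for p in phases if not p.secondary]) == 1

    def test_90min_gap_splits(self, ld3):
        pattern = np.zeros(864)
        pattern[144:168] = 1
        pattern[186:210] = 1  # 90-min gap (18 epochs)
        sm = mask_from(ld3, pattern)
        phases = ek.detect_active_phases(pattern > 0, sm, ld3)
        assert len(phases) == 2

    def test_exactly_one_hour_gap_merges(self, ld3):
        pattern = np.zeros(864)
        pattern[144:168] = 1
        pattern[180:204] = 1  # exactly 12 inactive epochs = 1 h
        sm = mask_from(ld3, pattern)
        phases = ek.detect_active_phases(pattern > 0, sm, ld3)
        assert len([p for p in phases if not p.secondary]) == 1

    def test_merge_monotone_in_gap_tolerance(self, ld3):
        rng = np.random.default_rng(9)
        pattern = (rng.uniform(size=864) < 0.4).astype(float)
        sm = mask_from(ld3, pattern)
        counts = [len(ek.detect_active_phases(pattern > 0, sm, ld3, g))
                  for g in (0.25, 0.5, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_all_inactive_returns_empty(self, ld3):
        sm = mask_from(ld3, np.zeros(864))
        assert ek.detect_active_phases(np.zeros(864, bool), sm, ld3) == []


class TestBoxSignal:
    def test_dark_box_duration_and_onset(self, ld3):
        """Noiseless 12-h dark-aligned box: the mean threshold crosses at
        the box edges, so duration ≈ 12 h and onset ≈ ZT 12."""
        sm = ek.gaussian_smooth(box_series(ld3))
        mask, _ = ek.classify_active_epochs(sm)
        phases = ek.detect_active_phases(mask, sm, ld3)
        summ = ek.active_phase_summary(phases)
        assert summ.n_cycles == 3
        assert 11.5 <= summ.mean_duration_hours <= 12.5
        assert summ.mean_onset_zt == pytest.approx(12.0, abs=0.5)
        assert summ.mean_offset_zt == pytest.approx(24.0, abs=0.5)

    def test_pipeline_scale_invariance(self, ld3):
        """Multiplying raw counts by a positive constant changes no mask,
        onset, offset or duration."""
        rng = np.random.default_rng(6)
        zt = np.atleast_1d(ld3.zt_of(np.arange(864) / 12.0))
        x = rng.poisson(np.where(zt >= 12, 20, 2)).astype(float)
        results = []
        for scale in (1.0, 7.3):
            sm = ek.gaussian_smooth(make_binned(scale * x, ld3))
            mask, _ = ek.classify_active_epochs(sm)
            phases = ek.detect_active_phases(mask, sm, ld3)
            results.append([(p.cycle_index, p.onset_zt_hours,
                             p.offset_zt_hours, p.duration_hours)
                            for p in phases])
        assert results[0] == results[1]


class TestSummary:
    def test_identical_phases_mean_equals_value(self):
        phases = [ek.ActivePhase("a", c, 11.5, 24.2, 12.7) for c in range(3)]
        s = ek.active_phase_summary(phases)
        assert s.mean_onset_zt == pytest.approx(11.5)
        assert s.mean_duration_hours == pytest.approx(12.7)
        assert s.n_cycles == 3

    def test_mean_of_varying_onsets(self):
        phases = [ek.ActivePhase("a", c, o, o + 12.0, 12.0)
                  for c, o in enumerate((11.5, 12.0, 12.5))]
        assert ek.active_phase_summary(phases).mean_onset_zt == \
            pytest.approx(12.0)

    def test_empty_summary(self):
        s = ek.active_phase_summary([])
        assert s.n_cycles == 0 and np.isnan(s.mean_duration_hours)

    def test_secondary_phases_excluded(self):
        phases = [ek.ActivePhase("a", 0, 12.0, 24.0, 12.0),
                  ek.ActivePhase("a", 0, 2.0, 3.0, 1.0, secondary=True)]
        s = ek.active_phase_summary(phases)
        assert s.n_cycles == 1
        assert s.mean_duration_hours == pytest.approx(12.0)

    def test_offset_unwrapped_beyond_24(self, ld3):
        """Activity running past lights-on yields offset > 24 unwrapped
        and duration stays linear."""
        dt = 1 / 12
        t = np.arange(0.0, 72.0, dt)
        zt = np.atleast_1d(ld3.zt_of(t))
        x = np.where((zt >= 12.0) | (zt < 1.0), 10.0, 0.0)  # 13-h bout
        sm = ek.gaussian_smooth(make_binned(x, ld3))
        mask, _ = ek.classify_active_epochs(sm)
        phases = [p for p in ek.detect_active_phases(mask, sm, ld3)
                  if not p.secondary]
        mid = phases[1]  # interior cycle, no edge effects
        assert mid.offset_zt_hours > 24.0
        assert mid.offset_zt_mod24 == pytest.approx(
            mid.offset_zt_hours - 24.0, abs=1e-9)
        assert mid.duration_hours == pytest.approx(
            mid.offset_zt_hours - mid.onset_zt_hours, abs=1e-9)
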