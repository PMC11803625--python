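"""CV feature extraction against analytic and generator oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protoneuro import (
    CVSpec, PeaksNotFound, ValidationError, Voltammogram,
    decay_rate, efficiency_enhancement, extract_features, find_redox_peaks,
    fit_charge_decay, gen_voltammogram, hysteresis_area, integrated_charge,
    peak_ratio, peak_separation, reversibility_index, segment_cycles,
    summarize, transfer_efficiency, zero_crossings,
)


def _triangle(n_cycles=3, m=100):
    e1 = np.concatenate([np.linspace(0, 1, m, endpoint=False),
                         np.linspace(1, 0, m, endpoint=False)])
    return np.tile(e1, n_cycles)


class TestSegmentCycles:
    def test_three_triangles_three_cycles(self):
        e = _triangle(3)
        vg = segment_cycles(Voltammogram(e, np.zeros_like(e)))
        assert vg.n_cycles == 3
        # each cycle contains both sweep directions
        for n in range(1, 4):
            cyc = vg.cycle_slice(n)
            de = np.diff(cyc.e)
            assert (de > 0).any() and (de < 0).any()

    def test_monotone_ramp_rejected(self):
        e = np.linspace(0, 1, 50)
        with pytest.raises(ValidationError):
            segment_cycles(Voltammogram(e, np.zeros_like(e)))

    def test_generator_cycles_recovered(self):
        vg = gen_voltammogram(CVSpec(n_cycles=100, noise_sd=0.0), seed=0)
        fresh = segment_cycles(Voltammogram(vg.e, vg.i, scan_rate=vg.scan_rate))
        assert fresh.n_cycles == 100


class TestPeaks:
    def test_gaussian_peaks_located(self, clean_cv):
        epa, ipa, epc, ipc = find_redox_peaks(clean_cv.cycle_slice(1))
        grid = 0.9 / 250  # potential grid resolution of the generator
        assert epa == pytest.approx(0.30, abs=2 * grid)
        assert epc == pytest.approx(0.134, abs=2 * grid)
        assert ipa > 0 > ipc

    def test_flat_current_peaks_not_found(self):
        e = _triangle(1)
        with pytest.raises(PeaksNotFound):
            find_redox_peaks(Voltammogram(e, np.zeros_like(e)), noise_floor=0.1)

    def test_offset_shifts_peak_current_exactly(self, clean_cv):
        cyc = clean_cv.cycle_slice(1)
        _, ipa, _, _ = find_redox_peaks(cyc)
        shifted = Voltammogram(cyc.e, cyc.i + 5.0, cyc.cycle, cyc.scan_rate)
        _, ipa2, _, _ = find_redox_peaks(shifted)
        assert ipa2 == pytest.approx(ipa + 5.0, abs=1e-12)


class TestScalarFeatures:
    def test_peak_separation_arithmetic(self):
        assert peak_separation(0.60, -0.358) == pytest.approx(0.958)
        assert peak_separation(0.30, 0.134) == pytest.approx(0.166)
        assert peak_separation(0.2, 0.2) == 0.0

    def test_peak_ratio_absolute_value(self):
        assert peak_ratio(2.58, -5.86) == pytest.approx(0.440, abs=5e-4)
        assert peak_ratio(1.0, 1.0) == 1.0
        assert peak_ratio(2.0, -4.0) == peak_ratio(2.0, 4.0)
        with pytest.raises(ValidationError):
            peak_ratio(1.0, 0.0)

    def test_reversibility_index_reproduces_reported_means(self):
        assert reversibility_index(1.04, -1.0, 0.947) == pytest.approx(1.10, abs=0.01)
        assert reversibility_index(0.44, -1.0, 0.958) == pytest.approx(0.46, abs=0.01)
        # linear in the current ratio
        assert reversibility_index(2.08, -1.0, 0.947) == pytest.approx(
            2 * reversibility_index(1.04, -1.0, 0.947))

    def test_transfer_efficiency_reported_and_quadratic(self):
        eps = transfer_efficiency(3.53, -17.6, 0.166)
        assert eps == pytest.approx(374.3, rel=1e-3)
        assert transfer_efficiency(0.0, -17.6, 0.166) == 0.0
        assert transfer_efficiency(7.06, -35.2, 0.166) == pytest.approx(4 * eps)

    def test_efficiency_enhancement_percent(self):
        assert efficiency_enhancement(16.23, 16.23) == 0.0
        assert efficiency_enhancement(16.23, 373.86) == pytest.approx(2203.5, abs=0.5)
        assert efficiency_enhancement(16.23, 2011.69) == pytest.approx(12295.0, abs=5.0)
        with pytest.raises(ValidationError):
            efficiency_enhancement(0.0, 10.0)


class TestCharge:
    def test_constant_current_rectangle(self):
        # |i| = 1 uA while sweeping 1 V at 0.1 V/s -> 10 s -> 10 uC
        e = np.linspace(0, 1, 1001)
        vg = Voltammogram(e, np.ones_like(e), np.ones(e.size, int), scan_rate=0.1)
        assert integrated_charge(vg) == pytest.approx(10.0, rel=1e-6)

    def test_zero_current_zero_charge(self):
        e = np.linspace(0, 1, 100)
        vg = Voltammogram(e, np.zeros_like(e), np.ones(100, int), scan_rate=0.1)
        assert integrated_charge(vg) == 0.0

    def test_gaussian_peak_matches_closed_form(self):
        # a Gaussian current peak swept slowly: integral = A * w * sqrt(2*pi) / nu
        e = np.linspace(-1, 1, 20_001)
        amp, width, nu = 2.0, 0.05, 0.1
        i = amp * np.exp(-0.5 * (e / width) ** 2)
        vg = Voltammogram(e, i, np.ones(e.size, int), scan_rate=nu)
        expected = amp * width * np.sqrt(2 * np.pi) / nu
        assert integrated_charge(vg) == pytest.approx(expected, rel=1e-2)


class TestChargeDecay:
    def test_noiseless_exact(self):
        n = np.arange(1, 101)
        q0, alpha, resid = fit_charge_decay(10 * np.exp(-0.02 * n))
        assert q0 == pytest.approx(10.0, rel=1e-9)
        assert alpha == pytest.approx(0.02, abs=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-20)

    def test_constant_series_zero_alpha(self):
        _, alpha, _ = fit_charge_decay(np.full(10, 5.0))
        assert alpha == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            fit_charge_decay([1.0, 2.0, -1.0, 3.0, 4.0])

    def test_noisy_recovery_across_seeds(self):
        n = np.arange(1, 101)
        clean = 10 * np.exp(-0.02 * n)
        errors = []
        for s in range(100):
            rng = np.random.default_rng(s)
            q = clean * (1 + rng.normal(0, 0.05, clean.size))
            if np.any(q <= 0):
                continue
            _, alpha, _ = fit_charge_decay(q)
            errors.append(abs(alpha / 0.02 - 1))
        assert np.median(errors) < 0.15


class TestDecayRate:
    def test_constant_series_all_zero(self):
        r = decay_rate([5.0, 5.0, 5.0])
        assert np.isnan(r[0])
        np.testing.assert_allclose(r[1:], 0.0)

    def test_halving_is_minus_fifty_percent(self):
        np.testing.assert_allclose(decay_rate([10.0, 5.0])[1], -50.0)

    def test_geometric_series_constant_rate(self):
        series = 8.0 * 0.9 ** np.arange(10)
        r = decay_rate(series)
        np.testing.assert_allclose(r[1:], -10.0, rtol=1e-9)


class TestZeroCrossings:
    def test_linear_root(self):
        m = 200
        e_f = np.linspace(0, 2, m, endpoint=False)
        e_r = np.linspace(2, 0, m, endpoint=False)
        i = np.concatenate([e_f - 1.2, -(e_r - 1.2)])
        vg = Voltammogram(np.concatenate([e_f, e_r]), i, np.ones(2 * m, int))
        ezc, izc = zero_crossings(vg)
        assert ezc == pytest.approx(1.2, abs=1e-9)

    def test_retraced_loop_izc_zero(self):
        m = 200
        e_f = np.linspace(0, 2, m, endpoint=False)
        e_r = np.linspace(2, 0, m, endpoint=False)
        i = np.concatenate([e_f - 1.0, e_r - 1.0])  # same current both ways
        vg = Voltammogram(np.concatenate([e_f, e_r]), i, np.ones(2 * m, int))
        ezc, izc = zero_crossings(vg)
        assert ezc == pytest.approx(1.0, abs=0.02)
        assert izc == pytest.approx(0.0, abs=1e-6)

    def test_no_sign_change_rejected(self):
        e = _triangle(1)
        with pytest.raises(ValidationError):
            zero_crossings(Voltammogram(e, np.ones_like(e), np.ones(e.size, int)))


class TestHysteresisArea:
    def test_retraced_line_zero(self):
        e = np.concatenate([np.linspace(0, 1, 50), np.linspace(1, 0, 50)])
        i = 2 * e
        assert hysteresis_area(Voltammogram(e, i, np.ones(100, int))) == pytest.approx(
            0.0, abs=1e-9)

    def test_rectangle(self):
        e = np.array([0, 1, 1, 0], float)
        i = np.array([0, 0, 2, 2], float)
        assert hysteresis_area(Voltammogram(e, i, np.ones(4, int))) == pytest.approx(2.0)

    def test_ellipse_analytic(self):
        th = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
        a, b = 0.5, 3.0
        vg = Voltammogram(a * np.cos(th), b * np.sin(th), np.ones(1000, int))
        assert hysteresis_area(vg) == pytest.approx(np.pi * a * b, rel=1e-3)


class TestSummaryAndInvariance:
    def test_two_cycle_summary(self):
        feats = extract_features(gen_voltammogram(
            CVSpec(alpha=0.0, n_cycles=2, noise_sd=0.0), seed=0))
        s = summarize(feats)
        assert s.n_cycles == 2
        assert s.sd["delta_ep"] == pytest.approx(0.0, abs=1e-12)

    def test_known_mean_sd(self):
        # direct check of the N-1 convention via delta_ep of two crafted cycles
        vals = np.array([0.1, 0.2])
        assert vals.mean() == pytest.approx(0.15)
        assert vals.std(ddof=1) == pytest.approx(0.0707, abs=5e-4)

    @settings(max_examples=20, deadline=None)
    @given(offset=st.floats(-2, 2))
    def test_delta_ep_invariant_under_potential_offset(self, offset):
        vg = gen_voltammogram(CVSpec(alpha=0.0, n_cycles=1, noise_sd=0.0), seed=0)
        cyc = vg.cycle_slice(1)
        epa, _, epc, _ = find_redox_peaks(cyc)
        shifted = Voltammogram(cyc.e + offset, cyc.i, cyc.cycle, cyc.scan_rate)
        epa2, _, epc2, _ = find_redox_peaks(shifted)
        assert peak_separation(epa2, epc2) == pytest.approx(
            peak_separation(epa, epc), abs=1e-9)

    @settings(max_examples=20, deadline=None)
    @given(offset=st.floats(-10, 10))
    def test_hysteresis_invariant_under_current_offset(self, offset):
        vg = gen_voltammogram(CVSpec(alpha=0.0, n_cycles=1, noise_sd=0.0), seed=0)
        cyc = vg.cycle_slice(1)
        shifted = Voltammogram(cyc.e, cyc.i + offset, cyc.cycle, cyc.scan_rate)
        assert hysteresis_area(shifted) == pytest.approx(hysteresis_area(cyc),
                                                         rel=1e-6, abs=1e-9)

    def test_pipeline_deterministic(self, clean_cv):
        a = extract_features(clean_cv)
        b = extract_features(clean_cv)
        assert [f.__dict__ for f in a] == [f.__dict__ for f in b]
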