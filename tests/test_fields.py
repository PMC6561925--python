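"""Spectral extraction, field gradients, RMS and directionality."""

import numpy as np
import pytest

from tacswave import fixtures as fx
from tacswave.conductor import simulate_phasor_field
from tacswave.fields import (
    compute_efield,
    directionality_fractions,
    extract_phase_amplitude,
    extract_spectra,
    phase_difference,
    rms_magnitude,
    summarize_condition,
)
from tacswave.phasor import same_sign_fraction


def _tone(f, fs, dur, phase_deg=0.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.cos(2 * np.pi * f * t + np.radians(phase_deg))


class TestExtractPhaseAmplitude:
    def test_pure_tone_exact_mode(self):
        x = _tone(10, 1000, 30, phase_deg=60.0, amp=5.0)
        amp, phase = extract_phase_amplitude(x, 1000, 10)
        assert amp == pytest.approx(5.0, abs=1e-6)
        assert phase == pytest.approx(60.0, abs=1e-6)

    def test_dc_has_no_10hz_component(self):
        amp, _ = extract_phase_amplitude(np.full(30_000, 3.0), 1000, 10)
        assert amp < 1e-9

    def test_interfering_tone_rejected_by_projection(self):
        x = _tone(10, 1000, 30, amp=1.0) + _tone(17, 1000, 30, amp=1.0)
        amp, _ = extract_phase_amplitude(x, 1000, 10)
        assert amp == pytest.approx(1.0, rel=5e-3)

    def test_fft_bin_mode_exact_when_tone_on_bin(self):
        # at 1024 Hz, 10 Hz falls exactly on padded-FFT bin 320 and the
        # 20 s record spans 200 whole cycles: the bin read-out is exact
        x = _tone(10, 1024, 20, phase_deg=20.0, amp=2.0)
        amp, phase = extract_phase_amplitude(x, 1024, 10, mode="fft_bin")
        assert amp == pytest.approx(2.0, rel=1e-9)
        assert phase == pytest.approx(20.0, abs=1e-6)

    def test_fft_bin_mode_leaks_when_tone_off_bin(self):
        # at 1000 Hz the nearest bin sits ~0.01 Hz off 10 Hz; rectangular-
        # window leakage biases the 30 s amplitude low by roughly 15%
        x = _tone(10, 1000, 30, phase_deg=20.0, amp=2.0)
        amp, _ = extract_phase_amplitude(x, 1000, 10, mode="fft_bin")
        assert amp == pytest.approx(2.0, rel=0.2)
        assert amp < 2.0  # the leakage bias the exact mode avoids

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            extract_phase_amplitude(np.zeros(1000), 100, 60)

    def test_floor_marks_undefined_phases(self):
        mat = np.vstack([_tone(10, 1000, 5), np.zeros(5000)])
        est = extract_spectra(mat, 1000, 10)
        assert est.defined[0] and not est.defined[1]
        assert np.isnan(est.phase_deg[1])


class TestComputeEfield:
    def test_linear_profile(self):
        x = np.arange(0, 30, 5.0)
        v = (10.0 - x)[:, None] * np.ones((1, 4))
        np.testing.assert_allclose(compute_efield(v, 5.0), np.ones((6, 4)))

    def test_quadratic_profile_exact_at_interior(self):
        x = np.arange(0, 30, 5.0)
        v = (x**2)[:, None] * np.ones((1, 3))
        e = compute_efield(v, 5.0)
        np.testing.assert_allclose(e[1:-1], (-2 * x[1:-1])[:, None] * np.ones((1, 3)))

    def test_two_contacts_single_estimate(self):
        v = np.array([[1.0], [0.0]])
        e = compute_efield(v, 5.0)
        np.testing.assert_allclose(e, np.full((2, 1), 0.2))

    def test_single_contact_rejected(self):
        with pytest.raises(ValueError):
            compute_efield(np.ones((1, 10)), 5.0)


class TestRms:
    def test_sinusoid_rms(self):
        x = _tone(10, 1000, 2, amp=3.0)
        assert rms_magnitude(x, 1000, 10) == pytest.approx(3.0 / np.sqrt(2), rel=1e-9)

    def test_unit_amplitude(self):
        assert rms_magnitude(_tone(10, 1000, 1), 1000, 10) == pytest.approx(0.7071, abs=1e-4)

    def test_noise_variance_adds(self, rng):
        x = _tone(10, 1000, 100, amp=1.0) + rng.normal(0, 0.1, 100_000)
        assert rms_magnitude(x, 1000, 10) ** 2 == pytest.approx(0.5 + 0.01, rel=0.02)

    def test_partial_cycle_dropped(self):
        x = np.concatenate([_tone(10, 1000, 1), np.full(30, 100.0)])
        assert rms_magnitude(x, 1000, 10) == pytest.approx(np.sqrt(0.5), rel=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            rms_magnitude(np.zeros(50), 1000, 10)


class TestPhaseDifference:
    @pytest.mark.parametrize(
        "a, p, expected", [(170, -170, -20), (45, 45, 0), (0, 180, 180)]
    )
    def test_wrapping(self, a, p, expected):
        assert phase_difference(a, p) == pytest.approx(expected)

    def test_nan_propagates(self):
        assert np.isnan(phase_difference(float("nan"), 10.0))


class TestDirectionality:
    def _field_matrix(self, setup, theta):
        montage, geometry, medium = setup
        pf = simulate_phasor_field(montage, geometry, medium, theta)
        t_ms = fx.midpoint_cycle_times_ms(10.0, 1000.0)
        return pf.e_timecourse(t_ms)

    def test_180_condition_fully_unidirectional(self, symmetric_setup):
        fr = directionality_fractions(self._field_matrix(symmetric_setup, 180.0), 1000, 10)
        assert fr.as_tuple() == pytest.approx((1.0, 0.0, 0.0))

    def test_0_condition_alternates_inward_outward(self, symmetric_setup):
        fr = directionality_fractions(self._field_matrix(symmetric_setup, 0.0), 1000, 10)
        assert fr.unidirectional == pytest.approx(0.0)
        assert fr.inward == pytest.approx(0.5, abs=0.01)
        assert fr.outward == pytest.approx(0.5, abs=0.01)

    def test_end_driven_90_condition_50_25_25(self):
        e = fx.end_driven_e_matrix(90.0)
        fr = directionality_fractions(e, 1000, 10)
        assert fr.unidirectional == pytest.approx(0.50, abs=0.01)
        assert fr.inward == pytest.approx(0.25, abs=0.01)
        assert fr.outward == pytest.approx(0.25, abs=0.01)

    def test_fractions_sum_to_one(self, symmetric_setup):
        for theta in (30.0, 90.0, 150.0):
            fr = directionality_fractions(self._field_matrix(symmetric_setup, theta), 1000, 10)
            assert sum(fr.as_tuple()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_same_sign_fraction_on_two_contact_tracks(self):
        """Analytic cross-check: two sinusoids offset by delta share a sign
        for 1 - delta/180 of each cycle."""
        t_ms = fx.midpoint_cycle_times_ms(10.0, 2000.0, n_cycles=2)
        w = 2 * np.pi * 10.0 * t_ms / 1000.0
        for dphi in (36.0, 90.0, 126.0):
            e = np.vstack([np.cos(w), np.cos(w + np.radians(dphi))])
            fr = directionality_fractions(e, 2000, 10)
            assert fr.unidirectional == pytest.approx(same_sign_fraction(dphi), abs=0.01)


class TestSummarizeCondition:
    def _summary(self, setup, theta):
        montage, geometry, medium = setup
        pf = simulate_phasor_field(montage, geometry, medium, theta)
        t_ms = fx.midpoint_cycle_times_ms(10.0, 1000.0, n_cycles=2)
        v = pf.v_timecourse(t_ms)
        e = pf.e_timecourse(t_ms)
        sv = extract_spectra(v, 1000, 10)
        se = extract_spectra(e, 1000, 10)
        return summarize_condition(sv, se, e, setup[1], theta, 1000, 10)

    def test_voltage_range_smaller_in_phase_than_anti_phase(self, symmetric_setup):
        assert (
            self._summary(symmetric_setup, 0.0).voltage_range_mv
            < self._summary(symmetric_setup, 180.0).voltage_range_mv
        )

    def test_field_phase_difference_zero_at_180(self, symmetric_setup):
        assert abs(self._summary(symmetric_setup, 180.0).dphi_e_deg) < 1.0

    def test_field_phase_difference_180_at_0(self, symmetric_setup):
        assert abs(self._summary(symmetric_setup, 0.0).dphi_e_deg) == pytest.approx(180.0, abs=1.0)

    def test_ratio_is_first_over_last_contact(self, symmetric_setup):
        s = self._summary(symmetric_setup, 90.0)
        np.testing.assert_allclose(
            s.superficial_deep_ratio, s.rms_e[0] / s.rms_e[-1], rtol=1e-12
        )
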