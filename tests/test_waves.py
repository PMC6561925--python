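"""Traveling-wave metrics: dissimilarity, spatial variability, phase-gradient
regression and propagation speed."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tacswave import fixtures as fx
from tacswave.conductor import simulate_phasor_field
from tacswave.waves import (
    detect_wave,
    dissimilarity_index,
    fit_phase_gradient,
    fit_wave,
    normalize_timecourses,
    spatial_variability_index,
    unwrap_track_phases,
    wave_speed,
)


def _cycle(f=10.0, fs=1000.0, n_cycles=1):
    return fx.midpoint_cycle_times_ms(f, fs, n_cycles)


def _symmetric_field(setup, theta, t_ms):
    montage, geometry, medium = setup
    return simulate_phasor_field(montage, geometry, medium, theta).e_timecourse(t_ms)


class TestNormalize:
    def test_peak_is_one(self):
        t = _cycle()
        e = 2.0 * np.cos(2 * np.pi * 10 * t / 1000)[None, :]
        norm, valid = normalize_timecourses(e)
        assert valid[0]
        assert np.max(norm) == pytest.approx(1.0)

    def test_amplitude_scaling_invisible_after_normalization(self):
        t = _cycle()
        base = np.cos(2 * np.pi * 10 * t / 1000)
        e = np.vstack([base, 7.3 * base])
        norm, _ = normalize_timecourses(e)
        np.testing.assert_allclose(norm[0], norm[1], atol=1e-12)

    def test_all_zero_contact_flagged(self):
        e = np.vstack([np.ones(10), np.zeros(10)])
        norm, valid = normalize_timecourses(e)
        assert valid[0] and not valid[1]
        assert np.isnan(norm[1]).all()


class TestDissimilarity:
    def test_zero_for_stationary_conditions(self, symmetric_setup):
        t = _cycle()
        for theta in (0.0, 180.0):
            norm, _ = normalize_timecourses(_symmetric_field(symmetric_setup, theta, t))
            assert dissimilarity_index(norm).index == pytest.approx(0.0, abs=1e-12)

    def test_quadrature_pair_matches_numeric_integration(self):
        """|cos| traces offset by 90 degrees: MSD by direct quadrature."""
        u = (np.arange(200_000) + 0.5) / 200_000 * 2 * np.pi
        a, b = np.abs(np.cos(u)), np.abs(np.cos(u + np.pi / 2))
        expected = np.mean((a - b) ** 2)  # = 1 - 2/pi for unit |cos| traces
        t = _cycle(fs=100_000.0)
        w = 2 * np.pi * 10 * t / 1000
        e = np.vstack([np.cos(w), np.cos(w + np.pi / 2)])
        norm, _ = normalize_timecourses(e)
        assert dissimilarity_index(norm).index == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(1 - 2 / np.pi, abs=1e-4)

    def test_duplicated_identical_traces_stay_zero(self):
        t = _cycle()
        base = np.abs(np.cos(2 * np.pi * 10 * t / 1000))
        for n in (2, 5, 9):
            norm = np.tile(base, (n, 1))
            assert dissimilarity_index(norm).index == 0.0

    @given(st.floats(0.1, 10), st.integers(0, 80))
    def test_invariant_to_scaling_and_common_time_shift(self, scale, shift):
        t = _cycle()
        w = 2 * np.pi * 10 * t / 1000
        e = np.vstack([np.cos(w), np.cos(w + 0.7)])
        rolled = np.roll(e, shift, axis=1)
        n1, _ = normalize_timecourses(e)
        n2, _ = normalize_timecourses(np.vstack([rolled[0] * scale, rolled[1]]))
        d1 = dissimilarity_index(n1).index
        d2 = dissimilarity_index(n2).index
        assert d1 == pytest.approx(d2, rel=1e-9, abs=1e-12)

    def test_needs_two_valid_contacts(self):
        with pytest.raises(ValueError):
            dissimilarity_index(np.ones((1, 10)))


class TestSpatialVariability:
    def test_zero_for_stationary_conditions(self, symmetric_setup):
        t_ms = np.arange(36) / 360 * 1000.0
        for theta in (0.0, 180.0):
            mag = np.abs(_symmetric_field(symmetric_setup, theta, t_ms))
            _, max_sd, _ = spatial_variability_index(mag)
            assert max_sd <= 1e-9

    def test_traveling_condition_exceeds_floor(self, symmetric_setup):
        t_ms = np.arange(36) / 360 * 1000.0
        mag = np.abs(_symmetric_field(symmetric_setup, 45.0, t_ms))
        _, max_sd, _ = spatial_variability_index(mag)
        assert max_sd > 0.05

    def test_zero_crossing_steps_are_skipped(self, symmetric_setup):
        t_ms = np.arange(36) / 360 * 1000.0
        mag = np.abs(_symmetric_field(symmetric_setup, 180.0, t_ms))
        _, _, n_skipped = spatial_variability_index(mag)
        assert n_skipped == 2  # the two carrier zero crossings per cycle

    def test_replicated_single_location_all_zero(self):
        mag = np.tile(np.abs(np.cos(np.linspace(0, 2 * np.pi, 40))), (6, 1))
        sd_map, max_sd, _ = spatial_variability_index(mag)
        assert max_sd == 0.0
        np.testing.assert_array_equal(sd_map, 0.0)


class TestPhaseGradient:
    def test_exact_line(self):
        x = np.arange(0, 55, 5.0)
        r, b, r2 = fit_phase_gradient(1.5 * x + 10.0, x)
        assert (r, b, r2) == pytest.approx((1.5, 10.0, 1.0))

    def test_constant_phase(self):
        x = np.arange(0, 30, 5.0)
        r, _, _ = fit_phase_gradient(np.full_like(x, 42.0), x)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_wrapped_phases_recovered_after_unwrap(self):
        from tacswave.phasor import wrap_phase_deg

        x = np.arange(0, 55, 5.0)
        true = 2.0 * x + 5.0
        wrapped = wrap_phase_deg(true)
        r, _, r2 = fit_phase_gradient(wrapped, x)
        assert r == pytest.approx(2.0, rel=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_180_degree_direction_flips_removed(self):
        x = np.arange(0, 30, 5.0)
        true = 1.2 * x
        flipped = true + 180.0 * np.array([0, 1, 0, 1, 1, 0])
        r, _, _ = fit_phase_gradient(unwrap_track_phases(flipped), x)
        assert r == pytest.approx(1.2, rel=1e-9)

    def test_too_few_defined_phases(self):
        with pytest.raises(ValueError):
            fit_phase_gradient([0.0, np.nan, np.nan, 10.0], [0, 5, 10, 15])


class TestWaveSpeed:
    @pytest.mark.parametrize("r_true, c_expected", [(1.8, 2.0), (3.6, 1.0)])
    def test_matches_maximum_tracking_oracle(self, r_true, c_expected):
        """Brute force: follow the normalized-field maximum across space."""
        assert wave_speed(r_true, 10.0) == pytest.approx(c_expected, rel=1e-12)
        dt = 0.02  # ms
        xf = np.linspace(0, 55, 1101)
        tf = np.arange(0, 40.0, dt)
        ef = np.cos(2 * np.pi * 10 * tf[None, :] / 1000 + np.radians(r_true * xf[:, None]))
        loc = xf[np.argmax(np.abs(ef), axis=0)]
        # regress location on time over the longest run where the maximum is
        # a genuine interior peak (not stuck at a domain boundary) and moves
        # without wrap-around jumps
        interior = (loc > 0.5) & (loc < 54.5)
        new_seg = np.zeros(loc.size, dtype=bool)
        new_seg[1:] = (np.abs(np.diff(loc)) > 1.0) | (interior[1:] != interior[:-1])
        segment_id = np.cumsum(new_seg)
        runs = [np.flatnonzero(segment_id == s) for s in np.unique(segment_id[interior])]
        best = max((r for r in runs if interior[r[0]]), key=len)
        slope = np.polyfit(tf[best], loc[best], 1)[0]
        assert abs(slope) == pytest.approx(c_expected, rel=0.02)

    def test_zero_gradient_flagged(self):
        with pytest.raises(ValueError, match="stationary"):
            wave_speed(0.0, 10.0)
        fit = fit_wave([0.0, 0.0, 0.0, 0.0], [0, 5, 10, 15], 10.0)
        assert np.isnan(fit.c_mm_per_ms) and fit.direction == 0


class TestDetection:
    @pytest.mark.parametrize("r, expected", [(1.42, True), (0.5, False), (1.0, True), (-1.2, True)])
    def test_threshold_inclusive(self, r, expected):
        assert detect_wave(r) is expected

    def test_symmetric_fixture_no_wave_near_180(self, symmetric_setup):
        """The spatial frequency stays below detection within 180 +- 60 deg."""
        montage, geometry, medium = symmetric_setup
        x = np.arange(12) * 5.0
        for theta in np.arange(120.0, 241.0, 15.0):
            pf = simulate_phasor_field(montage, geometry, medium, theta)
            fit = fit_wave(pf.e_phase_deg, x, 10.0)
            assert not fit.detected
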