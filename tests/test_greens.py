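import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuralwave import (
    NonOscillatoryError,
    Stimulus1D,
    WaveParams,
    decay_null_xmin,
    greens_function,
    interference_map,
    linear_response,
    wave_params,
    zone2_spectrum,
)
from conftest import scaled_params


class TestWaveParams:
    def test_reference_config_is_weakly_damped(self, wave_low):
        assert wave_low.lam / wave_low.k_n <= 0.05

    def test_decoupled_populations_have_no_wave(self, ref_low):
        c = ref_low.replace(W_EI=0.0, W_IE=0.0, D_EI=0.0, D_IE=0.0)
        with pytest.raises(NonOscillatoryError):
            wave_params(c)

    def test_spread_scaling_rescales_roots(self, ref_mod, wave_mod):
        # D -> beta D maps the characteristic roots u -> u / beta, so both
        # k_n and lam scale by 1 / sqrt(beta)
        beta = 4.0
        w2 = wave_params(scaled_params(ref_mod, beta))
        assert w2.k_n == pytest.approx(wave_mod.k_n / math.sqrt(beta), rel=1e-10)
        assert w2.lam == pytest.approx(wave_mod.lam / math.sqrt(beta), rel=1e-10)

    def test_greens_integral_equals_static_uniform_gain(self, ref_low, wave_low):
        # Fourier zero mode: integral of G equals the response to uniform input
        x = np.linspace(-400, 400, 160001)
        GE, GI = greens_function(wave_low, x)
        M = np.array([[ref_low.W_EE - 1, -ref_low.W_EI],
                      [ref_low.W_IE, -(ref_low.W_II + 1)]])
        gain = np.linalg.solve(M, [-ref_low.alpha, -(1 - ref_low.alpha)])
        assert np.trapezoid(GE, x) == pytest.approx(gain[0], rel=2e-3)
        assert np.trapezoid(GI, x) == pytest.approx(gain[1], rel=2e-3)


class TestGreensFunction:
    def test_value_at_origin_is_gamma(self, wave_low):
        GE, GI = greens_function(wave_low, 0.0)
        assert GE == pytest.approx(wave_low.Gamma_E)
        assert GI == pytest.approx(wave_low.Gamma_I)

    def test_even_symmetry(self, wave_low):
        x = np.linspace(0.1, 30, 500)
        GE_p, _ = greens_function(wave_low, x)
        GE_m, _ = greens_function(wave_low, -x)
        np.testing.assert_allclose(GE_p, GE_m, rtol=1e-12)

    def test_zero_spacing_approaches_half_period_at_low_damping(self, wave_low):
        x = np.linspace(5.0, 60.0, 40001)
        GE, _ = greens_function(wave_low, x)
        sgn = np.sign(GE)
        idx = np.nonzero(np.diff(sgn))[0]
        spacing = np.diff(0.5 * (x[idx] + x[idx + 1]))
        assert np.allclose(spacing, math.pi / wave_low.k_n, rtol=0.02)


class TestLinearResponse:
    def test_single_point_recovers_greens(self, wave_low):
        grid = np.linspace(-30, 30, 1201)
        r = linear_response(Stimulus1D(kind="point", j0=1.0), wave_low, grid)
        GE, GI = greens_function(wave_low, grid)
        np.testing.assert_allclose(r.r_E, GE, rtol=1e-10)
        np.testing.assert_allclose(r.r_I, GI, rtol=1e-10)

    def test_coincident_pair_doubles_single_response(self, wave_low):
        grid = np.linspace(-30, 30, 1201)
        pair = Stimulus1D(kind="point_pair", j0=1.0, positions=(0.0, 0.0))
        single = linear_response(Stimulus1D(kind="point", j0=1.0), wave_low, grid)
        double = linear_response(pair, wave_low, grid)
        np.testing.assert_allclose(double.r_E, 2 * single.r_E, rtol=1e-12)

    def test_coarse_grid_rejected(self, wave_low):
        grid = np.arange(-30, 30, wave_low.period / 4)
        with pytest.raises(ValueError, match="8 samples"):
            linear_response(Stimulus1D(kind="point"), wave_low, grid)

    def test_zone1_interior_oscillates_at_stimulus_frequency(self, wave_low):
        T = wave_low.period
        grid = np.arange(-40 * T, 10 * T, T / 32)
        k_stim = 0.5 * wave_low.k_n
        r = linear_response(
            Stimulus1D(kind="bounded_grating", j0=1.0, k=k_stim, region=(grid[0], 0.0)),
            wave_low, grid,
        )
        sel = (grid > -35 * T) & (grid < -8 * T)
        seg = r.r_E[sel] - r.r_E[sel].mean()
        freqs = 2 * math.pi * np.fft.rfftfreq(seg.size, d=T / 32)
        spec = np.abs(np.fft.rfft(seg * np.hanning(seg.size)))
        assert freqs[np.argmax(spec)] == pytest.approx(k_stim, abs=freqs[1] - freqs[0])


@pytest.fixture(scope="module")
def imap(wave_low):
    T = wave_low.period
    grid = np.arange(-10 * T, 10 * T, T / 64)
    d = np.arange(0.0, 2.0001, 0.01) * T
    return interference_map(wave_low, d, grid), T


class TestInterference:

    def test_zero_separation_row_is_twice_point_response(self, imap, wave_low):
        m, T = imap
        GE, _ = greens_function(wave_low, m.grid)
        np.testing.assert_allclose(m.field[0], 2 * GE, rtol=1e-10)

    def test_first_energy_minimum_at_half_period(self, imap):
        m, T = imap
        e = m.energy
        i = 1
        while not (e[i] < e[i - 1] and e[i] <= e[i + 1]):
            i += 1
        assert m.distances[i] / T == pytest.approx(0.5, abs=0.05)

    def test_energy_maximum_near_one_period(self, imap):
        m, T = imap
        sel = (m.distances / T > 0.5) & (m.distances / T <= 1.5)
        d_peak = m.distances[sel][np.argmax(m.energy[sel])]
        assert d_peak / T == pytest.approx(1.0, abs=0.05)

    def test_row_period_independent_of_separation(self, imap, wave_low):
        m, T = imap
        for i in range(0, m.distances.size, 25):
            assert m.row_period(i) == pytest.approx(T, rel=0.03)

    def test_negative_separation_rejected(self, wave_low):
        with pytest.raises(ValueError):
            interference_map(wave_low, [-1.0], np.linspace(-10, 10, 512))


class TestZone2:
    @pytest.mark.parametrize("mult", [0.5, 1.0, 2.0])
    def test_lateral_frequency_is_intrinsic_regardless_of_stimulus(self, wave_low, mult):
        T = wave_low.period
        grid = np.arange(-40 * T, 12 * T, T / 64)
        r = linear_response(
            Stimulus1D(kind="bounded_grating", j0=1.0, k=mult * wave_low.k_n,
                       region=(grid[0], 0.0)),
            wave_low, grid,
        )
        spec = zone2_spectrum(r, (grid[0], 0.0), k_hint=wave_low.k_n)
        assert spec["oscillatory"]
        assert abs(spec["k_spectral"] - wave_low.k_n) <= spec["uncertainty"]
        assert spec["k_zero_crossing"] == pytest.approx(wave_low.k_n, rel=0.02)

    def test_lateral_envelope_decays(self, wave_low):
        T = wave_low.period
        grid = np.arange(-40 * T, 12 * T, T / 64)
        r = linear_response(
            Stimulus1D(kind="bounded_grating", j0=1.0, k=wave_low.k_n,
                       region=(grid[0], 0.0)),
            wave_low, grid,
        )
        lat = grid > 0
        env_near = np.abs(r.r_E[lat & (grid < 4 * T)]).max()
        env_far = np.abs(r.r_E[lat & (grid > 8 * T)]).max()
        assert env_far < env_near

    def test_pure_decay_profile_flagged_non_wave(self):
        from neuralwave.fields import ResponseField
        x = np.linspace(-10, 40, 2048)
        prof = np.exp(-0.2 * np.clip(x, 0, None)) * (x > -1)
        r = ResponseField(grid=x, r_E=prof, r_I=prof)
        spec = zone2_spectrum(r, (-10, 0.0))
        assert not spec["oscillatory"]

    def test_short_lateral_segment_rejected(self, wave_low):
        from neuralwave.fields import ResponseField
        x = np.linspace(-10, 2, 256)
        r = ResponseField(grid=x, r_E=np.cos(x), r_I=np.cos(x))
        with pytest.raises(ValueError):
            zone2_spectrum(r, (-10, 0.0), k_hint=wave_low.k_n)


class TestDecayNull:
    def test_symmetric_case_minimum_at_origin(self):
        assert decay_null_xmin(2.0, 2.0, 0.7, 1.5, 1.5) == pytest.approx(0.0)

    def test_printed_formula_direct_evaluation(self):
        lam = 1.0
        assert decay_null_xmin(math.e ** (2 * lam), 1.0, lam, 0.0, 0.0) == pytest.approx(1.0)

    @given(
        A=st.floats(0.1, 10), B=st.floats(0.1, 10),
        lam=st.floats(0.2, 2.0), x0=st.floats(0.0, 3.0), x1=st.floats(0.0, 3.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_matches_grid_search_minimum(self, A, B, lam, x0, x1):
        xm = decay_null_xmin(A, B, lam, x0, x1)
        xs = np.linspace(xm - 20, xm + 20, 400001)
        prof = A * np.exp(-lam * (xs + x0)) + B * np.exp(-lam * (x1 - xs))
        assert xs[np.argmin(prof)] == pytest.approx(xm, abs=1e-3)

    def test_two_sided_decay_has_single_derivative_sign_change(self):
        A, B, lam, x0, x1 = 1.3, 0.4, 0.8, 0.5, 2.0
        xs = np.linspace(-30, 30, 200001)
        prof = A * np.exp(-lam * (xs + x0)) + B * np.exp(-lam * (x1 - xs))
        signs = np.sign(np.diff(prof))
        changes = np.count_nonzero(np.diff(signs[signs != 0]))
        assert changes == 1

    def test_invalid_inputs_rejected(self):
        for bad in [(-1, 1, 1), (1, 0, 1), (1, 1, -0.5)]:
            with pytest.raises(ValueError):
                decay_null_xmin(bad[0], bad[1], bad[2], 0.0, 1.0)
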