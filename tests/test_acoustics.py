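"""Monopole field theory, waveform conversions and binaural cues."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualhear import acoustics as ac

SPEC = ac.MonopoleSpec(amplitude=224.0, reference_distance=0.03)
RHO, C = 1000.0, 1500.0


class TestMonopoleFields:
    def test_pressure_magnitude_at_reference(self):
        p = ac.monopole_pressure(SPEC, 0.03, 780.0, 0.0)
        assert np.abs(p) == pytest.approx(224.0)

    def test_pressure_inverse_distance_law(self):
        p1 = np.abs(ac.monopole_pressure(SPEC, 0.05, 500.0))
        p2 = np.abs(ac.monopole_pressure(SPEC, 0.10, 500.0))
        assert p2 == pytest.approx(p1 / 2)

    def test_pressure_phase_periodicity(self):
        f = 1000.0
        lam = C / f
        p1 = ac.monopole_pressure(SPEC, 0.04, f)
        p2 = ac.monopole_pressure(SPEC, 0.04 + lam, f)
        dphi = np.angle(p2 / p1)
        assert dphi == pytest.approx(0.0, abs=1e-9)
        # magnitudes still follow 1/r
        assert np.abs(p2) == pytest.approx(np.abs(p1) * 0.04 / (0.04 + lam))

    def test_velocity_far_field_plane_wave_limit(self):
        # kr >> 1: |v| -> |p| / (rho c)
        r, f = 10.0, 5000.0
        v = ac.monopole_velocity(SPEC, r, f)
        p = ac.monopole_pressure(SPEC, r, f)
        assert np.abs(v) * RHO * C / np.abs(p) == pytest.approx(1.0, rel=1e-4)

    def test_velocity_near_field_slope(self):
        # kr << 1: log|v| vs log r has slope -2
        f = 20.0
        rs = np.array([0.001, 0.002])
        vs = np.abs(ac.monopole_velocity(SPEC, rs, f))
        slope = np.diff(np.log(vs)) / np.diff(np.log(rs))
        assert slope[0] == pytest.approx(-2.0, abs=1e-3)

    def test_velocity_level_drop_across_ears_is_about_4_percent(self):
        drop = ac.velocity_level_drop(0.0297, 0.0303, 100.0)
        assert round(drop * 100) == 4

    def test_acceleration_is_minus_i_omega_velocity(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            r = rng.uniform(0.005, 1.0)
            f = rng.uniform(50.0, 5000.0)
            v = ac.monopole_velocity(SPEC, r, f, t=1e-4)
            a = ac.monopole_acceleration(SPEC, r, f, t=1e-4)
            assert a == pytest.approx(-1j * 2 * np.pi * f * v, rel=1e-12)

    def test_acceleration_near_field_limit(self):
        r, f = 0.002, 10.0   # kr ~ 8e-5
        a = ac.monopole_acceleration(SPEC, r, f)
        p = ac.monopole_pressure(SPEC, r, f)
        assert np.abs(a) * RHO * r / np.abs(p) == pytest.approx(1.0, abs=1e-4)

    def test_acceleration_closed_form_at_3cm_780hz(self):
        # |a| = (|p|/rho) sqrt(r^-2 + k^2) evaluated independently
        r, f = 0.03, 780.0
        k = 2 * np.pi * f / C
        expected = (224.0 / RHO) * np.sqrt(r ** -2 + k ** 2)
        a = ac.monopole_acceleration(SPEC, r, f)
        assert np.abs(a) == pytest.approx(expected, rel=1e-12)
        # cross-check through the DFT pipeline on a pure tone at r0 = r
        sr, n = 51200.0, 2048
        t = np.arange(n) / sr
        f_bin = round(f * n / sr) * sr / n   # exact DFT bin
        tone = ac.Waveform(224.0 * np.sin(2 * np.pi * f_bin * t), sr, "pressure")
        accel = ac.pressure_to_acceleration(tone, r)
        k_bin = 2 * np.pi * f_bin / C
        assert accel.peak() == pytest.approx(
            (224.0 / RHO) * np.sqrt(r ** -2 + k_bin ** 2), rel=1e-6)

    @pytest.mark.parametrize("bad", [(-0.01, 100.0), (0.01, -5.0), (0.0, 100.0)])
    def test_invalid_arguments_rejected(self, bad):
        r, f = bad
        with pytest.raises(ValueError):
            ac.monopole_pressure(SPEC, r, f)

    def test_far_and_near_field_consistency_bands(self):
        # kr >= 100: |v| rho c / |p| in [1, 1.0001]
        f = 5000.0
        k = 2 * np.pi * f / C
        r = 120.0 / k
        ratio = np.abs(ac.monopole_velocity(SPEC, r, f)) * RHO * C \
            / np.abs(ac.monopole_pressure(SPEC, r, f))
        assert 1.0 <= ratio <= 1.0001
        # kr <= 0.01: |a| rho r / |p| in [1, 1.0001]
        r = 0.005 / k
        ratio = np.abs(ac.monopole_acceleration(SPEC, r, f)) * RHO * r \
            / np.abs(ac.monopole_pressure(SPEC, r, f))
        assert 1.0 <= ratio <= 1.0001


def _brute_force_acceleration(p: np.ndarray, sr: float, r0: float) -> np.ndarray:
    """Independent O(N^2) oracle: direct DFT sums, per-component factor,
    direct inverse sums, Hermitian symmetry built explicitly."""
    n = len(p)
    l_idx = np.arange(n)
    W = np.exp(-2j * np.pi * np.outer(l_idx, l_idx) / n)
    P = W @ p
    freqs = np.where(l_idx <= n // 2, l_idx, l_idx - n) * sr / n
    k = 2 * np.pi * freqs / C
    A = (1.0 / r0 + 1j * k) / RHO * P
    a = (W.conj() @ A) / n
    return a.real


class TestPressureToAcceleration:
    def test_pure_tone_amplitude_and_phase(self):
        sr, n, r0 = 51200.0, 1024, 0.03
        f = 10 * sr / n
        t = np.arange(n) / sr
        tone = ac.Waveform(np.cos(2 * np.pi * f * t), sr, "pressure")
        out = ac.pressure_to_acceleration(tone, r0)
        k = 2 * np.pi * f / C
        amp = np.sqrt(r0 ** -2 + k ** 2) / RHO
        # RMS * sqrt(2) estimates the tone amplitude exactly over whole cycles
        assert out.rms() * np.sqrt(2) == pytest.approx(amp, rel=1e-9)
        # time-domain identity a = p/(rho r0) + p'/(rho c)
        expected = (np.cos(2 * np.pi * f * t) / (RHO * r0)
                    - 2 * np.pi * f * np.sin(2 * np.pi * f * t) / (RHO * C))
        assert np.allclose(out.samples, expected, atol=1e-12 * amp)

    def test_zero_input_zero_output(self):
        w = ac.Waveform(np.zeros(64), 1000.0, "pressure")
        assert not np.any(ac.pressure_to_acceleration(w, 0.05).samples)

    def test_matches_brute_force_dft_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.standard_normal(128)
        w = ac.Waveform(p, 51200.0, "pressure")
        fast = ac.pressure_to_acceleration(w, 0.03).samples
        slow = _brute_force_acceleration(p, 51200.0, 0.03)
        assert np.allclose(fast, slow, atol=1e-9 * np.max(np.abs(slow)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(alpha=st.floats(-5, 5), beta=st.floats(-5, 5),
           seed=st.integers(0, 100))
    def test_linearity(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        sr = 48000.0
        p1 = rng.standard_normal(96)
        p2 = rng.standard_normal(96)
        lhs = ac.pressure_to_acceleration(
            ac.Waveform(alpha * p1 + beta * p2, sr, "pressure"), 0.04).samples
        rhs = (alpha * ac.pressure_to_acceleration(ac.Waveform(p1, sr, "pressure"), 0.04).samples
               + beta * ac.pressure_to_acceleration(ac.Waveform(p2, sr, "pressure"), 0.04).samples)
        assert np.allclose(lhs, rhs, atol=1e-10 * max(1.0, np.max(np.abs(rhs))))

    def test_round_trip_recovers_pressure(self):
        rng = np.random.default_rng(11)
        p = rng.standard_normal(512)
        w = ac.Waveform(p, 51200.0, "pressure")
        back = ac.acceleration_to_pressure(
            ac.pressure_to_acceleration(w, 0.03), 0.03)
        rel = np.sqrt(np.mean((back.samples - p) ** 2) / np.mean(p ** 2))
        assert rel < 1e-10

    def test_propagation_preserves_spreading_and_delay(self):
        sr = 51200.0
        t = np.arange(512) / sr
        pulse = np.exp(-((t - 2e-3) / 2e-4) ** 2)
        w = ac.Waveform(pulse, sr, "pressure")
        out = ac.propagate_pressure(w, 0.03, 0.06)
        energy_ratio = np.sum(out.samples ** 2) / np.sum(pulse ** 2)
        assert energy_ratio == pytest.approx(0.25, rel=1e-3)
        delay = (np.argmax(out.samples) - np.argmax(pulse)) / sr
        assert delay == pytest.approx(0.03 / C, abs=1.0 / sr)


class TestGradientAcceleration:
    SR = 51200.0

    def test_identical_inputs_give_zero(self):
        w = ac.Waveform(np.sin(np.linspace(0, 20, 256)), self.SR, "pressure")
        out = ac.gradient_acceleration(w, w, 0.015)
        assert not np.any(out.samples)

    def test_linear_spatial_ramp(self):
        # p(x) = beta x, constant in t -> a = -beta / rho
        beta = 200.0
        left = ac.Waveform(np.full(128, beta * 0.0), self.SR, "pressure")
        right = ac.Waveform(np.full(128, beta * 0.015), self.SR, "pressure")
        out = ac.gradient_acceleration(left, right, 0.015)
        assert np.allclose(out.samples, -beta * 0.015 / (RHO * 0.015))

    def test_matches_analytic_monopole_acceleration(self):
        # monopole field sampled 1.5 cm apart approximates the analytic
        # x-projected acceleration within 5% for in-band frequencies
        sr = 51200.0
        t = np.arange(1024) / sr
        f = 800.0
        src = ac.Waveform(np.sin(2 * np.pi * f * t) * np.hanning(1024), sr,
                          "pressure")
        r_mid = 0.06
        p_l = ac.propagate_pressure(src, 0.03, r_mid - 0.0075)
        p_r = ac.propagate_pressure(src, 0.03, r_mid + 0.0075)
        est = ac.gradient_acceleration(p_l, p_r, 0.015)
        ref = ac.pressure_to_acceleration(
            ac.propagate_pressure(src, 0.03, r_mid), r_mid)
        err = np.sqrt(np.mean((est.samples - ref.samples) ** 2)
                      / np.mean(ref.samples ** 2))
        assert err < 0.05

    def test_mismatched_inputs_rejected(self):
        a = ac.Waveform(np.zeros(64) + 1.0, self.SR, "pressure")
        b = ac.Waveform(np.zeros(65) + 1.0, self.SR, "pressure")
        with pytest.raises(ValueError):
            ac.gradient_acceleration(a, b, 0.015)


def _monopole_pair(src: ac.Waveform, x_src: float, x0: float, x1: float):
    """(p, ax) at two points from a monopole at x_src on the x axis."""
    fields = []
    for x in (x0, x1):
        r = abs(x - x_src)
        sign = np.sign(x - x_src)
        p = ac.propagate_pressure(src, 0.03, r)
        a = ac.pressure_to_acceleration(p, r)
        fields.append((p, a.with_samples(sign * a.samples)))
    return fields


class TestCueEstimation:
    SR = 51200.0

    def _source(self, f=780.0, n=1024):
        t = np.arange(n) / self.SR
        return ac.Waveform(np.sin(2 * np.pi * f * t) * np.hanning(n),
                           self.SR, "pressure")

    def test_identical_fields_zero_cues_undefined_itd(self):
        src = self._source()
        a = ac.pressure_to_acceleration(src, 0.03)
        cues = ac.estimate_cues((src, a), (src, a), spacing=0.03)
        assert cues.p_ild == 0 and cues.m_ild == 0
        assert not cues.p_itd_defined and not cues.m_itd_defined

    def test_monopole_on_left_gives_positive_cues(self):
        src = self._source()
        (pl, al), (pr, ar) = _monopole_pair(src, -0.03, -0.015, 0.015)
        cues = ac.estimate_cues((pl, al), (pr, ar), spacing=0.03)
        assert cues.p_ild > 0 and cues.m_ild > 0 and cues.p_itd > 0

    def test_silent_fields_raise(self):
        z = ac.Waveform(np.zeros(64), self.SR, "pressure")
        za = ac.Waveform(np.zeros(64), self.SR, "acceleration")
        with pytest.raises(ac.SilentFieldError):
            ac.estimate_cues((z, za), (z, za), spacing=0.03)

    def test_maximal_itd_for_ear_separation(self):
        # source on the sensor axis: delay = separation / c = 0.4 us
        itd = ac.geometric_itd(0.03 - 0.0003, 0.03 + 0.0003)
        assert itd * 1e6 == pytest.approx(0.4, rel=1e-12)

    def test_phase_delay_agrees_with_cross_correlation(self):
        src = self._source(f=600.0)
        delayed = ac.propagate_pressure(src, 0.03, 0.045)
        tau_ref = 0.015 / C
        tau_xc = ac.cross_correlation_delay(src, delayed)
        assert tau_xc == pytest.approx(tau_ref, abs=3e-6)
        a0 = ac.pressure_to_acceleration(src, 0.03)
        a1 = ac.pressure_to_acceleration(delayed, 0.045)
        cues = ac.estimate_cues((src, a0), (delayed, a1), spacing=0.015)
        assert cues.p_itd == pytest.approx(tau_ref, rel=0.1)

    def test_pressure_ild_frequency_independent_at_2_percent(self):
        # level drop across 0.6 mm at 3 cm is 2% at every frequency
        for f in (100.0, 780.0, 3000.0, 10000.0):
            near = np.abs(ac.monopole_pressure(SPEC, 0.0297, f))
            far = np.abs(ac.monopole_pressure(SPEC, 0.0303, f))
            assert round((1 - far / near) * 100) == 2


class TestWaveformIO:
    def test_wav_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        w = ac.Waveform(rng.standard_normal(256).astype(np.float32),
                        48000.0, "acceleration")
        w.to_wav(tmp_path / "w.wav")
        back = ac.Waveform.from_wav(tmp_path / "w.wav")
        assert back.quantity == "acceleration"
        assert back.sample_rate == 48000.0
        assert np.allclose(back.samples, w.samples, atol=1e-7)

    def test_csv_round_trip(self, tmp_path):
        w = ac.Waveform(np.sin(np.linspace(0, 6, 100)), 1000.0, "pressure")
        w.to_csv(tmp_path / "w.csv")
        back = ac.Waveform.from_csv(tmp_path / "w.csv")
        assert back.sample_rate == pytest.approx(1000.0, rel=1e-6)
        assert np.allclose(back.samples, w.samples, atol=1e-12)

    def test_cue_table_columns(self):
        est = ac.CueEstimate(1.0, 0.1, 1e-6, 2e-6, 0.03)
        df = ac.cue_table({"single_L_pos": est})
        assert list(df.columns) == ["config_id", "p_ild_pa", "m_ild_ms2",
                                    "p_itd_s", "m_itd_s"]
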