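"""Multi-speaker conditioning: prediction, solving, trick, interpolation."""

import numpy as np
import pytest
from scipy.signal import correlate

from dualhear import acoustics as ac
from dualhear import field_control as fc
from dualhear import synthetic as syn

from conftest import N_CONDITION

SR = 51200.0


def _toy_grid(kernels, positions=None, speakers=None, sr=SR):
    m = kernels.shape[0]
    positions = positions if positions is not None else np.zeros((1, 2))
    speakers = speakers if speakers is not None else np.array(
        [[-0.08, 0.0], [0.08, 0.0], [0.0, 0.08], [0.0, -0.08]])[:m]
    return fc.ImpulseResponseGrid(kernels, positions, speakers, sr)


class TestPredictField:
    def test_unit_impulse_kernel_returns_drive(self):
        n_k, n_s = 32, 200
        kernels = np.zeros((1, 1, 3, n_k))
        kernels[0, 0, 0, 0] = 1.0       # pressure kernel = delta
        grid = _toy_grid(kernels, speakers=np.array([[-0.08, 0.0]]))
        rng = np.random.default_rng(0)
        sig = rng.standard_normal((1, n_s))
        prog = fc.SpeakerProgram(sig, SR, np.ones(1))
        field = fc.predict_field(grid, prog, 0)
        assert np.allclose(field.p.samples, sig[0])
        assert not np.any(field.ax.samples)

    def test_delayed_scaled_delta_shift_theorem(self):
        n_k, n_s, d, g = 64, 150, 11, -2.5
        kernels = np.zeros((1, 1, 3, n_k))
        kernels[0, 0, 0, d] = g
        grid = _toy_grid(kernels, speakers=np.array([[-0.08, 0.0]]))
        sig = np.zeros((1, n_s))
        sig[0, :40] = np.sin(np.arange(40))
        field = fc.predict_field(grid, fc.SpeakerProgram(sig, SR, np.ones(1)), 0)
        expected = np.zeros(n_s)
        expected[d:d + 40] = g * sig[0, :40]
        assert np.allclose(field.p.samples, expected)

    def test_matches_brute_force_convolution(self):
        rng = np.random.default_rng(5)
        kernels = rng.standard_normal((2, 1, 3, 40))
        grid = _toy_grid(kernels, speakers=np.array([[-0.08, 0], [0.08, 0]]))
        sig = rng.standard_normal((2, 100))
        field = fc.predict_field(grid, fc.SpeakerProgram(sig, SR, np.ones(2)), 0)
        for q, wf in enumerate((field.p, field.ax, field.ay)):
            direct = sum(np.convolve(kernels[i, 0, q], sig[i])[:100]
                         for i in range(2))
            rel = np.sqrt(np.mean((wf.samples - direct) ** 2)
                          / max(np.mean(direct ** 2), 1e-30))
            assert rel < 1e-9

    def test_sample_rate_mismatch_rejected(self, ir_grid):
        prog = fc.SpeakerProgram(np.zeros((4, 64)), 44100.0, np.ones(4))
        with pytest.raises(ValueError):
            fc.predict_field(ir_grid, prog, 0)


class TestSolveProgram:
    def test_closed_loop_all_configurations(self, ir_grid, template, centre_index):
        # every stimulus configuration reproduced with <= 5% relative RMS
        # per non-zero component and <= 5% leakage into zero components
        for label in ("single_L_pos", "single_R_neg", "pressure_pos",
                      "pressure_neg", "motion_pos", "motion_neg"):
            target = fc.TargetField.from_template(template, label,
                                                  n_samples=N_CONDITION)
            program = fc.solve_program(ir_grid, target, centre_index)
            errors = fc.field_errors(ir_grid, program, centre_index, target)
            for component, err in errors.items():
                assert err <= 0.05, (label, component, err)

    def test_under_determined_system_rejected(self, template):
        kernels = np.zeros((2, 1, 3, 16))
        grid = _toy_grid(kernels, speakers=np.array([[-0.08, 0], [0.08, 0]]))
        target = fc.TargetField.from_template(template, "single_L_pos",
                                              n_samples=1024)
        with pytest.raises(fc.ConditioningError):
            fc.solve_program(grid, target, 0)

    def test_tight_bounds_saturate_and_are_respected(self, ir_grid, template,
                                                     centre_index):
        target = fc.TargetField.from_template(template, "single_L_pos",
                                              n_samples=N_CONDITION)
        program = fc.solve_program(ir_grid, target, centre_index,
                                   alpha=0.02, gamma=1.0)
        n = program.n_samples
        freqs = np.fft.rfftfreq(n, 1.0 / SR)
        S = np.fft.rfft(program.signals, axis=1)
        B = 0.02 * 1.0 * np.abs(np.fft.rfft(target.bound_reference.samples))
        in_band = (freqs >= 200) & (freqs <= 1200) & (B > 0)
        tol = 1e-8 * max(B.max(), 1.0)
        assert np.all(np.abs(S[:, in_band].real) <= B[in_band] + tol)
        assert np.all(np.abs(S[:, in_band].imag) <= B[in_band] + tol)
        # bounds this tight must clip some coefficients to the box edge
        on_edge = np.isclose(np.abs(S[:, in_band].real), B[in_band], rtol=1e-6)
        assert on_edge.any()
        # and the residual is reported
        assert program.diagnostics["max_bin_residual"] > 0

    def test_conditioning_beats_naive_playback_tenfold(self, ir_grid, template,
                                                       centre_index,
                                                       single_left_program):
        target, program = single_left_program
        err_cond = fc.field_errors(ir_grid, program, centre_index, target)
        # naive: play the band-limited template from the left speaker,
        # optimally aligned and scaled for the pressure component
        n = target.n_samples
        sig = np.zeros((4, n))
        sig[0] = target.bound_reference.samples
        pred = fc.predict_field(
            ir_grid, fc.SpeakerProgram(sig, SR, np.ones(4)), centre_index)
        shift = int(np.argmax(correlate(target.p.samples, pred.p.samples,
                                        mode="full"))) - (n - 1)
        sig[0] = np.roll(sig[0], shift)
        pred = fc.predict_field(
            ir_grid, fc.SpeakerProgram(sig, SR, np.ones(4)), centre_index)
        scale = (np.dot(pred.p.samples, target.p.samples)
                 / np.dot(pred.p.samples, pred.p.samples))
        err_naive = fc.field_errors(
            ir_grid, fc.SpeakerProgram(sig * scale, SR, np.ones(4)),
            centre_index, target)
        assert err_naive["p"] >= 10 * err_cond["p"]
        assert err_naive["ax"] >= 10 * err_cond["ax"]

    def test_band_discipline(self, single_left_program):
        _, program = single_left_program
        for i in range(program.n_speakers):
            w = ac.Waveform(program.signals[i], SR, "voltage")
            assert fc.out_of_band_energy_fraction(w) <= 0.01

    def test_ill_conditioned_bins_skipped_with_diagnostics(self, template):
        # identical kernels for all speakers -> rank-1 kernel matrix
        rng = np.random.default_rng(2)
        base = rng.standard_normal(64) * np.exp(-np.arange(64) / 10)
        kernels = np.zeros((3, 1, 3, 64))
        for i in range(3):
            kernels[i, 0, 0] = base
        grid = _toy_grid(kernels, speakers=np.array(
            [[-0.08, 0], [0.08, 0], [0.0, 0.08]]))
        target = fc.TargetField.from_template(template, "single_L_pos",
                                              n_samples=1024)
        program = fc.solve_program(grid, target, 0)
        assert len(program.diagnostics["skipped_bins"]) > 0
        assert np.all(np.isfinite(program.signals))


class TestStandingWaves:
    def test_symmetric_in_phase_drive_nulls_acceleration(self, anechoic_grid,
                                                         template):
        centre = anechoic_grid.position_index((0.0, 0.0))
        n = 2048
        ref = fc.band_limit(ac.Waveform(
            np.pad(template.samples, (0, n - len(template))), SR, "pressure"))
        sig = np.zeros((4, n))
        sig[0] = sig[1] = ref.samples          # opposing x speakers in phase
        field = fc.predict_field(
            anechoic_grid, fc.SpeakerProgram(sig, SR, np.ones(4)), centre)
        assert field.ax.rms() <= 1e-12 * field.p.rms()

    def test_symmetric_anti_phase_drive_nulls_pressure(self, anechoic_grid,
                                                       template):
        centre = anechoic_grid.position_index((0.0, 0.0))
        n = 2048
        ref = fc.band_limit(ac.Waveform(
            np.pad(template.samples, (0, n - len(template))), SR, "pressure"))
        sig = np.zeros((4, n))
        sig[0] = ref.samples
        sig[1] = -ref.samples
        field = fc.predict_field(
            anechoic_grid, fc.SpeakerProgram(sig, SR, np.ones(4)), centre)
        assert field.p.rms() <= 1e-10 * field.ax.rms() * 30.0

    @pytest.mark.parametrize("mode", ["pressure_only", "motion_only"])
    def test_solver_leakage_on_echoic_kernels(self, ir_grid, template,
                                              centre_index, mode):
        program = fc.make_standing_wave_program(
            ir_grid, template, mode, centre_index, n_samples=N_CONDITION)
        assert program.diagnostics["off_target_leakage"] <= 0.05

    def test_unknown_mode_rejected(self, ir_grid, template, centre_index):
        with pytest.raises(ValueError):
            fc.make_standing_wave_program(ir_grid, template, "both",
                                          centre_index)


class TestTrickProgram:
    @pytest.fixture(scope="class")
    @staticmethod
    def trick(ir_grid, centre_index, single_left_program):
        target, program = single_left_program
        return fc.make_trick_program(ir_grid, program, centre_index, target)

    def test_pressure_inverted_motion_preserved(self, trick):
        assert trick.diagnostics["pressure_correlation"] <= -0.99
        assert trick.diagnostics["ax_correlation"] >= 0.99

    def test_cue_signs_flip_for_pressure_not_motion(self, ir_grid, centre_index,
                                                    single_left_program, trick):
        _, single = single_left_program
        left = ir_grid.position_index((-0.015, 0.0))
        right = ir_grid.position_index((0.015, 0.0))

        def cues(program):
            fl = fc.predict_field(ir_grid, program, left)
            fr = fc.predict_field(ir_grid, program, right)
            return ac.estimate_cues((fl.p, fl.ax), (fr.p, fr.ax), spacing=0.03)

        cs, ct = cues(single), cues(trick)
        assert np.sign(ct.p_ild) == -np.sign(cs.p_ild)
        assert np.sign(ct.p_itd) == -np.sign(cs.p_itd)
        assert np.sign(ct.m_ild) == np.sign(cs.m_ild)
        assert np.sign(ct.m_itd) == np.sign(cs.m_itd)

    def test_difference_field_is_twice_the_pressure(self, ir_grid, centre_index,
                                                    single_left_program, trick):
        # trick-minus-single: pressure ~ -2 p_single, ax difference <= 5% RMS
        _, single = single_left_program
        f_single = fc.predict_field(ir_grid, single, centre_index)
        f_trick = fc.predict_field(ir_grid, trick, centre_index)
        dp = f_trick.p.samples - f_single.p.samples
        rel = np.sqrt(np.mean((dp + 2 * f_single.p.samples) ** 2)
                      / np.mean((2 * f_single.p.samples) ** 2))
        assert rel <= 0.05
        da = f_trick.ax.samples - f_single.ax.samples
        assert np.sqrt(np.mean(da ** 2) / np.mean(f_single.ax.samples ** 2)) <= 0.05

    def test_zero_orthogonal_pressure_response_rejected(self, ir_grid, template,
                                                        centre_index,
                                                        single_left_program):
        target, program = single_left_program
        crippled = fc.ImpulseResponseGrid(ir_grid.kernels.copy(),
                                          ir_grid.positions,
                                          ir_grid.speaker_positions,
                                          ir_grid.sample_rate)
        crippled.kernels[2, :, 0, :] = 0.0   # y-axis speakers: no pressure
        crippled.kernels[3, :, 0, :] = 0.0
        with pytest.raises(fc.ConditioningError):
            fc.make_trick_program(crippled, program, centre_index, target)


class TestInterpolation:
    @pytest.fixture(scope="class")
    @staticmethod
    def node_programs(ir_grid, template):
        programs = {}
        for xy in [(0.0, 0.0), (0.015, 0.0), (0.0, 0.015), (0.015, 0.015)]:
            idx = ir_grid.position_index(xy)
            target = fc.TargetField.from_template(template, "single_L_pos",
                                                  n_samples=2048)
            programs[idx] = fc.solve_program(ir_grid, target, idx)
        return programs

    def test_query_at_node_returns_node_program(self, ir_grid, node_programs):
        idx = ir_grid.position_index((0.015, 0.0))
        out = fc.interpolate_program(ir_grid, node_programs, (0.015, 0.0))
        assert np.allclose(out.signals, node_programs[idx].signals)

    def test_midpoint_is_arithmetic_mean(self, ir_grid, node_programs):
        a = node_programs[ir_grid.position_index((0.0, 0.0))]
        b = node_programs[ir_grid.position_index((0.015, 0.0))]
        out = fc.interpolate_program(ir_grid, node_programs, (0.0075, 0.0))
        assert np.allclose(out.signals, 0.5 * (a.signals + b.signals))

    def test_interpolated_field_error_stays_bounded(self, tank, ir_grid,
                                                    template, node_programs):
        # field error at an interpolated position <= field error at the
        # surrounding nodes + 10%; the true field at the off-grid query is
        # evaluated through a finer synthetic kernel grid of the same tank
        query = (0.0075, 0.0075)
        out = fc.interpolate_program(ir_grid, node_programs, query)
        target = fc.TargetField.from_template(template, "single_L_pos",
                                              n_samples=2048)
        node_errs = [fc.field_errors(ir_grid, prog, idx, target)["p"]
                     for idx, prog in node_programs.items()]
        fine = syn.make_tank_irs(tank, grid_n=3, spacing=0.0075)
        err = fc.field_errors(fine, out, fine.position_index(query), target)["p"]
        assert err <= max(node_errs) + 0.10

    def test_query_outside_hull_rejected(self, ir_grid, node_programs):
        with pytest.raises(ValueError):
            fc.interpolate_program(ir_grid, node_programs, (0.2, 0.0))

    def test_missing_node_program_rejected(self, ir_grid, node_programs):
        with pytest.raises(ValueError):
            fc.interpolate_program(ir_grid, node_programs, (-0.0075, 0.0))


class TestGridIO:
    def test_hdf5_round_trip(self, ir_grid, tmp_path):
        path = tmp_path / "grid.h5"
        ir_grid.to_hdf5(path)
        back = fc.ImpulseResponseGrid.from_hdf5(path)
        assert np.allclose(back.kernels, ir_grid.kernels)
        assert np.allclose(back.positions, ir_grid.positions)
        assert back.sample_rate == ir_grid.sample_rate

    def test_program_wav_round_trip(self, single_left_program, tmp_path):
        _, program = single_left_program
        path = tmp_path / "prog.wav"
        program.to_wav(path)
        back = fc.SpeakerProgram.from_wav(path)
        assert back.label == program.label
        assert back.band == program.band
        assert np.allclose(back.signals, program.signals, atol=1e-6)

    def test_kernel_csv_export(self, ir_grid, tmp_path):
        path = tmp_path / "kernel.csv"
        ir_grid.export_kernel_csv(path, 0, 0, "pressure")
        w = ac.Waveform.from_csv(path)
        assert len(w) == ir_grid.kernel_length
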