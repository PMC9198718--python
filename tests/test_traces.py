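"""P/8 subtraction, steady-state windows and Q_off integration."""

import numpy as np
import pytest
from dataclasses import replace

from clc4pipe import (
    CellPassiveSpec,
    ProtocolSpec,
    Recording,
    VariantConfig,
    build_iv,
    integrate_qoff,
    measure_steady_state,
    p8_subtract,
    simulate_cell,
)


def passive_only_variant():
    """A 'cell' with no transporter at all (i_max_density = 0)."""
    return VariantConfig("empty", v_half=75.0, i_max_density=0.0)


class TestP8Subtraction:
    def test_linear_cell_subtracts_to_exact_zero_without_noise(self, protocol):
        passive = CellPassiveSpec(noise_sd=0.0)
        rec = simulate_cell(passive_only_variant(), protocol, passive, seed=1)
        sub = p8_subtract(rec)
        assert np.max(np.abs(sub.sweeps)) < 1e-9

    def test_linear_cell_leaves_zero_mean_noise(self, protocol, noisy_passive):
        rec = simulate_cell(passive_only_variant(), protocol, noisy_passive,
                            seed=2)
        sub = p8_subtract(rec)
        # averaging 8 subpulses and scaling by 8 triples the per-sample noise
        expected_sd = 3.0 * noisy_passive.noise_sd
        # the subtracted template baseline adds a common per-sweep offset of
        # sd = 8*noise_sd/sqrt(8*n_pre); the grand mean feels both terms
        sd_offset = (protocol.p8_count * noisy_passive.noise_sd
                     / np.sqrt(protocol.p8_count * protocol.n_pre))
        sd_mean = np.sqrt(sd_offset ** 2 / protocol.n_voltages
                          + expected_sd ** 2 / sub.sweeps.size)
        assert abs(sub.sweeps.mean()) < 4 * sd_mean
        assert sub.sweeps.std() == pytest.approx(expected_sd, rel=0.05)

    def test_nonlinear_component_preserved(self, noisy_wt_recording,
                                           noisy_passive):
        """Subtracted traces match the simulator's stored nonlinear
        decomposition; residuals are pure (amplified) sampling noise."""
        rec = noisy_wt_recording
        sub = p8_subtract(rec)
        gt = rec.ground_truth
        for i, v in enumerate(rec.protocol.voltages):
            resid = sub.sweeps[i] - gt.nonlinear_sweep(rec.protocol, v)
            rms = np.sqrt(np.mean(resid ** 2))
            assert rms <= 3.3 * noisy_passive.noise_sd
            assert np.max(np.abs(resid)) <= 6 * 3 * noisy_passive.noise_sd

    def test_subtraction_is_idempotent(self, quiet_wt_recording,
                                       noisy_wt_recording, noisy_passive):
        once = p8_subtract(quiet_wt_recording)
        twice = p8_subtract(once)
        assert np.max(np.abs(twice.sweeps - once.sweeps)) < 1e-9
        once_n = p8_subtract(noisy_wt_recording)
        twice_n = p8_subtract(once_n)
        # second pass changes traces at most at the noise floor
        delta = twice_n.sweeps - once_n.sweeps
        assert np.sqrt(np.mean(delta ** 2)) < 3.5 * noisy_passive.noise_sd

    def test_missing_subpulses_rejected(self, quiet_wt_recording):
        rec = Recording(
            protocol=quiet_wt_recording.protocol,
            sweeps=quiet_wt_recording.sweeps,
            p8_sweeps=None,
            fluorescence=0.0,
        )
        with pytest.raises(ValueError, match="P/8"):
            p8_subtract(rec)

    def test_provenance_recorded(self, quiet_wt_recording):
        assert p8_subtract(quiet_wt_recording).subtraction == "P/8"


class TestSteadyState:
    def test_constant_segment_returns_its_value(self, protocol):
        sweeps = np.full((protocol.n_voltages, protocol.n_samples), 1000.0)
        rec = Recording(protocol=protocol, sweeps=sweeps, p8_sweeps=None,
                        fluorescence=0.0)
        np.testing.assert_allclose(measure_steady_state(rec), 1.0)  # 1 nA

    def test_noise_free_wt_matches_closed_form(self, quiet_wt_recording):
        sub = p8_subtract(quiet_wt_recording)
        gt = quiet_wt_recording.ground_truth
        i_ss = measure_steady_state(sub)
        assert i_ss[-1] == pytest.approx(gt.i_ss(175.0), rel=5e-3)

    @pytest.mark.parametrize("window", [(5.0, 5.0), (9.0, 11.0), (-1.0, 2.0)])
    def test_bad_windows_rejected(self, quiet_wt_recording, window):
        with pytest.raises(ValueError):
            measure_steady_state(quiet_wt_recording, window_ms=window)


class TestQoffIntegration:
    def make_tail_recording(self, tail_pa):
        """Single-sweep recording whose tail is the given trace (pA)."""
        prot = ProtocolSpec(v_start=135.0, v_end=135.0, tail_ms=20.0)
        sweeps = np.zeros((1, prot.n_samples))
        sweeps[0, prot.tail_slice] = tail_pa
        return prot, Recording(protocol=prot, sweeps=sweeps, p8_sweeps=None,
                               fluorescence=0.0)

    def test_zero_trace_gives_zero_charge(self):
        prot, rec = self.make_tail_recording(0.0)
        assert integrate_qoff(rec)[0] == 0.0

    def test_exponential_tail_matches_closed_form(self):
        """An exponential tail I0*exp(-t/tau) integrates to I0*tau: 100 pA
        with tau = 1 ms carries 0.1 pC (sign: outward tail -> negative q)."""
        prot = ProtocolSpec(v_start=135.0, v_end=135.0, tail_ms=20.0)
        t = np.arange(prot.n_tail) * prot.dt_ms
        _, rec = self.make_tail_recording(100.0 * np.exp(-t / 1.0))
        q = integrate_qoff(rec, tail_window_ms=(0.0, 15.0))[0]
        assert abs(q) == pytest.approx(0.1, rel=0.01)
        assert q < 0  # positive (outward) tail current => negative charge

    def test_linearity_and_baseline_invariance(self):
        prot = ProtocolSpec(v_start=135.0, v_end=135.0, tail_ms=20.0)
        t = np.arange(prot.n_tail) * prot.dt_ms
        tail = -80.0 * np.exp(-t / 0.7)
        _, rec1 = self.make_tail_recording(tail)
        _, rec3 = self.make_tail_recording(3.0 * tail)
        _, rec_off = self.make_tail_recording(tail + 55.0)
        q1 = integrate_qoff(rec1)[0]
        assert integrate_qoff(rec3)[0] == pytest.approx(3 * q1, rel=1e-9)
        assert integrate_qoff(rec_off)[0] == pytest.approx(q1, rel=1e-6)

    def test_noise_free_simulation_matches_designed_charge(
            self, quiet_wt_recording):
        sub = p8_subtract(quiet_wt_recording)
        gt = quiet_wt_recording.ground_truth
        q = integrate_qoff(sub)
        i135 = int(np.argmin(np.abs(sub.protocol.voltages - 135.0)))
        assert q[i135] == pytest.approx(gt.q_off(135.0), rel=0.01)

    def test_window_beyond_tail_rejected(self, quiet_wt_recording):
        with pytest.raises(ValueError):
            integrate_qoff(quiet_wt_recording, tail_window_ms=(0.0, 25.0))


class TestBuildIV:
    def test_full_protocol_yields_30_sorted_points(self, quiet_wt_recording):
        iv = build_iv(p8_subtract(quiet_wt_recording))
        assert len(iv) == 30
        v = [p.v for p in iv]
        assert v == sorted(v)
        assert np.all(np.diff(v) > 0)

    def test_single_step_protocol_yields_one_point(self, wt, quiet_passive):
        prot = ProtocolSpec(v_start=135.0, v_end=135.0)
        rec = simulate_cell(wt, prot, quiet_passive, seed=9)
        iv = build_iv(p8_subtract(rec))
        assert len(iv) == 1 and iv[0].v == 135.0
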