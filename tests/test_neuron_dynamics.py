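"""Membrane, receptor-kinetics and magnesium-block unit tests.

Numerical oracles are the closed-form solutions of the passive membrane and
the first-order gating ODE; Euler trajectories must converge to them at
first order in the step size.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chainsim.neuron_dynamics import (NeuronParams, NeuronState, ReceptorParams,
                                      mg_block, receptor_current, step_membrane,
                                      update_gating)


class TestMgBlock:
    def test_no_magnesium_means_no_block(self):
        for V in (-90.0, -70.0, 0.0, 40.0):
            assert mg_block(V, 0.0) == 1.0

    @pytest.mark.parametrize("V, expected", [(0.0, 0.781), (-70.0, 0.0445)])
    def test_jahr_stevens_values(self, V, expected):
        assert mg_block(V, 1.0) == pytest.approx(expected, rel=1e-2)

    def test_monotone_in_voltage_and_inverse_mg(self):
        V = np.linspace(-90, 50, 200)
        B = mg_block(V, 1.0)
        assert np.all(np.diff(B) > 0)
        assert mg_block(-50.0, 0.5) > mg_block(-50.0, 1.0) > mg_block(-50.0, 2.0)
        assert mg_block(200.0, 1.0) == pytest.approx(1.0, abs=1e-4)

    def test_negative_mg_rejected(self):
        with pytest.raises(ValueError):
            mg_block(-60.0, -0.1)


class TestGating:
    def test_no_drive_stays_closed(self):
        assert update_gating(0.0, 0.0, 1.1, 0.19, 0.1) == 0.0

    def test_exponential_decay_matches_closed_form(self):
        beta, dt, t_end = 0.19, 0.01, 10.0
        s = 1.0
        for _ in range(int(t_end / dt)):
            s = update_gating(s, 0.0, 1.1, beta, dt)
        assert s == pytest.approx(np.exp(-beta * t_end), rel=1e-2)

    def test_steady_state_under_constant_transmitter(self):
        alpha, beta, T = 1.1, 0.19, 1.0
        s = 0.0
        for _ in range(20000):
            s = update_gating(s, T, alpha, beta, 0.01)
        assert s == pytest.approx(alpha * T / (alpha * T + beta), rel=1e-3)
        assert s == pytest.approx(0.853, abs=5e-3)

    def test_euler_error_shrinks_first_order(self):
        beta, t_end = 0.19, 5.0
        errs = []
        for dt in (0.1, 0.01):
            s = 1.0
            for _ in range(int(round(t_end / dt))):
                s = update_gating(s, 0.0, 1.1, beta, dt)
            errs.append(abs(s - np.exp(-beta * t_end)))
        assert 5 < errs[0] / errs[1] < 20

    @given(s=st.floats(0, 1), T=st.floats(0, 2), dt=st.floats(0.01, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_gating_stays_in_unit_interval(self, s, T, dt):
        out = update_gating(s, T, alpha=5.0, beta=0.18, dt=dt)
        assert 0.0 <= out <= 1.0

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            update_gating(0.5, 1.0, 1.1, 0.19, 0.0)


class TestReceptorCurrent:
    def _ampa(self, g=2.0):
        return ReceptorParams("AMPA_rec", g_max=g, E_rev=0.0, alpha=1.1, beta=0.19)

    def test_closed_receptors_pass_no_current(self):
        state = NeuronState(V=-60.0, s=np.zeros(4))
        assert receptor_current(state, self._ampa(), np.ones(4)) == 0.0

    def test_zero_at_reversal_potential(self):
        state = NeuronState(V=0.0, s=np.full(3, 0.7))
        assert receptor_current(state, self._ampa(), np.ones(3)) == 0.0

    def test_single_afferent_magnitude(self):
        # w=1, s=0.5, g=2 nS, V - E_rev = -60 mV: 60 pA depolarizing
        state = NeuronState(V=-60.0, s=np.array([0.5]))
        I = receptor_current(state, self._ampa(2.0), np.array([1.0]))
        assert I == pytest.approx(60.0)
        assert I > 0  # inward convention: excitation below reversal depolarizes

    def test_nmda_current_is_mg_blocked(self):
        nmda = ReceptorParams("NMDA", g_max=2.0, E_rev=0.0, alpha=0.072,
                              beta=0.0066, Mg=1.0)
        state = NeuronState(V=-60.0, s=np.array([0.5]))
        I = receptor_current(state, nmda, np.array([1.0]))
        assert I == pytest.approx(60.0 * mg_block(-60.0, 1.0))

    def test_length_mismatch_is_structural_error(self):
        state = NeuronState(V=-60.0, s=np.zeros(3))
        with pytest.raises(ValueError, match="weight"):
            receptor_current(state, self._ampa(), np.ones(4))


class TestMembrane:
    def test_equilibrium_at_leak_potential(self):
        p = NeuronParams()
        st_ = NeuronState(V=p.V_L)
        st_, spiked = step_membrane(st_, p, 0.0, 0.1)
        assert st_.V == p.V_L and not spiked

    def test_passive_decay_matches_closed_form(self):
        p = NeuronParams()  # tau_m = 20 ms
        assert p.tau_m == pytest.approx(20.0)
        st_ = NeuronState(V=-60.0)
        for _ in range(200):  # 20 ms at dt=0.1
            st_, _ = step_membrane(st_, p, 0.0, 0.1)
        expected = p.V_L + 10.0 * np.exp(-1.0)  # -66.32 mV
        assert st_.V == pytest.approx(expected, abs=0.05)
        assert st_.V == pytest.approx(-66.32, abs=0.05)

    def test_euler_error_shrinks_first_order(self):
        p = NeuronParams()
        errs = []
        for dt in (0.1, 0.01):
            st_ = NeuronState(V=-60.0)
            for _ in range(int(round(20.0 / dt))):
                st_, _ = step_membrane(st_, p, 0.0, dt)
            errs.append(abs(st_.V - (p.V_L + 10.0 * np.exp(-1.0))))
        assert 5 < errs[0] / errs[1] < 20

    def test_threshold_crossing_spikes_and_resets(self):
        p = NeuronParams()
        st_ = NeuronState(V=p.V_thr - 0.1)
        st_, spiked = step_membrane(st_, p, 5e4, 0.1)
        assert spiked and st_.V == p.V_reset and st_.refr_remaining == p.tau_ref

    def test_refractory_clamps_voltage(self):
        p = NeuronParams()
        st_ = NeuronState(V=p.V_reset, refr_remaining=p.tau_ref)
        for _ in range(int(round(p.tau_ref / 0.1))):
            st_, spiked = step_membrane(st_, p, 1e5, 0.1)
            assert not spiked and st_.V == p.V_reset
        # refractory over: huge current may spike again
        st_, spiked = step_membrane(st_, p, 1e6, 0.1)
        assert spiked

    def test_min_interspike_interval_respects_refractory(self):
        p = NeuronParams()
        st_ = NeuronState(V=p.V_L)
        rng = np.random.default_rng(0)
        spikes = []
        t = 0.0
        for _ in range(20000):
            I = rng.uniform(0, 2500.0)
            st_, spiked = step_membrane(st_, p, I, 0.1, t=t)
            if spiked:
                spikes.append(t)
            t += 0.1
        isi = np.diff(spikes)
        assert len(spikes) > 10
        assert isi.min() >= p.tau_ref - 1e-9

    def test_nonfinite_current_raises(self):
        p = NeuronParams()
        with pytest.raises(FloatingPointError):
            step_membrane(NeuronState(V=-60.0), p, np.nan, 0.1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(V_reset=-40.0, V_thr=-50.0)
        with pytest.raises(ValueError):
            NeuronParams(tau_ref=-1.0)
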