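"""STDP kernel, efficacy dynamics and event-driven weight updates.

The event-driven implementation is cross-checked against brute-force
double loops over all spike pairs (and, for nearest pairing, over most
recent partners), with the efficacy trajectory replayed independently.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chainsim.config import STDPConfig
from chainsim.plasticity import (EfficacyState, PlasticityState, process_spike_train,
                                 stdp_kernel, update_efficacy)


def params(**kw):
    defaults = dict(eta=0.01, A_plus=1.0, A_minus=1.0, tau_plus=20.0,
                    tau_minus=20.0, w_min=0.0, w_max=5.0, pairing="nearest")
    defaults.update(kw)
    return STDPConfig(**defaults)


class TestKernel:
    def test_vanishes_at_long_lags(self):
        p = params()
        assert abs(stdp_kernel(1e4, p)) < 1e-12
        assert abs(stdp_kernel(-1e4, p)) < 1e-12

    def test_maximum_magnitude_is_one(self):
        p = params()
        grid = np.linspace(-500.0, 500.0, 200001)
        assert np.abs(stdp_kernel(grid, p)).max() == pytest.approx(1.0, abs=1e-3)

    def test_closed_form_value_at_one_time_constant(self):
        p = params()
        assert stdp_kernel(20.0, p) == pytest.approx(np.exp(-1.0), rel=1e-12)
        assert stdp_kernel(20.0, p) == pytest.approx(0.368, abs=5e-4)

    def test_coincident_spikes_produce_no_change(self):
        assert stdp_kernel(0.0, params()) == 0.0

    @given(dt=st.floats(0.01, 400.0))
    @settings(max_examples=100, deadline=None)
    def test_sign_antisymmetry(self, dt):
        p = params()
        assert np.sign(stdp_kernel(dt, p)) == -np.sign(stdp_kernel(-dt, p)) == 1.0

    def test_nonfinite_lag_rejected(self):
        with pytest.raises(ValueError):
            stdp_kernel(np.nan, params())


class TestEfficacy:
    def test_spike_depresses_multiplicatively(self):
        s = EfficacyState(E=1.0, u=0.2)
        assert update_efficacy(s, True, 0.1).E == pytest.approx(0.8)

    def test_recovery_matches_closed_form(self):
        tau = 500.0
        s = EfficacyState(E=0.5, u=0.2, tau_E=tau)
        dt, t_end = 0.1, 800.0
        for _ in range(int(t_end / dt)):
            update_efficacy(s, False, dt)
        assert s.E == pytest.approx(1.0 - 0.5 * np.exp(-t_end / tau), rel=1e-3)

    def test_rapid_spiking_approaches_depression_floor(self):
        s = EfficacyState(E=1.0, u=0.2, tau_E=500.0)
        values = []
        for _ in range(200):
            update_efficacy(s, True, 1.0)
            update_efficacy(s, False, 1.0)
            values.append(s.E)
        diffs = np.diff(values)
        assert np.all(diffs <= 1e-12)  # monotone decrease toward the floor
        assert 0.0 < values[-1] < 0.02


def _make_state(n=6, u=0.2, tau_E=500.0, w0=1.0, seed=0):
    rng = np.random.default_rng(seed)
    plastic = ~np.eye(n, dtype=bool)
    W = np.full((n, n), w0) * plastic
    return PlasticityState(W=W.copy(), plastic=plastic, u=u, tau_E=tau_E), W


def _random_spikes(n, count, t_max, seed):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0.0, t_max, count))
    ids = rng.integers(0, n, count)
    return t, ids


def _replay_efficacy(times, neurons, n, u, tau_E):
    """Independent scalar replay of E_j(t) for every spike; returns E at
    each event (before the event's own depression)."""
    E = np.ones(n)
    t_last = np.zeros(n)
    out = []
    for t, j in zip(times, neurons):
        Ej = 1.0 - (1.0 - E[j]) * np.exp(-(t - t_last[j]) / tau_E)
        out.append(Ej)
        # recover everyone lazily is equivalent; only j mutates here
        E[j] = Ej * (1.0 - u)
        t_last[j] = t
    return out


def _brute_force(times, neurons, n, p, u, tau_E, W0, mode):
    """Double-loop oracle over spike pairs (all pairs or nearest)."""
    W = W0.copy()
    plastic = ~np.eye(n, dtype=bool)
    E_at = _replay_efficacy(times, neurons, n, u, tau_E)
    hist = {j: [] for j in range(n)}
    for k, (t, post) in enumerate(zip(times, neurons)):
        for pre in range(n):
            if pre == post or not plastic[post, pre]:
                continue
            spikes = hist[pre] if mode == "all-pairs" else hist[pre][-1:]
            dw = 0.0
            for (tp, kp) in spikes:
                # efficacy of the presynaptic neuron at the update time
                Ej = E_at_of(E_at, times, neurons, pre, t, u, tau_E)
                dw += p.eta * Ej * p.A_plus * np.exp(-(t - tp) / p.tau_plus)
            W[post, pre] = np.clip(W[post, pre] + dw, p.w_min, p.w_max)
        for q in range(n):
            if q == post or not plastic[q, post]:
                continue
            spikes = hist[q] if mode == "all-pairs" else hist[q][-1:]
            dw = 0.0
            for (tq, kq) in spikes:
                dw -= p.eta * E_at[k] * p.A_minus * np.exp((tq - t) / p.tau_minus)
            W[q, post] = np.clip(W[q, post] + dw, p.w_min, p.w_max)
        hist[post].append((t, k))
    return W


def E_at_of(E_at, times, neurons, j, t, u, tau_E):
    """Efficacy of neuron j at time t, replayed from its spike history."""
    E, t_last = 1.0, 0.0
    for tk, nk, Ek in zip(times, neurons, E_at):
        if tk >= t:
            break
        if nk == j:
            E = Ek * (1.0 - u)
            t_last = tk
    return 1.0 - (1.0 - E) * np.exp(-(t - t_last) / tau_E)


class TestWeightUpdate:
    def test_zero_learning_rate_leaves_weights(self):
        state, W0 = _make_state()
        t, ids = _random_spikes(6, 50, 500.0, seed=1)
        process_spike_train(state, t, ids, params(eta=0.0))
        assert np.array_equal(state.W, W0)

    def test_single_pair_potentiation_value(self):
        # pre at t=0, post at t=10 ms, tau_plus=20, full efficacy (u=0):
        # dw = eta * e^(-1/2)
        state, _ = _make_state(n=2, w0=1.0, u=0.0)
        process_spike_train(state, [0.0, 10.0], [0, 1], params(eta=0.01))
        dw = state.W[1, 0] - 1.0
        assert dw == pytest.approx(0.01 * np.exp(-0.5), rel=1e-9)
        assert dw == pytest.approx(0.00607, abs=2e-5)

    def test_post_before_pre_depresses(self):
        state, _ = _make_state(n=2, w0=1.0)
        process_spike_train(state, [0.0, 10.0], [1, 0], params(eta=0.01))
        assert state.W[1, 0] < 1.0

    def test_weight_bounds_hold_under_dense_spiking(self):
        state, _ = _make_state(n=5, w0=4.9)
        t, ids = _random_spikes(5, 2000, 1000.0, seed=2)
        p = params(eta=0.5)
        process_spike_train(state, t, ids, p)
        off = ~np.eye(5, dtype=bool)
        assert np.all(state.W[off] >= p.w_min)
        assert np.all(state.W[off] <= p.w_max)
        assert np.all(np.isfinite(state.W))

    @pytest.mark.parametrize("mode", ["nearest", "all-pairs"])
    def test_event_driven_matches_brute_force(self, mode):
        n, u, tau_E = 6, 0.2, 500.0
        t, ids = _random_spikes(n, 50, 400.0, seed=7)
        p = params(eta=0.05, pairing=mode, w_max=50.0)
        state, W0 = _make_state(n=n, u=u, tau_E=tau_E, w0=1.0)
        process_spike_train(state, t, ids, p)
        W_ref = _brute_force(t, ids, n, p, u, tau_E, W0, mode)
        assert np.allclose(state.W, W_ref, atol=1e-9)
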