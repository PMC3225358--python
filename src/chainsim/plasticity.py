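"""Spike-timing-dependent plasticity with activity-dependent efficacy, and
the chain-learning experiment.

The weight update for a synapse j -> i is

    dw_ij = eta * E_j(t) * K(t_post - t_pre)

where K is the classic asymmetric exponential STDP kernel
(+A_plus exp(-dt/tau_plus) for post-after-pre, -A_minus exp(dt/tau_minus)
for pre-after-post, 0 at exactly dt = 0) and E_j is the short-term synaptic
efficacy of the presynaptic neuron: E drops by the factor (1 - u) at each of
its spikes and recovers toward 1 with time constant tau_E.  Efficacy keeps
the update bounded during dense firing.

The learning experiment drives four all-to-all-connected pools with
sequential template activity profiles (four ~300 ms bursts overlapping
~80 ms).  Because successive pools are co-active only during the overlap —
with the earlier pool leading — the kernel accumulates weight onto forward
(k -> k+1) connections and drains backward ones, hardwiring the pool
sequence into a feedforward chain.  Probes stimulate the first pool through
the full spiking network and record downstream responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .config import ModelConfig, STDPConfig as STDPParams
from .network_topology import Chain, NetworkTopology, build_learning_network
from .stimulus_generator import (StimulusEvent, TemplateProfileSpec,
                                 gen_poisson_train, gen_template_profiles)
from .task_engine import NetworkSimulator, TaskScenario, run_motor_task

__all__ = [
    "STDPParams",
    "EfficacyState",
    "PlasticityState",
    "stdp_kernel",
    "update_efficacy",
    "apply_weight_update",
    "run_learning_experiment",
    "LearningResult",
]


@dataclass
class EfficacyState:
    """Activity-dependent synaptic efficacy of one neuron (or an array)."""

    E: float | np.ndarray = 1.0
    u: float = 0.2
    tau_E: float = 500.0  # ms


def stdp_kernel(dt_spike, params: STDPParams):
    """Signed STDP kernel value(s) for spike-time difference t_post - t_pre (ms).

    Positive differences (post after pre) potentiate, negative depress;
    exactly coincident spikes produce no change.  With the default
    amplitudes A_plus = A_minus = 1 the kernel's maximum magnitude is 1.
    """
    dt = np.asarray(dt_spike, dtype=float)
    if not np.all(np.isfinite(dt)):
        raise ValueError("spike-time difference must be finite")
    out = np.where(
        dt > 0, params.A_plus * np.exp(-dt / params.tau_plus),
        np.where(dt < 0, -params.A_minus * np.exp(dt / params.tau_minus), 0.0))
    return out if out.ndim else float(out)


def update_efficacy(state: EfficacyState, spiked: bool, dt: float) -> EfficacyState:
    """Advance efficacy one step: multiplicative drop on a spike, otherwise
    Euler relaxation dE/dt = (1 - E)/tau_E.  E stays in (0, 1]."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if spiked:
        state.E = state.E * (1.0 - state.u)
    else:
        state.E = np.minimum(1.0, state.E + dt * (1.0 - state.E) / state.tau_E)
    return state


@dataclass
class PlasticityState:
    """Inter-pool weight matrix with STDP bookkeeping.

    ``W`` is dense, indexed ``[post, pre]``; ``plastic`` marks the synapses
    subject to learning.  Efficacy and spike traces are per neuron and
    updated lazily (values stored with their timestamp).
    """

    W: np.ndarray
    plastic: np.ndarray  # bool, same shape as W
    u: float = 0.2
    tau_E: float = 500.0
    last_spike: np.ndarray = None  # type: ignore[assignment]
    E_val: np.ndarray = None  # type: ignore[assignment]
    E_t: np.ndarray = None  # type: ignore[assignment]
    x_plus: np.ndarray = None  # all-pairs potentiation trace
    x_minus: np.ndarray = None  # all-pairs depression trace
    x_t: np.ndarray = None

    def __post_init__(self) -> None:
        n = self.W.shape[0]
        if self.last_spike is None:
            self.last_spike = np.full(n, -1e18)
        if self.E_val is None:
            self.E_val = np.ones(n)
        if self.E_t is None:
            self.E_t = np.zeros(n)
        if self.x_plus is None:
            self.x_plus = np.zeros(n)
        if self.x_minus is None:
            self.x_minus = np.zeros(n)
        if self.x_t is None:
            self.x_t = np.zeros(n)
        self._pre_of = [np.flatnonzero(self.plastic[i]) for i in range(n)]
        self._post_of = [np.flatnonzero(self.plastic[:, j]) for j in range(n)]

    def efficacy_at(self, idx, t):
        """Recovered efficacy E(t) for neuron index/indices without mutation."""
        return 1.0 - (1.0 - self.E_val[idx]) * np.exp(-(t - self.E_t[idx]) / self.tau_E)


def apply_weight_update(state: PlasticityState, neuron: int, t: float,
                        params: STDPParams) -> PlasticityState:
    """Process one spike event (neuron id + time) against the weight matrix.

    The spike acts simultaneously as the postsynaptic partner of all plastic
    synapses into the neuron (potentiation) and the presynaptic partner of
    all plastic synapses out of it (depression).  ``nearest`` pairing uses
    each partner's most recent spike; ``all-pairs`` accumulates over the full
    history through exponential spike traces.  Weights are clipped to
    [w_min, w_max] after the update.
    """
    eta = params.eta
    pres = state._pre_of[neuron]
    posts = state._post_of[neuron]
    E_n = float(state.efficacy_at(neuron, t))

    if params.pairing == "nearest":
        if pres.size and eta != 0.0:
            lag = t - state.last_spike[pres]
            kern = np.where(lag > 0, params.A_plus * np.exp(-lag / params.tau_plus), 0.0)
            E_pre = state.efficacy_at(pres, t)
            state.W[neuron, pres] = np.clip(
                state.W[neuron, pres] + eta * E_pre * kern, params.w_min, params.w_max)
        if posts.size and eta != 0.0:
            lag = state.last_spike[posts] - t  # <= 0
            kern = np.where(lag < 0, -params.A_minus * np.exp(lag / params.tau_minus), 0.0)
            state.W[posts, neuron] = np.clip(
                state.W[posts, neuron] + eta * E_n * kern, params.w_min, params.w_max)
    elif params.pairing == "all-pairs":
        decay_p = np.exp(-(t - state.x_t) / params.tau_plus)
        decay_m = np.exp(-(t - state.x_t) / params.tau_minus)
        if pres.size and eta != 0.0:
            E_pre = state.efficacy_at(pres, t)
            state.W[neuron, pres] = np.clip(
                state.W[neuron, pres]
                + eta * E_pre * params.A_plus * state.x_plus[pres] * decay_p[pres],
                params.w_min, params.w_max)
        if posts.size and eta != 0.0:
            state.W[posts, neuron] = np.clip(
                state.W[posts, neuron]
                - eta * E_n * params.A_minus * state.x_minus[posts] * decay_m[posts],
                params.w_min, params.w_max)
        # refresh this neuron's own traces and add the new spike
        self_p = state.x_plus[neuron] * np.exp(-(t - state.x_t[neuron]) / params.tau_plus)
        self_m = state.x_minus[neuron] * np.exp(-(t - state.x_t[neuron]) / params.tau_minus)
        state.x_plus[neuron] = self_p + 1.0
        state.x_minus[neuron] = self_m + 1.0
        state.x_t[neuron] = t
    else:
        raise ValueError(f"unknown pairing scheme {params.pairing!r}")

    state.E_val[neuron] = E_n * (1.0 - state.u)
    state.E_t[neuron] = t
    state.last_spike[neuron] = t
    return state


def process_spike_train(state: PlasticityState, times, neurons,
                        params: STDPParams) -> PlasticityState:
    """Apply a time-sorted stream of spikes to the plasticity state."""
    times = np.asarray(times, dtype=float)
    neurons = np.asarray(neurons, dtype=np.int64)
    for t, n in zip(times, neurons):
        apply_weight_update(state, int(n), float(t), params)
    return state


# ---------------------------------------------------------------------------
# the chain-learning experiment


@dataclass
class LearningResult:
    """Weight trajectories and probe responses of one learning run."""

    pool_ids: list[str]
    checkpoints: list[dict]  # {"session", "pool_peaks", "pair_means"}
    final_W: np.ndarray
    final_pair_means: np.ndarray  # (n_pools, n_pools) mean plastic weight
    manifest: dict

    def forward_backward(self, at=-1):
        """Mean forward (k -> k+1) and backward (k+1 -> k) weights per pair."""
        pm = self.checkpoints[at]["pair_means"]
        n = pm.shape[0]
        fwd = np.array([pm[k + 1, k] for k in range(n - 1)])  # [post, pre]
        bwd = np.array([pm[k, k + 1] for k in range(n - 1)])
        return fwd, bwd


def _pair_means(W, plastic, pools):
    n = len(pools)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            sl_post = slice(pools[a].start, pools[a].start + pools[a].size)
            sl_pre = slice(pools[b].start, pools[b].start + pools[b].size)
            mask = plastic[sl_post, sl_pre]
            out[a, b] = W[sl_post, sl_pre][mask].mean() if mask.any() else 0.0
    return out


def _probe(topology, W_dense, plastic, config, seed, duration=900.0):
    """Stimulate pool 1 through the spiking network; per-pool peak rates."""
    W_inter = sp.csr_matrix(np.where(plastic, W_dense, 0.0))
    topo = NetworkTopology(
        pools=topology.pools, chains=topology.chains,
        W_local_E=topology.W_local_E, W_local_I=topology.W_local_I,
        W_inter=W_inter, rng_seed=topology.rng_seed,
        ref_pool_size=topology.ref_pool_size)
    sim = NetworkSimulator(topo, config, seed)
    stim = config.stimulus
    sim.schedule_event(StimulusEvent(
        target_pool=topology.pools[0].id, target_fraction=stim.intention_fraction,
        onset=50.0, duration=2.0 * stim.intention_width, rate_profile="bell",
        peak_rate=stim.intention_rate, channel="pfc", seed=sim.next_seed(),
        width=stim.intention_width))
    sim.run(duration)
    rates = np.array(sim.rate_history)
    return rates.max(axis=0), rates


def run_learning_experiment(config: ModelConfig, n_pools=4, sessions=None,
                            checkpoints=None, seed=None, shuffle=False,
                            keep_checkpoint_weights=False) -> LearningResult:
    """Hebbian hardwiring of a pool sequence into a feedforward chain.

    Per session each pool's neurons fire as inhomogeneous Poisson processes
    following that pool's template activity profile; the resulting spike
    stream drives the STDP update of the all-to-all inter-pool weights.
    With ``shuffle=True`` the assignment of templates to pools is permuted
    anew each session (temporal-order control).  At the requested checkpoint
    sessions the network is probed by stimulating pool 1 only.
    """
    stdp = config.stdp
    sessions = stdp.sessions if sessions is None else sessions
    if sessions < 1:
        raise ValueError("sessions must be >= 1")
    checkpoints = list(stdp.checkpoints) if checkpoints is None else list(checkpoints)
    seed = config.seed if seed is None else seed
    spec: TemplateProfileSpec = config.stimulus.template
    if spec.n_acts != n_pools:
        spec = TemplateProfileSpec(
            n_acts=n_pools, burst_duration=spec.burst_duration, overlap=spec.overlap,
            peak_rate=spec.peak_rate, filter_sigma=spec.filter_sigma,
            baseline=spec.baseline)

    topo = build_learning_network(config, n_pools=n_pools,
                                  w_init_max=stdp.w_init_max)
    pools = topo.pools
    n = topo.n_neurons
    plastic = np.zeros((n, n), dtype=bool)
    coo = topo.W_inter.tocoo()
    plastic[coo.row, coo.col] = True
    W = np.zeros((n, n))
    W[coo.row, coo.col] = coo.data
    state = PlasticityState(W=W, plastic=plastic, u=config.depression.u,
                            tau_E=config.depression.tau_E)

    t_grid, profiles = gen_template_profiles(spec)
    session_len = float(t_grid[-1])
    gap = 2.0 * config.depression.tau_E  # efficacy recovers between sessions
    if profiles.shape[1] < 2 or session_len < spec.burst_duration:
        raise ValueError("template profiles shorter than one burst")

    ss = np.random.SeedSequence(seed)
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])
    probe_seed_rng = np.random.default_rng(ss.spawn(1)[0])

    results: list[dict] = []

    def record_checkpoint(session_idx):
        peaks, _ = _probe(topo, state.W, plastic, config,
                          int(probe_seed_rng.integers(2 ** 31)))
        entry = {
            "session": session_idx,
            "pool_peaks": peaks,
            "pair_means": _pair_means(state.W, plastic, pools),
        }
        if keep_checkpoint_weights:
            entry["W"] = state.W.copy()
        results.append(entry)

    t0 = 0.0
    for s in range(sessions + 1):
        if s in checkpoints:
            record_checkpoint(s)
        if s == sessions:
            break
        order = shuffle_rng.permutation(n_pools) if shuffle else np.arange(n_pools)
        all_t, all_id = [], []
        for k, pool in enumerate(pools):
            profile = profiles[order[k]]
            trains = gen_poisson_train(
                (t_grid, profile), session_len, pool.size,
                np.random.default_rng(ss.spawn(1)[0]))
            for j, tr in enumerate(trains):
                if tr.size:
                    all_t.append(tr + t0)
                    all_id.append(np.full(tr.size, pool.start + j, dtype=np.int64))
        if all_t:
            t_all = np.concatenate(all_t)
            id_all = np.concatenate(all_id)
            idx = np.argsort(t_all, kind="stable")
            process_spike_train(state, t_all[idx], id_all[idx], stdp)
        t0 += session_len + gap

    if sessions not in checkpoints:
        record_checkpoint(sessions)

    return LearningResult(
        pool_ids=[p.id for p in pools], checkpoints=results,
        final_W=state.W, final_pair_means=_pair_means(state.W, plastic, pools),
        manifest={"seed": int(seed), "sessions": sessions, "shuffle": bool(shuffle),
                  "n_pools": n_pools, "config_hash": config.config_hash()})


def propagation_test(config: ModelConfig, learned: LearningResult,
                     topology=None, seed=0, duration=2200.0):
    """Motor-style propagation probe on a learned network.

    Rebuilds the learning topology, installs the learned inter-pool weights,
    declares the pool order as a chain and runs the full motor protocol
    (pool-1 intention burst + sensory gating).  Returns the SimulationResult.
    """
    topo = topology or build_learning_network(
        config, n_pools=len(learned.pool_ids), w_init_max=config.stdp.w_init_max)
    n = topo.n_neurons
    plastic = np.zeros((n, n), dtype=bool)
    coo = topo.W_inter.tocoo()
    plastic[coo.row, coo.col] = True
    W_inter = sp.csr_matrix(np.where(plastic, learned.final_W, 0.0))
    chain = Chain(id="learned", pool_sequence=list(learned.pool_ids))
    topo2 = NetworkTopology(
        pools=topo.pools, chains=[chain], W_local_E=topo.W_local_E,
        W_local_I=topo.W_local_I, W_inter=W_inter, rng_seed=topo.rng_seed,
        ref_pool_size=topo.ref_pool_size)
    scenario = TaskScenario(mode="motor", chains_active=["learned"],
                            act_duration=config.engine.act_duration)
    return run_motor_task(topo2, scenario, config, duration=duration, seed=seed)
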