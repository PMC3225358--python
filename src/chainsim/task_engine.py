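"""Closed-loop task orchestration: motor execution, blind (ambiguous) goal
disambiguation, and visual action recognition.

The engine advances the whole network with vectorized Euler steps and, at
every analysis bin (20 ms), inspects per-pool population rates to detect
pool activations (the avalanche-like transition to a coherent burst).  Task
protocols react to activations by scheduling the external signals that gate
propagation:

* motor mode — an intention burst from PFC ignites the first pool; each
  activated pool receives corollary discharge for the duration of its motor
  act, and at act completion sensory feedback is delivered to the next pool.
  Chain input alone is subthreshold: the next pool ignites only when chain
  input and sensory input coincide.
* ambiguous (blind) mode — both goal chains start in parallel; the sensory
  event that gates the final transition is delivered only to the cued chain
  once the object has been recognized at grasp completion, so activity dies
  out in the other chain.
* visual mode — the motor gate is closed (no motor output events); a tonic
  subthreshold PFC prediction primes the hypothesized chain and stepwise
  observation events drive propagation; a mismatch between predicted and
  observed act halts the chain.

The total input to a chain neuron decomposes into chain input from the
previous pool, sensory input, prefrontal input (first pools only), motor
corollary input and local recurrent input; the engine can record this
decomposition per pool and bin (``record_currents=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network_topology import NetworkTopology, Pool, build_pool
from .neuron_dynamics import mg_block
from .stimulus_generator import StimulusEvent, realize_event_trains

__all__ = [
    "ConfigurationError",
    "TaskScenario",
    "PoolInputs",
    "SimulationResult",
    "NetworkSimulator",
    "detect_pool_activation",
    "run_motor_task",
    "run_ambiguous_task",
    "run_visual_task",
    "calibrate_pool_regime",
]


class ConfigurationError(ValueError):
    """A task scenario violates the protocol's contract."""


@dataclass
class TaskScenario:
    """Declarative description of one simulation protocol."""

    mode: str  # motor | ambiguous | visual
    chains_active: list[str]
    cue: str | None = None  # goal label of the cued chain (ambiguous mode)
    act_duration: float = 300.0  # ms
    motor_gate: str = "open"  # open | closed
    sensory_feedback: bool = True
    disambiguation: bool = True
    disambiguation_onset: float | None = None  # optional explicit onset (ms)
    observed_acts: list[str] | None = None  # visual mode: acts actually observed

    def validate(self) -> None:
        if self.mode not in ("motor", "ambiguous", "visual"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "visual" and self.motor_gate != "closed":
            raise ConfigurationError("visual mode requires motor_gate='closed'")
        if self.mode == "ambiguous" and len(self.chains_active) < 2:
            raise ConfigurationError("ambiguous mode needs at least two active chains")
        if self.mode == "motor" and len(self.chains_active) != 1:
            raise ConfigurationError("motor mode drives exactly one chain")
        if self.act_duration <= 0:
            raise ConfigurationError("act_duration must be positive")


@dataclass
class PoolInputs:
    """Mean per-neuron current components of one pool in one bin (pA)."""

    I_prev: float  # from the preceding chain pool
    I_sens: float
    I_PFC: float
    I_mot: float
    I_local: float  # recurrent in-pool (excitatory + inhibitory)

    @property
    def total(self) -> float:
        return self.I_prev + self.I_sens + self.I_PFC + self.I_mot + self.I_local


@dataclass
class SimulationResult:
    """Raster, rate traces, burst annotations and outcome of one run."""

    spike_times: np.ndarray  # ms
    spike_neurons: np.ndarray
    spike_pools: np.ndarray  # pool index per spike
    pool_ids: list[str]
    pool_rates: np.ndarray  # (n_bins, n_pools), Hz
    bin_ms: float
    bursts: dict  # pool id -> list of burst dicts
    activations: dict  # pool id -> detection time (ms)
    outcome: dict  # {"completed": [...], "halted": {chain: pools_activated}}
    motor_events: list  # [(t_ms, pool_id, motor_act), ...]
    manifest: dict
    pool_inputs: dict | None = None  # pool id -> list[PoolInputs] per bin

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def raster_df(self):
        import pandas as pd

        return pd.DataFrame({
            "neuron_id": self.spike_neurons.astype(np.int64),
            "pool_id": [self.pool_ids[k] for k in self.spike_pools],
            "t_ms": self.spike_times,
        })

    def rates_df(self):
        import pandas as pd

        t = np.arange(self.pool_rates.shape[0]) * self.bin_ms
        df = pd.DataFrame(self.pool_rates, columns=self.pool_ids)
        df.insert(0, "t_ms", t)
        return df


# ---------------------------------------------------------------------------
# core vectorized simulator


class NetworkSimulator:
    """Fixed-step Euler simulator of the whole network.

    One gating variable per presynaptic neuron and receptor type carries
    transmission to all its targets (transmitter pulses from successive
    spikes extend, not stack, the 1 ms pulse window).  External input uses
    one gating variable per neuron and routing channel (pfc / sensory /
    motor), so the Eq-1-style source decomposition stays reportable.
    """

    CHANNELS = ("pfc", "sensory", "motor")

    def __init__(self, topology: NetworkTopology, config, seed: int,
                 record_currents: bool = False):
        self.topology = topology
        self.config = config
        self.dt = config.engine.dt
        self.bin_ms = config.engine.bin_ms
        self.record_currents = record_currents
        n = topology.n_neurons
        self.n = n

        nr = config.neuron
        self._V_L, self._V_thr = nr.V_L, nr.V_thr
        self._V_reset, self._g_L = nr.V_reset, nr.g_L
        self._tau_ref = nr.tau_ref
        self._inv_Cm = 1.0 / (1000.0 * nr.C_m)  # pA -> mV/ms

        rec = config.receptors
        self._ampa = rec["AMPA_rec"]
        self._nmda = rec["NMDA"]
        self._gaba = rec["GABA"]
        self._ext = rec["AMPA_ext"]

        self.W_E = topology.W_local_E.tocsr()
        self.W_X = topology.W_inter.tocsr()
        self.W_I = topology.W_local_I.tocsr()

        dep = config.depression
        self._dep_on = dep.enabled
        self._dep_u, self._dep_tauE = dep.u, dep.tau_E
        self._chain_ag = config.synapse.chain_ampa_gain
        self._chain_ng = config.synapse.chain_nmda_gain

        self.V = np.full(n, nr.V_L)
        self.refr = np.zeros(n)
        self.E = np.ones(n)  # presynaptic transmission efficacy
        self.s_ampa = np.zeros(n)
        self.s_nmda = np.zeros(n)
        self.s_gaba = np.zeros(n)
        self.pulse = np.zeros(n)  # remaining transmitter time after own spikes
        # external gating: one row per routing channel (pfc, sensory, motor)
        self.s_ext = np.zeros((3, n))
        self.ext_pulse = np.zeros((3, n))
        self._chan_row = {c: k for k, c in enumerate(self.CHANNELS)}
        self._ext_w = np.array([
            config.stimulus.pfc_weight,
            config.stimulus.sensory_weight,
            config.stimulus.motor_weight,
        ])
        self._mg_fac = self._nmda.Mg / 3.57

        self._eff2 = np.zeros((n, 2))
        self._zeros = np.zeros(n)
        self._has_inter = self.W_X.nnz > 0

        self.t = 0.0
        self._step_i = 0
        self._pending = []  # scheduled external spike chunks
        self._seed_rng = np.random.default_rng(np.random.SeedSequence(seed))

        self._pool_starts = np.array([p.start for p in topology.pools])
        self._pool_sizes = np.array([p.size for p in topology.pools])
        self._pool_of = topology.pool_of_neuron
        self._bin_counts = np.zeros(len(topology.pools))
        self.rate_history: list[np.ndarray] = []
        self._spike_t: list[np.ndarray] = []
        self._spike_id: list[np.ndarray] = []
        if record_currents:
            self._cur_acc = {k: np.zeros(len(topology.pools)) for k in
                             ("local_E", "local_I", "inter", "pfc", "sensory", "motor")}
            self.current_history: list[dict] = []

    # -- scheduling -------------------------------------------------------

    def next_seed(self) -> int:
        return int(self._seed_rng.integers(2 ** 31))

    def schedule_event(self, event: StimulusEvent) -> None:
        """Realize an event into spike trains and queue its deliveries."""
        pool = self.topology.pool(event.target_pool)
        ids, trains = realize_event_trains(event, pool)
        t_all = np.concatenate(trains)
        id_all = np.concatenate([np.full(tr.size, i, dtype=np.int64)
                                 for i, tr in zip(ids, trains)])
        order = np.argsort(t_all, kind="stable")
        self._pending.append({
            "t": t_all[order], "id": id_all[order].astype(np.int64),
            "ptr": 0, "channel": event.channel,
        })

    # -- stepping ---------------------------------------------------------

    def _deliver_external(self, t_hi: float) -> None:
        T_dur = self._ext.T_dur
        done = False
        for chunk in self._pending:
            p = chunk["ptr"]
            tarr = chunk["t"]
            q = int(np.searchsorted(tarr, t_hi, side="left")) if p < tarr.size else p
            if q > p:
                row = self._chan_row[chunk["channel"]]
                self.ext_pulse[row, chunk["id"][p:q]] = T_dur
                chunk["ptr"] = q
            done = done or chunk["ptr"] >= tarr.size
        if done:
            self._pending = [c for c in self._pending if c["ptr"] < c["t"].size]

    def step(self) -> np.ndarray:
        """Advance one Euler step; returns the indices of neurons that spiked."""
        dt = self.dt
        self._deliver_external(self.t + dt)

        # receptor gating (first-order kinetics, transmitter pulses square)
        T_on = (self.pulse > 0).astype(float)
        a, b = self._ampa.alpha * self._ampa.T_amp, self._ampa.beta
        self.s_ampa += dt * a * T_on * (1.0 - self.s_ampa) - dt * b * self.s_ampa
        a, b = self._nmda.alpha * self._nmda.T_amp, self._nmda.beta
        self.s_nmda += dt * a * T_on * (1.0 - self.s_nmda) - dt * b * self.s_nmda
        a, b = self._gaba.alpha * self._gaba.T_amp, self._gaba.beta
        self.s_gaba += dt * a * T_on * (1.0 - self.s_gaba) - dt * b * self.s_gaba
        self.pulse -= dt
        a, b = self._ext.alpha * self._ext.T_amp, self._ext.beta
        on = (self.ext_pulse > 0).astype(float)
        self.s_ext += dt * a * on * (1.0 - self.s_ext) - dt * b * self.s_ext
        self.ext_pulse -= dt

        # synaptic currents, explicit in V (Jahr-Stevens block inlined)
        V = self.V
        self._eff2[:, 0] = self.s_ampa
        self._eff2[:, 1] = self.s_nmda
        if self._dep_on:
            self._eff2 *= self.E[:, None]
        B = 1.0 / (1.0 + self._mg_fac * np.exp(-0.062 * V))
        loc = self.W_E @ self._eff2
        loc_a, loc_n = loc[:, 0], loc[:, 1]
        if self._has_inter:
            inter = self.W_X @ self._eff2
            int_a, int_n = inter[:, 0], inter[:, 1]
        else:
            int_a = int_n = self._zeros
        gaba = self.W_I @ self.s_gaba
        I_loc_E = -(self._ampa.g_max * loc_a + self._nmda.g_max * B * loc_n) * V
        I_int = -(self._ampa.g_max * self._chain_ag * int_a
                  + self._nmda.g_max * self._chain_ng * B * int_n) * V
        I_loc_I = -self._gaba.g_max * gaba * (V - self._gaba.E_rev)
        g_ext = self._ext.g_max
        ext_drive = self._ext_w @ self.s_ext  # summed weighted channels
        I_ext_all = -g_ext * ext_drive * V
        I = I_loc_E + I_int + I_loc_I + I_ext_all

        if self.record_currents:
            idx = self._pool_starts
            gV = -g_ext * V
            for key, vec in (("local_E", I_loc_E), ("local_I", I_loc_I),
                             ("inter", I_int),
                             ("pfc", gV * self._ext_w[0] * self.s_ext[0]),
                             ("sensory", gV * self._ext_w[1] * self.s_ext[1]),
                             ("motor", gV * self._ext_w[2] * self.s_ext[2])):
                self._cur_acc[key] += np.add.reduceat(vec, idx)

        # membrane update with refractory clamp
        active = self.refr <= 0
        dV = dt * (-self._g_L * (V - self._V_L) + I) * self._inv_Cm
        V += np.where(active, dV, 0.0)
        V[~active] = self._V_reset
        self.refr = np.maximum(self.refr - dt, 0.0)

        spiked = np.flatnonzero(active & (V >= self._V_thr))
        if spiked.size:
            V[spiked] = self._V_reset
            self.refr[spiked] = self._tau_ref
            self.pulse[spiked] = self._ampa.T_dur
            if self._dep_on:
                self.E[spiked] *= (1.0 - self._dep_u)
            self._spike_t.append(np.full(spiked.size, self.t + dt))
            self._spike_id.append(spiked.copy())
            np.add.at(self._bin_counts, self._pool_of[spiked], 1.0)
        if self._dep_on:
            self.E += dt * (1.0 - self.E) / self._dep_tauE

        self.t += dt
        self._step_i += 1
        return spiked

    def run(self, t_end: float, bin_callback=None) -> None:
        """Run until ``t_end``, invoking ``bin_callback(bin_idx, t, rates)``
        after every completed analysis bin."""
        steps_per_bin = max(1, int(round(self.bin_ms / self.dt)))
        while self.t < t_end - 1e-9:
            self.step()
            if self._step_i % steps_per_bin == 0:
                rates = 1000.0 * self._bin_counts / (self._pool_sizes * self.bin_ms)
                self.rate_history.append(rates)
                self._bin_counts[:] = 0.0
                if self.record_currents:
                    nsteps = steps_per_bin
                    snap = {k: v / (nsteps * self._pool_sizes)
                            for k, v in self._cur_acc.items()}
                    self.current_history.append(snap)
                    for v in self._cur_acc.values():
                        v[:] = 0.0
                if bin_callback is not None:
                    bin_callback(len(self.rate_history) - 1, self.t, rates)

    # -- results ----------------------------------------------------------

    def collect_spikes(self):
        if self._spike_t:
            t = np.concatenate(self._spike_t)
            ids = np.concatenate(self._spike_id)
        else:
            t, ids = np.empty(0), np.empty(0, np.int64)
        return t, ids

    def pool_inputs(self) -> dict:
        """Per-pool, per-bin mean current decomposition (requires recording)."""
        if not self.record_currents:
            raise RuntimeError("simulator was built with record_currents=False")
        out = {}
        for k, p in enumerate(self.topology.pools):
            out[p.id] = [
                PoolInputs(I_prev=snap["inter"][k], I_sens=snap["sensory"][k],
                           I_PFC=snap["pfc"][k], I_mot=snap["motor"][k],
                           I_local=snap["local_E"][k] + snap["local_I"][k])
                for snap in self.current_history
            ]
        return out


# ---------------------------------------------------------------------------
# burst detection


def detect_pool_activation(rate_trace, bin_ms, floor_hz=20.0, rel=0.5,
                           smooth_bins=3, min_bins=2):
    """Annotate population bursts in a binned rate trace.

    Bursts are maximal runs where the (moving-average smoothed) rate is at
    least ``rel`` times the trace peak and above the absolute floor.  Runs
    shorter than ``min_bins`` are discarded.  Returns a list of dicts with
    onset/offset (ms), peak rate (Hz) and peak time.
    """
    r = np.asarray(rate_trace, dtype=float)
    if r.size == 0 or not np.any(r > 0):
        return []
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        r = np.convolve(r, kernel, mode="same")
    peak = float(r.max())
    thr = max(floor_hz, rel * peak)
    above = r >= thr
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    bursts = []
    for s, e in zip(starts, ends):
        if e - s < min_bins:
            continue
        seg = r[s:e]
        k = int(np.argmax(seg))
        bursts.append({
            "onset_ms": s * bin_ms,
            "offset_ms": e * bin_ms,
            "peak_hz": float(seg[k]),
            "peak_t_ms": (s + k) * bin_ms,
        })
    return bursts


# ---------------------------------------------------------------------------
# task protocols


class _ChainTracker:
    """Per-chain stage machine driven by pool activations."""

    def __init__(self, chain, topology):
        self.chain = chain
        self.pool_ids = list(chain.pool_sequence)
        self.stage = 0
        self.activation_times: dict[str, float] = {}

    @property
    def complete(self) -> bool:
        return self.stage >= len(self.pool_ids)

    def current_pool(self):
        return self.pool_ids[self.stage] if not self.complete else None


def _finalize(sim: NetworkSimulator, scenario, trackers, seed, extra_manifest=None,
              motor_events=None):
    topo = sim.topology
    t, ids = sim.collect_spikes()
    rates = np.array(sim.rate_history) if sim.rate_history \
        else np.zeros((0, len(topo.pools)))
    pool_ids = [p.id for p in topo.pools]
    floor = sim.config.engine.activation_floor_hz
    bursts = {pid: detect_pool_activation(rates[:, k], sim.bin_ms, floor)
              for k, pid in enumerate(pool_ids)}
    completed = [tr.chain.id for tr in trackers if tr.complete]
    halted = {tr.chain.id: tr.stage for tr in trackers if not tr.complete}
    activations = {}
    for tr in trackers:
        activations.update(tr.activation_times)
    manifest = {
        "seed": int(seed),
        "config_hash": sim.config.config_hash(),
        "mode": scenario.mode if scenario is not None else "calibration",
        "duration_ms": float(sim.t),
        "topology_hash": topo.structure_hash(),
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    return SimulationResult(
        spike_times=t, spike_neurons=ids,
        spike_pools=topo.pool_of_neuron[ids] if ids.size else np.empty(0, np.int64),
        pool_ids=pool_ids, pool_rates=rates, bin_ms=sim.bin_ms,
        bursts=bursts, activations=activations,
        outcome={"completed": completed, "halted": halted},
        motor_events=motor_events or [], manifest=manifest,
        pool_inputs=sim.pool_inputs() if sim.record_currents else None)


def _run_chain_protocol(topology, scenario, config, duration, seed,
                        record_currents=False):
    """Shared machinery of the motor and ambiguous protocols."""
    scenario.validate()
    stim = config.stimulus
    eng = config.engine
    sim = NetworkSimulator(topology, config, seed, record_currents=record_currents)
    trackers = [_ChainTracker(topology.chain(cid), topology)
                for cid in scenario.chains_active]
    motor_events: list[tuple] = []
    final_stage = {tr.chain.id: len(tr.pool_ids) - 1 for tr in trackers}

    for tr in trackers:
        sim.schedule_event(StimulusEvent(
            target_pool=tr.pool_ids[0], target_fraction=stim.intention_fraction,
            onset=0.0, duration=2.0 * stim.intention_width, rate_profile="bell",
            peak_rate=stim.intention_rate, channel="pfc", seed=sim.next_seed(),
            width=stim.intention_width))

    def deliver_sensory(pool_id, onset):
        sim.schedule_event(StimulusEvent(
            target_pool=pool_id, target_fraction=stim.feedback_fraction,
            onset=onset, duration=stim.feedback_duration, rate_profile="constant",
            peak_rate=stim.feedback_rate, channel="sensory", seed=sim.next_seed()))

    pool_index = {p.id: k for k, p in enumerate(topology.pools)}

    def on_bin(bin_idx, t, rates):
        for tr in trackers:
            pid = tr.current_pool()
            if pid is None:
                continue
            if rates[pool_index[pid]] < eng.activation_floor_hz:
                continue
            # pool activation detected
            tr.activation_times[pid] = t
            pool = topology.pool(pid)
            if scenario.motor_gate == "open":
                motor_events.append((t, pid, pool.motor_act))
            # corollary discharge sustains the pool while its act executes
            # (extended by the coarticulation overlap so successive bursts
            # overlap as in the recordings)
            sim.schedule_event(StimulusEvent(
                target_pool=pid, target_fraction=stim.feedback_fraction,
                onset=t, duration=scenario.act_duration + eng.overlap,
                rate_profile="constant", peak_rate=stim.feedback_rate,
                channel="motor", seed=sim.next_seed()))
            stage = tr.stage
            if stage < len(tr.pool_ids) - 1 and scenario.sensory_feedback:
                completion = t + scenario.act_duration
                next_pid = tr.pool_ids[stage + 1]
                is_final_transition = (stage + 1 == final_stage[tr.chain.id])
                if scenario.mode == "ambiguous" and is_final_transition:
                    if scenario.disambiguation and tr.chain.id == scenario.cue:
                        onset = scenario.disambiguation_onset
                        if onset is None:
                            onset = completion
                        elif onset < completion - 1e-9:
                            raise ConfigurationError(
                                "disambiguation event scheduled before grasp completion")
                        deliver_sensory(next_pid, onset)
                else:
                    deliver_sensory(next_pid, completion)
            tr.stage += 1

    sim.run(duration, on_bin)
    return _finalize(sim, scenario, trackers, seed, motor_events=motor_events)


def run_motor_task(topology, scenario, config, duration=2500.0, seed=0,
                   record_currents=False):
    """Simulation of overt action execution along one goal chain.

    The intention burst ignites the first pool at t=0; propagation then
    follows the activation/feedback loop.  If no pool activates within
    ``duration`` the outcome reports the chain as halted (no exception).
    """
    if scenario.mode != "motor":
        raise ConfigurationError("run_motor_task requires scenario.mode='motor'")
    return _run_chain_protocol(topology, scenario, config, duration, seed,
                               record_currents)


def run_ambiguous_task(topology, scenario, config, duration=2500.0, seed=0,
                       record_currents=False):
    """Blind task: both chains run in parallel until sensory disambiguation.

    Pools up to the grasping step burst in both chains; the final sensory
    event reaches only the cued chain, whose last pool completes while the
    other chain's final pool stays silent.
    """
    if scenario.mode != "ambiguous":
        raise ConfigurationError("run_ambiguous_task requires scenario.mode='ambiguous'")
    if scenario.cue is not None and scenario.disambiguation \
            and scenario.cue not in scenario.chains_active:
        raise ConfigurationError(f"cue {scenario.cue!r} does not name an active chain")
    return _run_chain_protocol(topology, scenario, config, duration, seed,
                               record_currents)


def run_visual_task(topology, scenario, config, duration=2500.0, seed=0,
                    record_currents=False):
    """Action recognition: propagation driven by observation, no motor output.

    A tonic subthreshold PFC prediction primes the hypothesized chain's
    first pool; observation events (hand configuration / motion) arrive one
    per observed act and gate stepwise propagation.  When the observed act
    differs from the chain's expected act, no event is delivered to the
    expected pool and propagation halts there.
    """
    if scenario.mode != "visual":
        raise ConfigurationError("run_visual_task requires scenario.mode='visual'")
    scenario.validate()
    stim = config.stimulus
    eng = config.engine
    sim = NetworkSimulator(topology, config, seed, record_currents=record_currents)
    chain = topology.chain(scenario.chains_active[0])
    tracker = _ChainTracker(chain, topology)
    expected_acts = [topology.pool(pid).motor_act for pid in chain.pool_sequence]
    observed = scenario.observed_acts if scenario.observed_acts is not None \
        else list(expected_acts)

    # tonic prediction input: subthreshold, first pool only
    sim.schedule_event(StimulusEvent(
        target_pool=chain.pool_sequence[0], target_fraction=stim.intention_fraction,
        onset=0.0, duration=duration, rate_profile="constant",
        peak_rate=stim.visual_tonic_rate, channel="pfc", seed=sim.next_seed()))

    # observation events follow the observed agent's timeline
    for k, act in enumerate(observed):
        if k >= len(expected_acts):
            break
        if act != expected_acts[k]:
            continue  # mismatch: the expected pool receives no visual evidence
        sim.schedule_event(StimulusEvent(
            target_pool=chain.pool_sequence[k], target_fraction=stim.feedback_fraction,
            onset=k * scenario.act_duration,
            duration=scenario.act_duration + eng.overlap,
            rate_profile="constant", peak_rate=stim.feedback_rate,
            channel="sensory", seed=sim.next_seed()))

    pool_index = {p.id: k for k, p in enumerate(topology.pools)}

    def on_bin(bin_idx, t, rates):
        pid = tracker.current_pool()
        if pid is None:
            return
        if rates[pool_index[pid]] >= eng.activation_floor_hz:
            tracker.activation_times[pid] = t
            tracker.stage += 1

    sim.run(duration, on_bin)
    return _finalize(sim, scenario, [tracker], seed, motor_events=[])


# ---------------------------------------------------------------------------
# excitation/inhibition regime calibration


def _single_pool_topology(config, w_E, w_I, seed):
    net = config.network
    syn = config.synapse
    pool, tE, tI = build_pool(
        net.pool_size, syn.inh_fraction, syn.p_intra, w_E, w_I, seed,
        pool_id="probe", motor_act="probe", ref_pool_size=net.ref_pool_size)
    n = net.pool_size

    def mat(trip):
        rows, cols, vals = trip
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    empty = sp.csr_matrix((n, n))
    return NetworkTopology(pools=[pool], chains=[], W_local_E=mat(tE),
                           W_local_I=mat(tI), W_inter=empty, rng_seed=seed,
                           ref_pool_size=net.ref_pool_size)


def calibrate_pool_regime(config, w_E_grid, w_I_grid, seed=0, duration=1200.0,
                          probe_onset=100.0):
    """Classify single-pool responses over a (w_E, w_I) grid.

    Each grid point stimulates an isolated pool with the standard intention
    burst and classifies the response: ``silent`` (no population burst),
    ``transient`` (burst that returns to near-zero rate) or ``sustained``
    (rate still above the activation floor at the end of the window).
    Returns ``(labels, results)`` where ``labels[i, j]`` corresponds to
    ``(w_E_grid[i], w_I_grid[j])``.
    """
    w_E_grid = np.asarray(w_E_grid, dtype=float)
    w_I_grid = np.asarray(w_I_grid, dtype=float)
    if np.any(w_E_grid < 0) or np.any(w_I_grid < 0):
        raise ValueError("weight grids must be non-negative")
    stim = config.stimulus
    eng = config.engine
    labels = np.empty((w_E_grid.size, w_I_grid.size), dtype=object)
    details = {}
    for i, wE in enumerate(w_E_grid):
        for j, wI in enumerate(w_I_grid):
            topo = _single_pool_topology(config, wE, wI, seed)
            sim = NetworkSimulator(topo, config, seed)
            sim.schedule_event(StimulusEvent(
                target_pool="probe", target_fraction=stim.intention_fraction,
                onset=probe_onset, duration=2.0 * stim.intention_width,
                rate_profile="bell", peak_rate=stim.intention_rate,
                channel="pfc", seed=sim.next_seed(), width=stim.intention_width))
            sim.run(duration)
            rates = np.array(sim.rate_history)[:, 0]
            bursts = detect_pool_activation(rates, eng.bin_ms,
                                            eng.activation_floor_hz)
            tail = rates[-max(1, int(150 / eng.bin_ms)):]
            if not bursts:
                label = "silent"
            elif tail.mean() >= eng.activation_floor_hz:
                label = "sustained"
            else:
                label = "transient"
            labels[i, j] = label
            details[(float(wE), float(wI))] = {
                "label": label, "peak_hz": float(rates.max()),
                "tail_hz": float(tail.mean()),
            }
    return labels, details
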