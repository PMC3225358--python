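# chainsim

A spiking-network simulator of goal-directed **neuronal chains** in the
inferior parietal lobe (IPL).  Parietal motor and mirror neurons that code
elementary motor acts (reaching, shaping, grasping, bringing to the mouth,
placing) fire differently depending on the *final goal* of the action the
act is embedded in.  `chainsim` models the circuit organization proposed to
explain this: pools of neurons coding subsequent motor acts are wired into
goal-specific unidirectional chains, and an activity burst propagates along
the chain selected by a prefrontal "intention" signal, gated at every step
by sensory and motor-corollary input.  The same chains, driven by visual
observation events instead of motor signals and with the motor output gate
closed, implement mirror-neuron-style action recognition; an STDP rule with
short-term synaptic efficacy hardwires new chains from sequential activity.

The package is aimed at computational neuroscientists who want to simulate,
probe and extend the chain hypothesis: every constant is exposed in a YAML
config, all signals are generated from seeds, and results serialize to
plain CSV/JSON.

## Model core

Each neuron is a conductance-based leaky integrate-and-fire unit,

```
C_m dV/dt = -g_L (V - V_L) + I_syn(t),
```

with spike/reset at `V_thr -> V_reset` and absolute refractory period
`tau_ref`.  Synaptic current decomposes into external AMPA, recurrent
AMPA + NMDA, and GABA_A components, each following the kinetic form

```
I_X = g_X (V - E_X) * sum_j w_j s_j,     ds/dt = alpha [T] (1 - s) - beta s,
```

with a square transmitter pulse `[T]` per presynaptic spike and, for NMDA,
the voltage-dependent magnesium block `B(V) = 1/(1 + [Mg]/3.57 e^{-0.062V})`.
Pools (500 units, 25% inhibitory, 20% intra-pool fan-in) respond to
suprathreshold input with an avalanche-like transient burst, terminated by
short-term presynaptic depression (`E -> E(1-u)` per spike, recovery
`tau_E`).  Inter-pool chain links are NMDA-dominated, so a pool's chain
input integrates its predecessor's recent firing and, through `B(V)`, is
strongest exactly when coincident sensory input already depolarizes the
target — chain input alone stays subthreshold, implementing the gating rule
that propagation requires two converging sources.

Plasticity follows `dw_ij = eta * E_j(t) * K(t_post - t_pre)` with the
asymmetric exponential STDP kernel `K` (`+A_+ e^{-dt/tau_+}` /
`-A_- e^{dt/tau_-}`, amplitudes 1) and the same activity-dependent efficacy
`E_j` attached to the presynaptic neuron.

## Worked example

Blind (ambiguous) task: the target object is hidden, so both the *eat* and
the *place* chain start in parallel; at grasp completion the object is
recognized and sensory input reaches only the cued chain's final pool.

```python
import chainsim as cs

cfg = cs.test_profile_config(seed=1)          # 100-neuron pools, weights rescaled
topo = cs.build_network(cfg)                  # two four-pool chains: eat, place
scenario = cs.TaskScenario(mode="ambiguous",
                           chains_active=["eat", "place"], cue="eat")
result = cs.run_ambiguous_task(topo, scenario, cfg, duration=2500.0, seed=1)

print("outcome:", result.outcome)
for pid in topo.chain("eat").pool_sequence + topo.chain("place").pool_sequence:
    bursts = result.bursts[pid]
    ...
```

prints

```
outcome: {'completed': ['eat'], 'halted': {'place': 3}}
  eat:reaching                 120-180 ms, peak 156 Hz
  eat:shaping                  440-520 ms, peak 192 Hz
  eat:grasping                 760-840 ms, peak 192 Hz
  eat:bringing_to_mouth        1120-1180 ms, peak 202 Hz
  place:reaching               80-140 ms, peak 186 Hz
  place:shaping                420-480 ms, peak 190 Hz
  place:grasping               760-840 ms, peak 194 Hz
  place:placing                silent
```

Both chains burst in parallel through grasping (~340 ms stride = 300 ms
act duration + detection latency); after disambiguation the eat chain
completes while the place chain's final pool stays silent — the signature
recorded in IPL neurons.

A CLI wraps the same protocols:

```sh
chainsim simulate-motor  --seed 1 --out out/motor
chainsim simulate-blind  --cue eat --seed 1 --out out/blind
chainsim simulate-visual --observed reaching,shaping,grasping,placing --seed 1 --out out/visual
chainsim calibrate       --seed 1 --out out/regime
chainsim learn-chain     --sessions 150 --checkpoints 0,50,100,150 --seed 1 --out out/learn
```

Each run writes `raster.csv`, `rates.csv` (20 ms bins), `bursts.json` and a
`manifest.json` with the seed and config hash.

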