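# Methods

## Model overview

`chainsim` simulates a two-dimensional sheet of spiking neurons organized
into local pools, with pools wired into goal-specific feedforward chains.
The simulation has three interacting layers:

1. **Neuron and synapse dynamics** — conductance-based leaky
   integrate-and-fire neurons with kinetic AMPA/NMDA/GABA_A receptor
   channels, advanced by explicit first-order Euler steps.
2. **Network structure** — pools with exact-fan-in local wiring and
   unidirectional, NMDA-dominated inter-pool links.
3. **Task orchestration** — closed-loop protocols in which pool
   activations trigger simulated motor-corollary and sensory events that
   gate further propagation.

## Neuron and synapse model

Below threshold the membrane obeys `C_m dV/dt = -g_L (V - V_L) + I_syn`;
reaching `V_thr` emits a spike, resets `V` to `V_reset` and clamps it there
for `tau_ref`.  Defaults (all exposed in the config, units fixed as mV, ms,
nF, nS, mM): `V_L = -70`, `V_thr = -50`, `V_reset = -60`, `C_m = 0.5 nF`,
`g_L = 25 nS` (so `tau_m = 20 ms`), `tau_ref = 2 ms`.

Receptor channels follow first-order kinetics
`ds/dt = alpha [T](1-s) - beta s`, with one gating variable per presynaptic
neuron and receptor type; each presynaptic spike opens a square transmitter
pulse (`[T] = 1 mM` for 1 ms) whose window is extended, not stacked, by
further spikes.  Kinetic constants are standard kinetic-synapse values:
AMPA `alpha = 1.1 /mM/ms`, `beta = 0.19 /ms`, `E = 0 mV`; NMDA
`alpha = 0.072`, `beta = 0.0066`, `E = 0`; GABA_A `alpha = 5.0`,
`beta = 0.18`, `E = -70 mV`.  The NMDA magnesium block is the
Jahr–Stevens form `B(V) = 1/(1 + [Mg]/3.57 mM * e^{-0.062 V})` with
`[Mg] = 1 mM`.  Currents are evaluated at the step-start voltage (fully
explicit scheme); the default step is `dt = 0.1 ms`.

Base conductances are effective per-connection maxima (AMPA 1 nS, NMDA
0.15 nS, GABA 3 nS, external AMPA 1 nS); dimensionless weights multiply
them.  The GABA conductance exceeds the AMPA value because an inhibitory
synapse must offset a ~3x larger excitatory fan-in and a ~4x larger
excitatory driving force at burst voltages; with equal conductances no
biologically reasonable `w_I` balances a pool.

## Short-term efficacy on transmission

Every excitatory neuron carries an activity-dependent efficacy `E` that
multiplies the drive of all its recurrent synapses: `E <- E (1 - u)` at
each of its spikes and `dE/dt = (1 - E)/tau_E` otherwise (`u = 0.1`,
`tau_E = 300 ms`).  This is the same depression-with-recovery process the
plasticity rule uses, applied to transmission, and it is what terminates a
pool's avalanche: with static synapses, a recurrent gain large enough to
ignite a whole pool from a 20%-targeted stimulus is also large enough to
sustain firing indefinitely, except on a measure-zero boundary.  With
depression the active state self-extinguishes once `E` collapses, yielding
the transient bell-shaped population bursts the protocols rely on, while a
genuinely non-transient (sustained) regime still exists at sufficiently
large excitatory weights — as the regime-map sweep verifies.

## Network structure

Pools have 500 neurons by default, 25% randomly chosen inhibitory.  Each
neuron receives connections from exactly `round(0.20 * size)` distinct
in-pool partners (exact fan-in rather than Bernoulli edges, so degree
counts are exact); excitatory partners carry weight `w_E = 4.0`, inhibitory
`w_I = 2.0`.  Inhibitory neurons never project outside their pool.

Chains connect consecutive pools forward only.  Each target neuron draws
connections from exactly `round(0.10 * n_excitatory)` excitatory neurons of
the preceding pool (`w_chain = 8.0`).  Exact fan-in here is deliberate: with
Bernoulli wiring the Binomial fan-in tail produces target neurons whose
chain input alone is suprathreshold, which breaks the gating rule at the
margins.

Chain links are routed through NMDA receptors with an effective conductance
of ~1 nS (`chain_nmda_gain = 6.67` on the 0.15 nS base) plus a small AMPA
component (`chain_ampa_gain = 0.04`).  Two properties motivate this.
First, NMDA gating integrates presynaptic firing over ~70 ms, so the chain
input a target pool receives is comparable during its predecessor's brief
ignition transient and its sustained act phase — with AMPA-routed chains the
ignition transient dominates by an order of magnitude and no `w_chain`
separates "subthreshold alone" from "suprathreshold with sensory input".
Second, the magnesium block makes chain current grow with target
depolarization, a coincidence-detection mechanism that favors exactly the
chain-plus-sensory conjunction the gating rule requires.

**Size rescaling.**  Test profiles use 100-neuron pools.  All recurrent
weights are scaled by `ref_pool_size / source_pool_size` so the summed
recurrent drive per neuron — and hence the pool regime — is approximately
size-invariant.  The fan-in counts quoted by the topology checks scale with
pool size as printed fractions.

## External signals

All external areas (PFC, sensory cortex, premotor/motor cortex, STS) are
modeled as seeded spike-train sources delivered through external-AMPA
receptors on three routing channels (pfc / sensory / motor), so the total
input to a chain neuron remains reportable as chain + sensory + prefrontal
+ corollary + local components.  Channel weights lump the afferent bundle
size: pfc 18, sensory 14, motor 20 (dimensionless multipliers on 1 nS).

Defaults: the intention burst is a bell-shaped train, 400 Hz peak, 150 ms
full width at half maximum, to a random 20% of the first pool; feedback and
observation trains are constant 200 Hz for 300 ms to a random 50% of the
target pool; the visual-mode PFC prediction is a tonic 60 Hz train (chosen
subthreshold: alone it produces at most a few stray spikes and never a
pool burst).  Rates were fixed once, before the behavioral suites, such
that a targeted neuron's drive sits clearly above rheobase (~500 pA) for
igniting inputs and clearly below for gating inputs.

## Task protocols

A pool counts as *activated* when its 20 ms-binned population rate crosses
an absolute floor of 20 Hz; offline burst annotation additionally uses a
half-of-peak criterion.  On activation in motor mode the engine (i) records
a motor output event (suppressed when the motor gate is closed), (ii)
delivers corollary discharge to the activated pool for
`act_duration + overlap` (300 + 80 ms) — the 80 ms coarticulation overlap
mirrors the overlap of successive bursts in the recordings and keeps the
predecessor's chain input alive when the successor ignites — and (iii) at
act completion delivers sensory feedback to the next pool.  In the
ambiguous task the final (goal-revealing) sensory event is delivered only
to the cued chain, at the cued chain's grasp completion; scheduling it
earlier than grasp completion is a configuration error.  In visual mode no
corollary or completion-driven feedback exists; observation events follow
the observed agent's timeline (act k at `k * act_duration`, duration
`act_duration + overlap`) and are delivered only when the observed act
matches the chain's expected act at that position.

## Plasticity and the learning experiment

The weight update is `dw_ij = eta * E_j(t) * K(t_post - t_pre)`, `K` the
asymmetric exponential kernel with `A_+ = A_- = 1`,
`tau_+ = tau_- = 20 ms`, and `K(0) = 0` (a tie belongs to neither branch).
Efficacy is attached to the presynaptic neuron and evaluated at the update
time.  Pairing is nearest-spike by default (bounded updates at high rates);
an all-pairs mode implemented with exponential spike traces exists and is
verified against a brute-force double loop over spike pairs.  Weights clip
to `[0, 100]`.

The learning experiment connects four pools all-to-all with initial
weights uniform in `[0, 0.05]` and drives each pool's neurons as
inhomogeneous Poisson processes following its template profile (an
activity clamp; the probe, by contrast, runs the full spiking network).
Template profiles are square bursts smoothed with a 20 ms Gaussian filter,
baseline-subtracted and peak-normalized to 60 Hz: four bursts of 300 ms
half-maximum width whose consecutive pairs are jointly above half maximum
for 80 ms.  Because a pool's burst both leads and overlaps its successor's,
potentiation events (post after pre) outnumber depression events on forward
synapses and vice versa on backward ones; forward weights grow roughly
linearly with sessions while backward weights stay near zero.  Shuffling
the template-to-pool assignment anew each session destroys the ordering and
with it the asymmetry (the control).

`eta = 1.5` is sized so that the scaled-down protocol (100-neuron pools,
150 sessions, probes at 0/50/100/150) traverses the full trajectory seen at
full scale over 500 sessions: probes of pool 1 leave downstream pools
silent until forward weights outgrow the *ungated* chain-ignition threshold
(~55 at this scale, far above the ~8 used for gated propagation), after
which the whole chain responds.  Sessions are separated by `2 tau_E` so
efficacy recovers between presentations.

## What the synthetic data do and do not show

The stimulus generators emulate the statistics the protocols need —
Poisson trains with prescribed rate envelopes, template profiles with the
recorded burst geometry — not the full variability of in-vivo recordings
(no trial-to-trial rate drift, no correlated noise, no background synaptic
bombardment; neurons are silent without input).  Passing suites therefore
demonstrate that the proposed circuit mechanisms produce the qualitative
phenomena (sequential gated propagation, disambiguation, recognition,
chain formation) under controlled drive, not that the model quantitatively
fits any recorded dataset.

## Numerical choices and degenerate inputs

Euler at `dt = 0.1 ms`; gating variables clipped to `[0, 1]`; trajectories
of the passive membrane, receptor gating and efficacy recovery converge to
their closed forms at first order (verified at `dt` vs `dt/10`).  A flat or
sub-floor rate trace yields an empty burst list rather than an error; a
motor run in which no pool activates reports a halted outcome.  Burst
detection smooths with a 3-bin moving average and ignores runs shorter
than 2 bins.  Exactly coincident pre/post spikes contribute no weight
change.  The probe classification in the regime sweep calls a response
*sustained* when the mean rate over the final 150 ms of the window stays
above the activation floor.

## Known limitations

* No synaptic transmission delays and no distance-dependent connectivity;
  propagation latencies arise solely from integration and detection times.
* PFC, sensory and motor areas are signal generators, not neuron
  populations; cue-to-chain association learning in PFC is out of scope
  (chain selection is given by configuration).
* Plasticity acts only on inter-pool weights; intra-pool wiring is frozen
  during learning.
* The desk-scale profile (100-neuron pools) reproduces the full-scale pool
  regime through weight rescaling, but finite-size rate fluctuations are
  ~2.2x larger; the activation floor (20 Hz) is chosen well above them.
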