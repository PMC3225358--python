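"""Conductance-based leaky integrate-and-fire neuron with kinetic receptor channels.

The membrane obeys

    C_m dV/dt = -g_L (V - V_L) + I_syn(t)

below threshold; crossing ``V_thr`` emits a spike, resets ``V`` to ``V_reset``
and clamps the membrane there for an absolute refractory period ``tau_ref``.
Synaptic input is carried by AMPA (external and recurrent), NMDA and GABA_A
channels, each described by a first-order kinetic scheme for the open-receptor
fraction ``s`` driven by square transmitter pulses, after Destexhe-style
kinetic synapse models.  The NMDA conductance is additionally gated by the
voltage-dependent magnesium block of Jahr & Stevens.

All quantities use a fixed unit system: mV, ms, nF, nS, mM; currents are in
pA (``nS * mV = pA``).  Since ``pA / nF = mV/s``, the membrane update carries
an explicit factor converting C_m from nF to pF.  Integration is explicit
first-order Euler; currents are evaluated at the voltage from the start of
the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "ReceptorParams",
    "NeuronState",
    "mg_block",
    "update_gating",
    "receptor_current",
    "step_membrane",
    "RECEPTOR_KINDS",
]

RECEPTOR_KINDS = ("AMPA_ext", "AMPA_rec", "NMDA", "GABA")

#: Jahr & Stevens magnesium-block constants: B(V) = 1 / (1 + (Mg/K_MG) e^(-GAMMA V))
_MG_K = 3.57  # mM
_MG_GAMMA = 0.062  # 1/mV


@dataclass
class NeuronParams:
    """Passive membrane and spiking parameters of a LIF neuron.

    Attributes
    ----------
    V_L : float
        Resting (leak) potential, mV.
    V_thr : float
        Firing threshold, mV.
    V_reset : float
        Post-spike reset potential, mV.
    C_m : float
        Membrane capacitance, nF.
    g_L : float
        Leak conductance, nS.
    tau_ref : float
        Absolute refractory period, ms.
    """

    V_L: float = -70.0
    V_thr: float = -50.0
    V_reset: float = -60.0
    C_m: float = 0.5
    g_L: float = 25.0
    tau_ref: float = 2.0

    def __post_init__(self) -> None:
        if not self.V_reset < self.V_thr:
            raise ValueError("V_reset must lie below V_thr")
        if self.C_m <= 0 or self.g_L <= 0:
            raise ValueError("C_m and g_L must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m/g_L in ms (nF/nS = s, hence the factor 1000)."""
        return 1000.0 * self.C_m / self.g_L

    def __repr__(self) -> str:  # tau_m shown for convenience
        return (
            f"NeuronParams(V_L={self.V_L}, V_thr={self.V_thr}, V_reset={self.V_reset}, "
            f"C_m={self.C_m}, g_L={self.g_L}, tau_ref={self.tau_ref}, tau_m={self.tau_m:.3g})"
        )


@dataclass
class ReceptorParams:
    """Kinetic parameters of one receptor channel type.

    ``alpha`` (1/(mM ms)) and ``beta`` (1/ms) are the opening and closing
    rates of the first-order gating scheme; each presynaptic spike places a
    square transmitter pulse of concentration ``T_amp`` (mM) lasting
    ``T_dur`` (ms) on the synapse.  ``Mg`` is only meaningful for NMDA.
    """

    kind: str
    g_max: float  # nS
    E_rev: float  # mV
    alpha: float  # 1/(mM ms)
    beta: float  # 1/ms
    T_amp: float = 1.0  # mM
    T_dur: float = 1.0  # ms
    Mg: float = 0.0  # mM

    def __post_init__(self) -> None:
        if self.kind not in RECEPTOR_KINDS:
            raise ValueError(f"unknown receptor kind {self.kind!r}")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.Mg < 0:
            raise ValueError("Mg concentration must be non-negative")


def default_receptors() -> dict[str, ReceptorParams]:
    """Destexhe-style kinetic constants for the four channel classes.

    Conductances are effective per-connection maxima; dimensionless
    connection weights multiply them.
    """
    return {
        "AMPA_ext": ReceptorParams("AMPA_ext", g_max=1.0, E_rev=0.0, alpha=1.1, beta=0.19),
        "AMPA_rec": ReceptorParams("AMPA_rec", g_max=1.0, E_rev=0.0, alpha=1.1, beta=0.19),
        "NMDA": ReceptorParams("NMDA", g_max=0.15, E_rev=0.0, alpha=0.072, beta=0.0066, Mg=1.0),
        "GABA": ReceptorParams("GABA", g_max=3.0, E_rev=-70.0, alpha=5.0, beta=0.18),
    }


@dataclass
class NeuronState:
    """Dynamical state of a single neuron (per-afferent gating variables)."""

    V: float
    s: np.ndarray = field(default_factory=lambda: np.zeros(0))
    refr_remaining: float = 0.0
    last_spike_time: float | None = None


def mg_block(V, Mg):
    """Voltage-dependent NMDA unblock factor B(V) of Jahr & Stevens.

    B(V) = 1 / (1 + (Mg / 3.57 mM) * exp(-0.062 V)); B == 1 when Mg == 0,
    monotonically increasing in V, approaching 1 at depolarized potentials.

    Parameters are the membrane potential in mV (scalar or array) and the
    external magnesium concentration in mM.
    """
    Mg = float(Mg)
    if Mg < 0:
        raise ValueError("Mg concentration must be non-negative")
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + (Mg / _MG_K) * np.exp(-_MG_GAMMA * V))
    return out if out.ndim else float(out)


def update_gating(s, T, alpha, beta, dt):
    """One Euler step of the first-order receptor kinetics.

    ds/dt = alpha * T * (1 - s) - beta * s, with the result clipped to [0, 1].
    ``T`` is the instantaneous transmitter concentration (mM), zero outside
    transmitter pulses.  Accepts scalars or arrays (broadcast together).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = np.asarray(s, dtype=float)
    T = np.asarray(T, dtype=float)
    s_new = s + dt * (alpha * T * (1.0 - s) - beta * s)
    s_new = np.clip(s_new, 0.0, 1.0)
    return s_new if s_new.ndim else float(s_new)


def receptor_current(state: NeuronState, params: ReceptorParams, weights, V=None):
    """Synaptic current (pA, inward-positive) through one receptor class.

    Evaluates ``I = -g_max * (V - E_rev) * sum_j w_j s_j`` so that an
    excitatory channel (E_rev above V) yields a positive, depolarizing
    current; this is the sign convention expected by :func:`step_membrane`,
    whose membrane equation adds I_syn.  For NMDA the sum is additionally
    scaled by the magnesium unblock factor ``mg_block(V, Mg)``.
    """
    weights = np.asarray(weights, dtype=float)
    s = np.asarray(state.s, dtype=float)
    if weights.shape != s.shape:
        raise ValueError(
            f"afferent weight vector (len {weights.size}) does not match "
            f"gating vector (len {s.size})"
        )
    v = state.V if V is None else float(V)
    drive = float(np.dot(weights, s))
    if params.kind == "NMDA":
        drive *= mg_block(v, params.Mg)
    return -params.g_max * (v - params.E_rev) * drive


def step_membrane(state: NeuronState, params: NeuronParams, I_syn: float, dt: float,
                  t: float | None = None):
    """Advance the membrane one Euler step; returns ``(state, spiked)``.

    During the refractory period V is clamped at ``V_reset`` and the
    refractory clock runs down.  Otherwise
    ``V += dt * (-g_L (V - V_L) + I_syn) / C_m``; reaching ``V_thr`` emits a
    spike, resets V and engages the refractory period.  The state is
    modified in place and also returned.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(I_syn):
        raise FloatingPointError("non-finite synaptic current")
    spiked = False
    if state.refr_remaining > 0:
        state.V = params.V_reset
        state.refr_remaining = max(0.0, state.refr_remaining - dt)
        return state, spiked
    # C_m is stored in nF; pA / pF = mV/ms, hence the factor 1000.
    dV = dt * (-params.g_L * (state.V - params.V_L) + I_syn) / (1000.0 * params.C_m)
    state.V += dV
    if state.V >= params.V_thr:
        spiked = True
        state.V = params.V_reset
        state.refr_remaining = params.tau_ref
        if t is not None:
            state.last_spike_time = t
    return state, spiked
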