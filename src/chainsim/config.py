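"""Configuration schema: every model constant by name, with units, in YAML.

The default values are the study conditions of the simulations: pools of
500 neurons (25% inhibitory, 20% intra-pool fan-in), two four-act chains
("eat" and "place"), 300 ms motor acts, 20 ms analysis bins.  Connection
strengths (w_E, w_I, w_chain) are calibration products of the pool-regime
sweep — chosen so a stimulated pool responds with a transient avalanche and
chain input alone stays subthreshold.  Test profiles shrink pools to 100
neurons; recurrent weights are size-rescaled automatically (see
:mod:`chainsim.network_topology`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .neuron_dynamics import NeuronParams, ReceptorParams, default_receptors
from .stimulus_generator import TemplateProfileSpec

__all__ = ["ModelConfig", "default_config", "test_profile_config"]


@dataclass
class ChainSpec:
    goal: str
    acts: list[str]


@dataclass
class NetworkConfig:
    pool_size: int = 500
    ref_pool_size: int = 500  # size at which w_* are defined; weights scale by ref/size
    chains: list[ChainSpec] = field(default_factory=lambda: [
        ChainSpec("eat", ["reaching", "shaping", "grasping", "bringing_to_mouth"]),
        ChainSpec("place", ["reaching", "shaping", "grasping", "placing"]),
    ])
    learning_acts: list[str] = field(default_factory=lambda: [
        "reaching", "shaping", "grasping", "bringing_to_mouth"])


@dataclass
class SynapseConfig:
    """Dimensionless weight multipliers on the receptor conductances.

    Inter-pool (chain) projections are NMDA-dominated: the slow NMDA gating
    integrates presynaptic-pool firing over tens of ms, so the chain input a
    target pool sees is comparable during its predecessor's brief avalanche
    and its sustained act phase, and the magnesium block makes the chain
    current largest exactly when the target is already depolarized by
    coincident sensory input.  ``chain_ampa_gain`` / ``chain_nmda_gain``
    scale the two receptor contributions of inter-pool links.
    """

    w_E: float = 4.0       # local excitatory strength (regime-map knob)
    w_I: float = 2.0       # local inhibitory strength
    w_chain: float = 8.0   # forward inter-pool strength (NMDA-routed)
    p_intra: float = 0.20  # intra-pool fan-in fraction
    p_inter: float = 0.10  # inter-pool fan-in fraction (of source excitatory)
    inh_fraction: float = 0.25
    chain_ampa_gain: float = 0.04
    chain_nmda_gain: float = 6.67  # ~1 nS effective NMDA conductance on chains


@dataclass
class DepressionConfig:
    """Activity-dependent synaptic efficacy E (presynaptic, multiplicative).

    E is multiplied into every recurrent excitatory synapse's drive; it drops
    by the factor (1 - u) at each presynaptic spike and recovers toward 1
    with time constant tau_E.  This terminates pool avalanches, producing the
    transient bell-shaped population bursts.
    """

    enabled: bool = True
    u: float = 0.1
    tau_E: float = 300.0  # ms


@dataclass
class StimulusConfig:
    """External drive amplitudes (rates in Hz per targeted neuron)."""

    intention_rate: float = 400.0
    intention_width: float = 150.0  # ms FWHM of the bell
    intention_fraction: float = 0.20
    feedback_rate: float = 200.0
    feedback_duration: float = 300.0  # ms
    feedback_fraction: float = 0.5
    visual_tonic_rate: float = 60.0  # subthreshold PFC prediction in visual mode
    # channel weights: dimensionless multipliers on the external-AMPA conductance,
    # lumping the size of each afferent fiber bundle
    pfc_weight: float = 18.0
    sensory_weight: float = 14.0
    motor_weight: float = 20.0
    template: TemplateProfileSpec = field(default_factory=TemplateProfileSpec)


@dataclass
class EngineConfig:
    dt: float = 0.1  # ms, Euler step
    bin_ms: float = 20.0  # analysis / detection bin
    activation_floor_hz: float = 20.0  # pool counts as active above this rate
    act_duration: float = 300.0  # ms per motor act
    overlap: float = 80.0  # ms coarticulation between consecutive acts


@dataclass
class STDPConfig:
    """Learning-rule constants; the kernel amplitudes are 1 by convention.

    ``eta`` is sized so that the learning experiment traverses the full
    silent -> partial -> propagating trajectory within the configured
    session count (forward weights must outgrow the ungated chain-ignition
    threshold, which sits far above the gated-propagation range).
    """

    eta: float = 1.5
    A_plus: float = 1.0
    A_minus: float = 1.0
    tau_plus: float = 20.0  # ms
    tau_minus: float = 20.0  # ms
    w_min: float = 0.0
    w_max: float = 100.0
    pairing: str = "nearest"  # nearest | all-pairs
    sessions: int = 500
    checkpoints: list[int] = field(default_factory=lambda: [0, 150, 250, 500])
    w_init_max: float = 0.05


@dataclass
class ModelConfig:
    seed: int = 1
    neuron: NeuronParams = field(default_factory=NeuronParams)
    receptors: dict[str, ReceptorParams] = field(default_factory=default_receptors)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    synapse: SynapseConfig = field(default_factory=SynapseConfig)
    depression: DepressionConfig = field(default_factory=DepressionConfig)
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    stdp: STDPConfig = field(default_factory=STDPConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        kw = {}
        kw["seed"] = d.get("seed", 1)
        kw["neuron"] = NeuronParams(**d.get("neuron", {}))
        kw["receptors"] = {k: ReceptorParams(**v) for k, v in
                           d.get("receptors", asdict_default_receptors()).items()}
        net = dict(d.get("network", {}))
        if "chains" in net:
            net["chains"] = [ChainSpec(**c) for c in net["chains"]]
        kw["network"] = NetworkConfig(**net)
        kw["synapse"] = SynapseConfig(**d.get("synapse", {}))
        kw["depression"] = DepressionConfig(**d.get("depression", {}))
        stim = dict(d.get("stimulus", {}))
        if "template" in stim:
            stim["template"] = TemplateProfileSpec(**stim["template"])
        kw["stimulus"] = StimulusConfig(**stim)
        kw["engine"] = EngineConfig(**d.get("engine", {}))
        kw["stdp"] = STDPConfig(**d.get("stdp", {}))
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path_or_text) -> "ModelConfig":
        try:
            with open(path_or_text) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError):
            d = yaml.safe_load(path_or_text)
        return cls.from_dict(d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=float).encode()
        ).hexdigest()


def asdict_default_receptors() -> dict:
    return {k: asdict(v) for k, v in default_receptors().items()}


def default_config(seed: int = 1) -> ModelConfig:
    """Full-scale study conditions (500-neuron pools)."""
    return ModelConfig(seed=seed)


def test_profile_config(seed: int = 1, pool_size: int = 100) -> ModelConfig:
    """Desk-scale profile: smaller pools, identical dynamics via weight rescaling."""
    cfg = ModelConfig(seed=seed)
    cfg.network.pool_size = pool_size
    return cfg
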