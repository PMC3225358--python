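"""Seeded generators for every external signal driving the chain network.

External areas are not modeled as neurons: prefrontal intention bursts,
sensory/proprioceptive feedback, motor corollary discharge and visual
observation events all arrive as trains of spikes delivered to configured
subsets of pool neurons through external-AMPA receptors.  The module also
generates the template activity profiles for the chain-learning experiment:
four sequential bell-shaped bursts (~300 ms at half maximum, successive
bursts overlapping ~80 ms), Gaussian-filtered, baseline-subtracted and
peak-normalized, emulating the firing profiles of parietal neurons recorded
during a reach-grasp-eat sequence.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "StimulusEvent",
    "StimulusProgram",
    "TemplateProfileSpec",
    "gen_poisson_train",
    "gen_intention_burst",
    "gen_feedback_train",
    "gen_template_profiles",
    "realize_event_trains",
]

#: routing channels; all are delivered through external-AMPA receptors
CHANNELS = ("pfc", "sensory", "motor")


@dataclass
class StimulusEvent:
    """One timed external input to a fraction of a pool.

    ``rate_profile`` is one of ``constant``, ``bell`` or ``template``.  For a
    bell event the rate follows a Gaussian of full width at half maximum
    ``width`` centered at ``onset + duration/2``; a template event carries an
    explicit (t, rate) sampling in ``profile_t``/``profile_rate``.
    """

    target_pool: str
    target_fraction: float
    onset: float  # ms
    duration: float  # ms
    rate_profile: str  # constant | bell | template
    peak_rate: float  # Hz, per targeted neuron
    channel: str = "sensory"
    receptor: str = "AMPA_ext"
    seed: int = 0
    width: float | None = None  # ms, FWHM (bell only)
    profile_t: np.ndarray | None = None
    profile_rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.target_fraction <= 1:
            raise ValueError("target_fraction must lie in (0, 1]")
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if self.peak_rate < 0:
            raise ValueError("peak_rate must be non-negative")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.rate_profile not in ("constant", "bell", "template"):
            raise ValueError(f"unknown rate profile {self.rate_profile!r}")
        if self.rate_profile == "bell" and (self.width is None or self.width <= 0):
            raise ValueError("bell profile requires a positive width")

    def rate_at(self, t):
        """Instantaneous rate (Hz) at absolute time(s) ``t`` (ms)."""
        t = np.asarray(t, dtype=float)
        inside = (t >= self.onset) & (t < self.onset + self.duration)
        if self.rate_profile == "constant":
            r = np.where(inside, self.peak_rate, 0.0)
        elif self.rate_profile == "bell":
            center = self.onset + self.duration / 2.0
            sigma = self.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            r = self.peak_rate * np.exp(-0.5 * ((t - center) / sigma) ** 2)
            r = np.where(inside, r, 0.0)
        else:
            r = np.interp(t, self.profile_t, self.profile_rate, left=0.0, right=0.0)
            r = np.where(inside, r, 0.0)
        return r if r.ndim else float(r)


@dataclass
class StimulusProgram:
    """A set of stimulus events, kept sorted by onset."""

    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset)

    def add(self, event: StimulusEvent) -> None:
        self.events.append(event)
        self.events.sort(key=lambda e: e.onset)

    def to_dict(self) -> dict:
        out = []
        for e in self.events:
            d = asdict(e)
            for k in ("profile_t", "profile_rate"):
                if d[k] is not None:
                    d[k] = np.asarray(d[k]).tolist()
            out.append(d)
        return {"events": out}

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProgram":
        events = []
        for ed in d["events"]:
            ed = dict(ed)
            for k in ("profile_t", "profile_rate"):
                if ed.get(k) is not None:
                    ed[k] = np.asarray(ed[k], dtype=float)
            events.append(StimulusEvent(**ed))
        return cls(events=events)

    def to_yaml(self, path=None) -> str:
        import yaml

        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "StimulusProgram":
        import yaml

        try:
            with open(path_or_text) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError):
            d = yaml.safe_load(path_or_text)
        return cls.from_dict(d)


@dataclass
class TemplateProfileSpec:
    """Geometry of the template activity profiles for chain learning.

    ``burst_duration`` is the width of each burst at half maximum (ms) and
    ``overlap`` the time successive bursts are jointly above half maximum.
    ``filter_sigma`` is the Gaussian smoothing applied to the raw profiles,
    matching the 20 ms histogram bin used throughout.
    """

    n_acts: int = 4
    burst_duration: float = 300.0  # ms at half maximum
    overlap: float = 80.0  # ms jointly above half maximum
    peak_rate: float = 60.0  # Hz after peak normalization
    filter_sigma: float = 20.0  # ms
    baseline: float = 0.0  # Hz, subtracted

    def __post_init__(self) -> None:
        if self.n_acts < 1:
            raise ValueError("n_acts must be at least 1")
        if self.burst_duration <= 0:
            raise ValueError("burst_duration must be positive")
        if not 0 <= self.overlap < self.burst_duration:
            raise ValueError("overlap must be non-negative and smaller than burst_duration")
        if self.peak_rate <= 0 or self.filter_sigma <= 0:
            raise ValueError("peak_rate and filter_sigma must be positive")


def _as_rate_fn(rate_profile):
    if callable(rate_profile):
        return rate_profile
    if np.isscalar(rate_profile):
        r = float(rate_profile)
        if r < 0:
            raise ValueError("rate must be non-negative")
        return lambda t: np.full_like(np.asarray(t, dtype=float), r)
    t_grid, r_grid = rate_profile
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid < 0):
        raise ValueError("rate must be non-negative")
    return lambda t: np.interp(t, t_grid, r_grid, left=0.0, right=0.0)


def gen_poisson_train(rate_profile, duration, n_targets, seed):
    """Inhomogeneous Poisson spike trains over ``[0, duration)`` ms.

    ``rate_profile`` may be a scalar rate (Hz), a ``(t_ms, rate_hz)`` grid
    pair, or a callable ``t -> rate``.  Returns a list of ``n_targets``
    sorted spike-time arrays (ms), generated by thinning and reproducible
    under the seed.
    """
    rate_fn = _as_rate_fn(rate_profile)
    probe = rate_fn(np.linspace(0.0, duration, max(64, int(duration) + 1)))
    if np.any(np.asarray(probe) < 0):
        raise ValueError("rate must be non-negative")
    rate_max = float(np.max(probe))
    rng = np.random.default_rng(seed)
    trains = []
    lam = rate_max / 1000.0  # spikes per ms
    for _ in range(n_targets):
        if lam == 0:
            trains.append(np.empty(0))
            continue
        n = rng.poisson(lam * duration)
        t = np.sort(rng.uniform(0.0, duration, size=n))
        keep = rng.uniform(0.0, rate_max, size=n) < rate_fn(t)
        trains.append(t[keep])
    return trains


def gen_intention_burst(target_pool, fraction, peak_rate, width, seed, *,
                        onset=0.0, channel="pfc"):
    """Bell-shaped prefrontal intention burst to a fraction of one pool.

    The burst has full width at half maximum ``width`` (ms) and is delivered
    over a support window of twice that width.  ``target_pool`` is a pool id.
    """
    if fraction <= 0:
        raise ValueError("target fraction must be positive (empty target set)")
    if width is None or width <= 0:
        raise ValueError("intention burst requires a positive width")
    return StimulusEvent(
        target_pool=target_pool, target_fraction=fraction, onset=onset,
        duration=2.0 * width, rate_profile="bell", peak_rate=peak_rate,
        channel=channel, seed=seed, width=width)


def gen_feedback_train(kind, target_pool, duration, seed, *, onset=0.0,
                       rate=200.0, fraction=0.25):
    """Constant-rate feedback train: ``sensory`` or ``corollary`` (motor copy)."""
    if kind not in ("sensory", "corollary"):
        raise ValueError(f"unknown feedback kind {kind!r}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    channel = "sensory" if kind == "sensory" else "motor"
    return StimulusEvent(
        target_pool=target_pool, target_fraction=fraction, onset=onset,
        duration=duration, rate_profile="constant", peak_rate=rate,
        channel=channel, seed=seed)


def gen_template_profiles(spec: TemplateProfileSpec, dt: float = 1.0):
    """Deterministic per-pool template rate profiles.

    Returns ``(t, profiles)`` where ``t`` is a common time grid (ms, step
    ``dt``) and ``profiles`` has shape ``(n_acts, len(t))`` in Hz.  Each
    profile is a square burst of width ``burst_duration`` smoothed with a
    Gaussian filter (``filter_sigma``), baseline-subtracted and normalized
    to ``peak_rate``; burst k is centered at
    ``margin + k * (burst_duration - overlap)`` so that consecutive bursts
    are jointly above half maximum for ``overlap`` ms.
    """
    w = spec.burst_duration
    stride = w - spec.overlap
    margin = w / 2.0 + 6.0 * spec.filter_sigma
    centers = margin + stride * np.arange(spec.n_acts)
    t_end = centers[-1] + w / 2.0 + 6.0 * spec.filter_sigma
    t = np.arange(0.0, t_end + dt, dt)
    profiles = np.zeros((spec.n_acts, t.size))
    for k, c in enumerate(centers):
        raw = np.where((t >= c - w / 2.0) & (t < c + w / 2.0), 1.0, 0.0)
        raw += spec.baseline / max(spec.peak_rate, 1e-12)
        smooth = gaussian_filter1d(raw, sigma=spec.filter_sigma / dt, mode="nearest")
        smooth = smooth - smooth.min()  # baseline subtraction
        smooth[smooth < 5e-3 * smooth.max()] = 0.0  # inter-burst rate -> 0
        profiles[k] = spec.peak_rate * smooth / smooth.max()  # peak normalization
    return t, profiles


def realize_event_trains(event: StimulusEvent, pool, seed=None):
    """Draw target neurons and spike trains for one event.

    Returns ``(neuron_ids, trains)`` where ``trains`` holds absolute spike
    times (ms).  Pure function of (event, pool, seed); ``seed`` defaults to
    the event's own seed.
    """
    rng_seed = event.seed if seed is None else seed
    n_targets = int(round(event.target_fraction * pool.size))
    if n_targets == 0:
        raise ValueError("event targets an empty neuron set")
    rng = np.random.default_rng(rng_seed)
    ids = np.sort(rng.choice(pool.size, size=n_targets, replace=False)) + pool.start
    rate_fn = lambda t: event.rate_at(np.asarray(t) + event.onset)
    trains = gen_poisson_train(rate_fn, event.duration, n_targets,
                               np.random.default_rng(rng_seed + 1))
    trains = [tr + event.onset for tr in trains]
    return ids, trains
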