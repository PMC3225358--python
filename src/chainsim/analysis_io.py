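"""Rasters, PSTHs, burst metrics and result serialization.

Histogram conventions follow the electrophysiology the model emulates:
20 ms bins, rates in spikes/s, traces optionally aligned to a task event
(by convention the moment the object is touched, i.e. grasp completion).
Results are written as plain CSV/JSON at desk scale: a raster table
(neuron_id, pool_id, t_ms), a binned rate table, burst annotations and a
manifest carrying the seed and config hash for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .task_engine import SimulationResult

__all__ = [
    "PSTH",
    "ParseError",
    "compute_psth",
    "measure_burst_stats",
    "write_result",
    "read_result",
    "results_equal",
]

RASTER_COLUMNS = ["neuron_id", "pool_id", "t_ms"]


class ParseError(ValueError):
    """A result file does not match the documented schema."""


@dataclass
class PSTH:
    """Per-pool peri-stimulus time histogram.

    ``counts[b, p]`` is the number of spikes of pool ``pool_ids[p]`` in bin
    ``[edges[b], edges[b+1])`` (times relative to the alignment event);
    ``rate`` is counts / (n_neurons * bin width) in Hz.
    """

    bin_width: float  # ms
    edges: np.ndarray  # ms, relative to alignment
    counts: np.ndarray  # (n_bins, n_pools)
    rate: np.ndarray  # Hz
    pool_ids: list[str]
    alignment_time: float


def compute_psth(raster: pd.DataFrame, bin_width=20.0, alignment_time=0.0,
                 pool_sizes=None, window=None) -> PSTH:
    """Bin a raster into a per-pool PSTH.

    ``raster`` needs columns ``neuron_id``, ``pool_id``, ``t_ms``.  Bin edges
    are half-open ``[t, t + bin)`` relative to ``alignment_time``.
    ``pool_sizes`` maps pool id -> neuron count for the rate normalization;
    when omitted, the number of distinct neurons observed per pool is used.
    ``window`` optionally fixes the (relative) time span as ``(lo, hi)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    missing = [c for c in RASTER_COLUMNS if c not in raster.columns]
    if missing:
        raise ParseError(f"raster is missing column(s) {missing}")
    pool_ids = sorted(raster["pool_id"].unique().tolist()) if len(raster) else []
    if pool_sizes is not None:
        pool_ids = sorted(set(pool_ids) | set(pool_sizes))
    t_rel = raster["t_ms"].to_numpy(dtype=float) - alignment_time
    if window is None:
        if t_rel.size == 0:
            window = (0.0, bin_width)
        else:
            lo = np.floor(t_rel.min() / bin_width) * bin_width
            hi = np.ceil((t_rel.max() + 1e-9) / bin_width) * bin_width
            window = (lo, max(hi, lo + bin_width))
    edges = np.arange(window[0], window[1] + 0.5 * bin_width, bin_width)
    n_bins = edges.size - 1
    counts = np.zeros((n_bins, len(pool_ids)))
    for p, pid in enumerate(pool_ids):
        sel = raster["pool_id"] == pid
        if sel.any():
            counts[:, p], _ = np.histogram(t_rel[sel.to_numpy()], bins=edges)
    if pool_sizes is not None:
        n_neurons = np.array([max(1, pool_sizes.get(pid, 1)) for pid in pool_ids])
    else:
        n_neurons = np.array([
            max(1, raster.loc[raster["pool_id"] == pid, "neuron_id"].nunique())
            for pid in pool_ids])
    rate = 1000.0 * counts / (n_neurons[None, :] * bin_width)
    return PSTH(bin_width=bin_width, edges=edges, counts=counts, rate=rate,
                pool_ids=pool_ids, alignment_time=alignment_time)


def _half_max_run(trace):
    """(start, stop) bin indices of the contiguous half-max run around the peak."""
    peak = trace.max()
    if peak <= 0:
        return None
    above = trace >= 0.5 * peak
    k = int(np.argmax(trace))
    lo = k
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = k + 1
    while hi < trace.size and above[hi]:
        hi += 1
    return lo, hi


def measure_burst_stats(pool_rates, bin_ms):
    """Half-maximum burst geometry of per-pool rate traces.

    ``pool_rates`` is an ordered mapping pool id -> binned rate trace (Hz).
    For each pool the onset, width and peak of the half-maximum run around
    the trace peak are reported; for each consecutive pool pair, the time
    both traces are simultaneously above their own half maxima.  All times
    are multiples of ``bin_ms``.
    """
    stats, order = {}, list(pool_rates)
    above = {}
    for pid in order:
        trace = np.asarray(pool_rates[pid], dtype=float)
        run = _half_max_run(trace)
        if run is None:
            stats[pid] = {}
            above[pid] = np.zeros(trace.size, dtype=bool)
            continue
        lo, hi = run
        stats[pid] = {
            "onset_ms": lo * bin_ms,
            "width_ms": (hi - lo) * bin_ms,
            "peak_hz": float(trace.max()),
            "peak_t_ms": int(np.argmax(trace)) * bin_ms,
        }
        above[pid] = trace >= 0.5 * trace.max()
    overlaps = []
    for a, b in zip(order, order[1:]):
        na, nb = above[a].size, above[b].size
        m = min(na, nb)
        joint = int(np.sum(above[a][:m] & above[b][:m]))
        overlaps.append({"pair": (a, b), "overlap_ms": joint * bin_ms})
    return {"pools": stats, "overlaps": overlaps}


# ---------------------------------------------------------------------------
# result files


def write_result(result: SimulationResult, path) -> Path:
    """Write a simulation result as raster.csv / rates.csv / bursts.json /
    manifest.json under ``path`` (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    result.raster_df().to_csv(path / "raster.csv", index=False)
    result.rates_df().to_csv(path / "rates.csv", index=False)
    with open(path / "bursts.json", "w") as fh:
        json.dump(result.bursts, fh, indent=1)
    manifest = dict(result.manifest)
    manifest.update({
        "bin_ms": result.bin_ms,
        "pool_ids": result.pool_ids,
        "activations": result.activations,
        "outcome": result.outcome,
        "motor_events": [list(e) for e in result.motor_events],
    })
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return path


def read_result(path) -> SimulationResult:
    """Read back a result directory written by :func:`write_result`."""
    path = Path(path)
    raster = pd.read_csv(path / "raster.csv")
    missing = [c for c in RASTER_COLUMNS if c not in raster.columns]
    if missing:
        raise ParseError(f"{path / 'raster.csv'}: missing column(s) {missing}")
    rates = pd.read_csv(path / "rates.csv")
    if "t_ms" not in rates.columns:
        raise ParseError(f"{path / 'rates.csv'}: missing column t_ms")
    with open(path / "bursts.json") as fh:
        bursts = json.load(fh)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    for key in ("pool_ids", "bin_ms", "outcome"):
        if key not in manifest:
            raise ParseError(f"{path / 'manifest.json'}: missing field {key!r}")
    pool_ids = manifest["pool_ids"]
    pool_pos = {pid: k for k, pid in enumerate(pool_ids)}
    spike_pools = np.array([pool_pos[p] for p in raster["pool_id"]], dtype=np.int64)
    activations = manifest.pop("activations", {})
    outcome = manifest.pop("outcome")
    motor_events = [tuple(e) for e in manifest.pop("motor_events", [])]
    return SimulationResult(
        spike_times=raster["t_ms"].to_numpy(dtype=float),
        spike_neurons=raster["neuron_id"].to_numpy(dtype=np.int64),
        spike_pools=spike_pools,
        pool_ids=pool_ids,
        pool_rates=rates[pool_ids].to_numpy(dtype=float),
        bin_ms=float(manifest.pop("bin_ms")),
        bursts=bursts,
        activations=activations,
        outcome=outcome,
        motor_events=motor_events,
        manifest=manifest)


def results_equal(a: SimulationResult, b: SimulationResult, rtol=1e-9) -> bool:
    """Lossless round-trip check between two results."""
    return (
        np.allclose(a.spike_times, b.spike_times, rtol=rtol)
        and np.array_equal(a.spike_neurons, b.spike_neurons)
        and np.array_equal(a.spike_pools, b.spike_pools)
        and a.pool_ids == b.pool_ids
        and np.allclose(a.pool_rates, b.pool_rates, rtol=rtol)
        and a.bin_ms == b.bin_ms
        and a.outcome == b.outcome
        and [tuple(e) for e in a.motor_events] == [tuple(e) for e in b.motor_events]
    )
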