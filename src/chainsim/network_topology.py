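"""Pools, chains and the sparse weight structure of the parietal-chain network.

Neurons are grouped into local pools (default 500 units, 25% inhibitory)
that are densely connected internally (each neuron draws an exact fan-in of
20% of its pool) and sparsely connected across pools: only excitatory
neurons send long-range projections, and chains are unidirectional — pool k
projects to pool k+1 and never backwards.  This gives the small-world-like
layout of strongly coupled local assemblies with few long-range links.

Weights are dimensionless multipliers on the receptor conductances.  To keep
pool dynamics comparable across pool sizes (test profiles use 100-neuron
pools), every stored weight is scaled by ``ref_pool_size / source_pool_size``
so the summed recurrent drive per neuron is approximately size-invariant.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Pool",
    "Chain",
    "NetworkTopology",
    "build_pool",
    "connect_chain",
    "build_network",
    "build_learning_network",
    "save_topology_csv",
    "load_topology_weights",
]


@dataclass
class Pool:
    """A local assembly of neurons sharing motor selectivity.

    ``start`` is the first global neuron index; the pool occupies
    ``range(start, start + size)``.  ``inhibitory_mask`` is a boolean array
    of length ``size`` (True for inhibitory neurons).
    """

    id: str
    motor_act: str
    size: int
    start: int
    inhibitory_mask: np.ndarray
    chain_id: str | None = None

    @property
    def neuron_ids(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.size)

    @property
    def n_inhibitory(self) -> int:
        return int(self.inhibitory_mask.sum())

    @property
    def excitatory_ids(self) -> np.ndarray:
        return self.neuron_ids[~self.inhibitory_mask]


@dataclass
class Chain:
    """An ordered, unidirectional sequence of pools realizing one action goal."""

    id: str
    pool_sequence: list[str]

    def __post_init__(self) -> None:
        if len(set(self.pool_sequence)) != len(self.pool_sequence):
            raise ValueError(f"chain {self.id!r}: pools may appear only once")


@dataclass
class NetworkTopology:
    """Complete wiring of the network.

    Weight matrices are CSR with shape (n, n) indexed ``[post, pre]``:
    ``W_local_E`` intra-pool excitatory, ``W_local_I`` intra-pool inhibitory,
    ``W_inter`` excitatory pool-to-pool links.
    """

    pools: list[Pool]
    chains: list[Chain]
    W_local_E: sp.csr_matrix
    W_local_I: sp.csr_matrix
    W_inter: sp.csr_matrix
    rng_seed: int
    ref_pool_size: int = 500
    _pool_index: dict[str, Pool] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._pool_index = {p.id: p for p in self.pools}

    @property
    def n_neurons(self) -> int:
        return sum(p.size for p in self.pools)

    def pool(self, pool_id: str) -> Pool:
        return self._pool_index[pool_id]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(chain_id)

    @property
    def inhibitory_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_neurons, dtype=bool)
        for p in self.pools:
            mask[p.start:p.start + p.size] = p.inhibitory_mask
        return mask

    @property
    def pool_of_neuron(self) -> np.ndarray:
        """Pool index (into ``self.pools``) for every neuron."""
        out = np.empty(self.n_neurons, dtype=np.int64)
        for k, p in enumerate(self.pools):
            out[p.start:p.start + p.size] = k
        return out

    def structure_hash(self) -> str:
        """SHA-256 over pool layout and sorted sparse triplets (determinism check)."""
        h = hashlib.sha256()
        for p in self.pools:
            h.update(f"{p.id}|{p.motor_act}|{p.chain_id}|{p.size}|{p.start}".encode())
            h.update(p.inhibitory_mask.tobytes())
        for W in (self.W_local_E, self.W_local_I, self.W_inter):
            coo = W.tocoo()
            order = np.lexsort((coo.col, coo.row))
            h.update(coo.row[order].astype(np.int64).tobytes())
            h.update(coo.col[order].astype(np.int64).tobytes())
            h.update(coo.data[order].astype(np.float64).tobytes())
        return h.hexdigest()


def _exact_fan_in(rng: np.random.Generator, size: int, k: int) -> np.ndarray:
    """(size, k) matrix: row i holds k distinct in-pool partners of neuron i (no self)."""
    partners = np.empty((size, k), dtype=np.int64)
    for i in range(size):
        pool_others = np.concatenate([np.arange(i), np.arange(i + 1, size)])
        partners[i] = rng.choice(pool_others, size=k, replace=False)
    return partners


def build_pool(size, inh_fraction, p_intra, w_E, w_I, seed, *, pool_id="pool",
               motor_act="", chain_id=None, start=0, ref_pool_size=500):
    """Build one pool and its local weight triplets.

    Exactly ``round(inh_fraction * size)`` neurons are inhibitory; each
    neuron receives connections from exactly ``round(p_intra * size)``
    distinct in-pool partners (excitatory partners carry ``w_E``, inhibitory
    ``w_I``).  Returns ``(Pool, (rows, cols, vals_E), (rows, cols, vals_I))``
    with indices already offset by ``start``.
    """
    if size < 2:
        raise ValueError("pool size must be at least 2")
    if not (0 <= inh_fraction <= 1 and 0 <= p_intra <= 1):
        raise ValueError("inh_fraction and p_intra must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_inh = int(round(inh_fraction * size))
    inh_mask = np.zeros(size, dtype=bool)
    inh_mask[rng.choice(size, size=n_inh, replace=False)] = True
    pool = Pool(id=pool_id, motor_act=motor_act, size=size, start=start,
                inhibitory_mask=inh_mask, chain_id=chain_id)

    fan_in = int(round(p_intra * size))
    scale = ref_pool_size / size
    if fan_in == 0:
        empty = (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, float))
        return pool, empty, empty

    partners = _exact_fan_in(rng, size, fan_in)
    post = np.repeat(np.arange(size), fan_in)
    pre = partners.ravel()
    pre_is_inh = inh_mask[pre]
    rows_E = post[~pre_is_inh] + start
    cols_E = pre[~pre_is_inh] + start
    vals_E = np.full(rows_E.size, w_E * scale)
    rows_I = post[pre_is_inh] + start
    cols_I = pre[pre_is_inh] + start
    vals_I = np.full(rows_I.size, w_I * scale)
    return pool, (rows_E, cols_E, vals_E), (rows_I, cols_I, vals_I)


def connect_chain(chain, pools, w_chain, p_inter, seed, *, ref_pool_size=500):
    """Forward inter-pool weight triplets for one chain.

    For each consecutive pair (k, k+1), every neuron of pool k+1 receives
    connections from exactly ``round(p_inter * n_excitatory(k))`` distinct
    *excitatory* neurons of pool k with weight ``w_chain`` (size-rescaled);
    no backward links exist.  Exact fan-in (mirroring the local wiring rule)
    keeps the chain input per target neuron sharp, which the subthreshold
    gating of propagation relies on.  ``pools`` maps pool id -> Pool.
    """
    seq = chain.pool_sequence
    for a, b in zip(seq, seq[1:]):
        if a == b:
            raise ValueError(f"chain {chain.id!r}: pool {a!r} repeated consecutively")
    rng = np.random.default_rng(seed)
    rows, cols, vals = [], [], []
    for a, b in zip(seq, seq[1:]):
        src, dst = pools[a], pools[b]
        src_exc = src.excitatory_ids
        fan_in = int(round(p_inter * src_exc.size))
        if fan_in == 0:
            continue
        scale = ref_pool_size / src.size
        for post in dst.neuron_ids:
            sources = rng.choice(src_exc, size=fan_in, replace=False)
            rows.append(np.full(fan_in, post, dtype=np.int64))
            cols.append(sources)
            vals.append(np.full(fan_in, w_chain * scale))
    if not rows:
        empty = np.empty(0, np.int64)
        return empty, empty, np.empty(0, float)
    return np.concatenate(rows), np.concatenate(cols), np.concatenate(vals)


def _assemble(triplets, n):
    rows = np.concatenate([t[0] for t in triplets]) if triplets else np.empty(0, np.int64)
    cols = np.concatenate([t[1] for t in triplets]) if triplets else np.empty(0, np.int64)
    vals = np.concatenate([t[2] for t in triplets]) if triplets else np.empty(0, float)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def build_network(config) -> NetworkTopology:
    """Build the full topology from a :class:`~chainsim.config.ModelConfig`.

    One pool is created per (chain, motor act); chains never share pools,
    even when they code the same motor act ("eat" and "place" both contain a
    grasping pool, but physically distinct ones).  Deterministic given
    ``config.seed``.
    """
    net = config.network
    syn = config.synapse
    pool_ids = []
    for chain_cfg in net.chains:
        for act in chain_cfg.acts:
            pid = f"{chain_cfg.goal}:{act}"
            if pid in pool_ids:
                raise ValueError(f"duplicate pool id {pid!r}")
            pool_ids.append(pid)

    ss = np.random.SeedSequence(config.seed)
    pool_seeds = ss.spawn(len(pool_ids))
    chain_seeds = ss.spawn(len(net.chains))

    pools, trip_E, trip_I = [], [], []
    start = 0
    i = 0
    for chain_cfg in net.chains:
        for act in chain_cfg.acts:
            pool, tE, tI = build_pool(
                net.pool_size, syn.inh_fraction, syn.p_intra, syn.w_E, syn.w_I,
                pool_seeds[i], pool_id=f"{chain_cfg.goal}:{act}", motor_act=act,
                chain_id=chain_cfg.goal, start=start, ref_pool_size=net.ref_pool_size)
            pools.append(pool)
            trip_E.append(tE)
            trip_I.append(tI)
            start += net.pool_size
            i += 1

    pool_map = {p.id: p for p in pools}
    chains, trip_X = [], []
    for k, chain_cfg in enumerate(net.chains):
        chain = Chain(id=chain_cfg.goal,
                      pool_sequence=[f"{chain_cfg.goal}:{a}" for a in chain_cfg.acts])
        chains.append(chain)
        trip_X.append(connect_chain(chain, pool_map, syn.w_chain, syn.p_inter,
                                    chain_seeds[k], ref_pool_size=net.ref_pool_size))

    n = start
    return NetworkTopology(
        pools=pools, chains=chains,
        W_local_E=_assemble(trip_E, n), W_local_I=_assemble(trip_I, n),
        W_inter=_assemble(trip_X, n), rng_seed=config.seed,
        ref_pool_size=net.ref_pool_size)


def build_learning_network(config, n_pools=4, w_init_max=0.05) -> NetworkTopology:
    """All-to-all network for the chain-learning experiment.

    ``n_pools`` pools with standard local wiring; every ordered pair of
    distinct pools is connected by excitatory links with low random initial
    weights drawn uniformly from ``[0, w_init_max]`` (these are the plastic
    synapses).  Fan-out per source neuron follows ``p_inter`` as for chains.
    """
    net = config.network
    syn = config.synapse
    acts = list(config.network.learning_acts)[:n_pools]
    if len(acts) < n_pools:
        acts += [f"act{i}" for i in range(len(acts), n_pools)]
    ss = np.random.SeedSequence(config.seed)
    pool_seeds = ss.spawn(n_pools)
    inter_rng = np.random.default_rng(ss.spawn(1)[0])

    pools, trip_E, trip_I = [], [], []
    start = 0
    for i in range(n_pools):
        pool, tE, tI = build_pool(
            net.pool_size, syn.inh_fraction, syn.p_intra, syn.w_E, syn.w_I,
            pool_seeds[i], pool_id=acts[i], motor_act=acts[i], chain_id=None,
            start=start, ref_pool_size=net.ref_pool_size)
        pools.append(pool)
        trip_E.append(tE)
        trip_I.append(tI)
        start += net.pool_size

    rows, cols, vals = [], [], []
    for a in pools:
        for b in pools:
            if a.id == b.id:
                continue
            src_exc = a.excitatory_ids
            fan_in = int(round(syn.p_inter * src_exc.size))
            scale = net.ref_pool_size / a.size
            for post in b.neuron_ids:
                sources = inter_rng.choice(src_exc, size=fan_in, replace=False)
                rows.append(np.full(fan_in, post, dtype=np.int64))
                cols.append(sources)
                vals.append(inter_rng.uniform(0.0, w_init_max * scale, size=fan_in))
    trip_X = (np.concatenate(rows), np.concatenate(cols), np.concatenate(vals))

    n = start
    return NetworkTopology(
        pools=pools, chains=[], W_local_E=_assemble(trip_E, n),
        W_local_I=_assemble(trip_I, n), W_inter=_assemble([trip_X], n),
        rng_seed=config.seed, ref_pool_size=net.ref_pool_size)


#: receptor routing of each weight matrix (local E carries AMPA+NMDA,
#: inter-pool links are NMDA-dominated; see the synapse config)
_MATRIX_KINDS = (("W_local_E", "AMPA_rec+NMDA"), ("W_local_I", "GABA"),
                 ("W_inter", "NMDA_chain"))


def save_topology_csv(topology: NetworkTopology, path) -> None:
    """Write the sparse weight structure as triplets
    (pre_id, post_id, weight, receptor_kind) in one CSV file."""
    import pandas as pd

    frames = []
    for attr, kind in _MATRIX_KINDS:
        coo = getattr(topology, attr).tocoo()
        frames.append(pd.DataFrame({
            "pre_id": coo.col.astype(np.int64),
            "post_id": coo.row.astype(np.int64),
            "weight": coo.data,
            "receptor_kind": kind,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_topology_weights(path, n: int):
    """Read a triplet CSV back into the three sparse matrices
    (W_local_E, W_local_I, W_inter)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"pre_id", "post_id", "weight", "receptor_kind"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing column(s) {required - set(df.columns)}")
    out = []
    for _, kind in _MATRIX_KINDS:
        sel = df[df["receptor_kind"] == kind]
        out.append(sp.csr_matrix(
            (sel["weight"].to_numpy(),
             (sel["post_id"].to_numpy(), sel["pre_id"].to_numpy())),
            shape=(n, n)))
    return tuple(out)
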