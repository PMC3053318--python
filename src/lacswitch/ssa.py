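"""Exact stochastic simulation (Gillespie direct method) of reaction networks.

The inner loop is compiled with numba.  Networks are lowered to flat arrays:
every reaction has at most two reactant species (all stoichiometries in the
lac model are one, but A+A pairs are supported), so propensities are computed
without touching a dense stoichiometry matrix.

Clamped species (constant-concentration pools) simply have zero net
stoichiometry, so their counts enter propensities but never change.

Reproducibility: ensembles derive one independent 31-bit seed per cell from
the master seed through ``numpy.random.SeedSequence``, so results are
bit-identical for a given master seed and independent of scheduling order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .countdist import CountDistribution
from .network import ReactionNetwork


class SimulationError(RuntimeError):
    pass


# --------------------------------------------------------------------- #
# kernel
# --------------------------------------------------------------------- #

@njit(cache=True)
def _ssa_core(counts, r1, r2, pair_same, kprop, net_idx, net_delta, net_len,
              t0, t_end, sample_times, out_counts,
              log_mask, log_times, log_rxn, seed):
    np.random.seed(seed)
    nr = kprop.shape[0]
    props = np.empty(nr)
    t = t0
    si = 0
    n_samples = sample_times.shape[0]
    n_log = 0
    max_log = log_times.shape[0]
    while True:
        a0 = 0.0
        for i in range(nr):
            a = kprop[i]
            j1 = r1[i]
            if j1 >= 0:
                if pair_same[i]:
                    n = counts[j1]
                    a *= 0.5 * n * (n - 1)
                else:
                    a *= counts[j1]
                    j2 = r2[i]
                    if j2 >= 0:
                        a *= counts[j2]
            props[i] = a
            a0 += a
        if a0 <= 0.0:
            # absorbing state: emit remaining samples and stop
            while si < n_samples:
                for s in range(counts.shape[0]):
                    out_counts[si, s] = counts[s]
                si += 1
            return 0, n_log, t
        tau = -np.log(np.random.random()) / a0
        t_next = t + tau
        while si < n_samples and sample_times[si] < t_next:
            for s in range(counts.shape[0]):
                out_counts[si, s] = counts[s]
            si += 1
        if si >= n_samples and t_next > t_end:
            return 0, n_log, t
        t = t_next
        if t > t_end:
            # only waiting for trailing samples exactly at t_end
            continue
        u = np.random.random() * a0
        acc = 0.0
        rxn = nr - 1
        for i in range(nr):
            acc += props[i]
            if u < acc:
                rxn = i
                break
        for m in range(net_len[rxn]):
            counts[net_idx[rxn, m]] += net_delta[rxn, m]
        if log_mask[rxn]:
            if n_log >= max_log:
                return 1, n_log, t
            log_times[n_log] = t
            log_rxn[n_log] = rxn
            n_log += 1


def _lower(network: ReactionNetwork):
    react, net, rates, clamp = network.to_arrays()
    nr = network.n_reactions
    r1 = np.full(nr, -1, dtype=np.int64)
    r2 = np.full(nr, -1, dtype=np.int64)
    pair_same = np.zeros(nr, dtype=np.bool_)
    for i in range(nr):
        idx = np.nonzero(react[i])[0]
        if idx.size == 0:
            continue
        if idx.size == 1:
            r1[i] = idx[0]
            if react[i, idx[0]] == 2:
                pair_same[i] = True
            elif react[i, idx[0]] != 1:
                raise SimulationError("stoichiometry > 2 not supported")
        elif idx.size == 2:
            r1[i], r2[i] = idx
            if react[i, idx[0]] != 1 or react[i, idx[1]] != 1:
                raise SimulationError("mixed high-order stoichiometry "
                                      "not supported")
        else:
            raise SimulationError("more than two reactant species")
    max_changes = max(1, int(np.max((net != 0).sum(axis=1))))
    net_idx = np.zeros((nr, max_changes), dtype=np.int64)
    net_delta = np.zeros((nr, max_changes), dtype=np.int64)
    net_len = np.zeros(nr, dtype=np.int64)
    for i in range(nr):
        nz = np.nonzero(net[i])[0]
        net_len[i] = nz.size
        for m, j in enumerate(nz):
            net_idx[i, m] = j
            net_delta[i, m] = net[i, j]
    return r1, r2, pair_same, rates, net_idx, net_delta, net_len, clamp


# --------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------- #

@dataclass
class Trajectory:
    """Fixed-interval samples of one SSA realization, plus an optional
    event log restricted to watched reactions."""

    times: np.ndarray
    counts: np.ndarray               # (n_samples, n_species)
    species: list
    network: ReactionNetwork | None = None
    event_times: np.ndarray | None = None
    event_reactions: np.ndarray | None = None
    seed: int | None = None

    def series(self, name: str) -> np.ndarray:
        return self.counts[:, self.species.index(name)]

    @property
    def final_counts(self) -> np.ndarray:
        return self.counts[-1]


@dataclass
class Ensemble:
    """Independent trajectories of one network under one condition."""

    trajectories: list
    network: ReactionNetwork
    condition: dict = field(default_factory=dict)
    seeds: np.ndarray | None = None

    def __len__(self):
        return len(self.trajectories)

    def stack(self, name: str) -> np.ndarray:
        """(n_cells, n_samples) matrix of one species' counts."""
        return np.stack([tr.series(name) for tr in self.trajectories])

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times


def cell_seeds(master_seed: int, n_cells: int) -> np.ndarray:
    """Per-cell 31-bit seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n_cells, dtype=np.uint32) % np.uint32(2 ** 31)
            ).astype(np.int64)


# --------------------------------------------------------------------- #
# drivers
# --------------------------------------------------------------------- #

def ssa_run(network: ReactionNetwork, init: np.ndarray, t_end: float,
            sample_interval: float, seed: int,
            log_reactions: list | None = None,
            t_start: float = 0.0,
            max_log: int = 1 << 20) -> Trajectory:
    """One exact SSA realization from ``t_start`` to ``t_end``.

    ``log_reactions`` selects reaction names whose firing times are recorded
    (opt-in, to bound memory); counts are sampled every ``sample_interval``.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    counts = np.array(init, dtype=np.int64).copy()
    if np.any(counts < 0):
        raise SimulationError("negative initial counts")
    r1, r2, pair_same, rates, net_idx, net_delta, net_len, _ = _lower(network)
    sample_times = np.arange(t_start, t_end + 0.5 * sample_interval,
                             sample_interval)
    out = np.zeros((sample_times.size, counts.size), dtype=np.int64)
    log_mask = np.zeros(network.n_reactions, dtype=np.bool_)
    if log_reactions:
        for name in log_reactions:
            log_mask[network.reaction_index(name)] = True
        cap = max_log
    else:
        cap = 1
    log_times = np.zeros(cap)
    log_rxn = np.zeros(cap, dtype=np.int64)
    status, n_log, _ = _ssa_core(
        counts, r1, r2, pair_same, rates, net_idx, net_delta, net_len,
        t_start, t_end, sample_times, out, log_mask, log_times, log_rxn,
        int(seed))
    if status != 0:
        raise SimulationError(
            f"event log overflowed ({cap} events); raise max_log")
    if np.any(counts < 0):
        raise SimulationError("negative species count; malformed network")
    return Trajectory(
        times=sample_times, counts=out, species=list(network.species),
        network=network,
        event_times=log_times[:n_log].copy() if log_reactions else None,
        event_reactions=log_rxn[:n_log].copy() if log_reactions else None,
        seed=int(seed))


def run_ensemble(network: ReactionNetwork, init_sampler, n_cells: int,
                 t_end: float, seed: int, sample_interval: float | None = None,
                 log_reactions: list | None = None,
                 condition: dict | None = None) -> Ensemble:
    """n_cells independent trajectories with per-cell derived seeds.

    ``init_sampler`` may be a fixed count vector, a list of per-cell count
    vectors, or a callable ``(rng, cell_index) -> counts``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if sample_interval is None:
        sample_interval = t_end / 200.0
    seeds = cell_seeds(seed, n_cells)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    trajectories = []
    for i in range(n_cells):
        if callable(init_sampler):
            init = init_sampler(rng, i)
        elif isinstance(init_sampler, (list, tuple)):
            init = init_sampler[i]
        elif isinstance(init_sampler, np.ndarray) and init_sampler.ndim == 2:
            init = init_sampler[i]
        else:
            init = init_sampler
        trajectories.append(
            ssa_run(network, init, t_end, sample_interval, seeds[i],
                    log_reactions=log_reactions))
    return Ensemble(trajectories=trajectories, network=network,
                    condition=dict(condition or {}), seeds=seeds)


def stationary_sample(network: ReactionNetwork, inducer_conc: float,
                      n_cells: int, seed: int,
                      burn_in: float = 10.0,
                      tau_p: float | None = None) -> CountDistribution:
    """Per-cell protein and mRNA counts after ``burn_in`` protein lifetimes.

    The chain forgets its initial condition on the protein-dilution
    timescale, so a burn-in of several lifetimes yields a stationary draw
    per cell.
    """
    if burn_in < 5:
        raise ValueError("burn_in must be at least 5 protein lifetimes")
    if tau_p is None:
        k_pdeg = [r.rate for r in network.reactions
                  if r.name == "protein_dilution"]
        tau_p = 1.0 / k_pdeg[0] if k_pdeg else 1.0
    t_end = burn_in * tau_p
    init = network.initial_state(inducer_conc=inducer_conc)
    ens = run_ensemble(network, init, n_cells, t_end, seed,
                       sample_interval=t_end)
    protein = np.array([tr.series("Y")[-1] for tr in ens.trajectories])
    mrna = np.array([tr.series("mY")[-1] for tr in ens.trajectories])
    return CountDistribution(
        protein=protein, mrna=mrna,
        metadata={
            "inducer_conc": inducer_conc, "variant": network.variant,
            "inducer_kind": network.inducer_kind, "n_cells": n_cells,
            "burn_in_lifetimes": burn_in, "seed": int(seed),
        })


def extract_operator_events(trajectory: Trajectory):
    """Free-operator intervals and their transcript counts.

    Returns a list of ``(release_time, rebind_time, n_mrna)`` for every
    maximal interval opened by a repressor release and closed by a rebinding
    within the logged window.  Zero-transcript intervals are included (they
    are unobservable as bursts; downstream statistics must drop them).
    """
    if trajectory.event_times is None:
        raise ValueError("trajectory has no event log; rerun with "
                         "log_reactions enabled")
    net = trajectory.network
    release = {net.reaction_index(n)
               for n in ("release_RO", "release_IRO", "release_I2RO")}
    bind = {net.reaction_index(n)
            for n in ("bind_R2", "bind_IR2", "bind_I2R2")}
    ts = net.reaction_index("transcription")
    events = []
    open_t = None
    n_mrna = 0
    for t, r in zip(trajectory.event_times, trajectory.event_reactions):
        if r in release:
            open_t = t
            n_mrna = 0
        elif r == ts:
            if open_t is not None:
                n_mrna += 1
        elif r in bind:
            if open_t is not None:
                events.append((open_t, t, n_mrna))
                open_t = None
    return events
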