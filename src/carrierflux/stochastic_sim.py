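"""Exact Gillespie simulation of the carrier network with event classification.

The same continuous-time Markov chain solved deterministically in
``reaction_network`` is simulated here with the stochastic simulation
algorithm (exponential waiting times, propensity-proportional event choice).
Each completed binding -> release episode is classified into one of four
fates per species: (1) bound cytoplasmic side, released matrix side
(productive import); (2) bound and released on the cytoplasmic side;
(3) bound and released on the matrix side; (4) bound matrix side, released
cytoplasmic side (productive export).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reaction_network import ReactionNetwork, State

__all__ = [
    "EventLog",
    "EpisodeCounts",
    "simulate",
    "classify_events",
    "flux_from_events",
    "occupancy_fractions",
    "occupancy_batches",
]

_CHUNK = 65536


@dataclass
class EpisodeCounts:
    """Completed bind->release episode counts for one species."""

    transport_cyt_to_mat: int = 0  # class 1
    returned_to_cyt: int = 0  # class 2
    returned_to_mat: int = 0  # class 3
    transport_mat_to_cyt: int = 0  # class 4

    @property
    def total(self) -> int:
        return (
            self.transport_cyt_to_mat
            + self.returned_to_cyt
            + self.returned_to_mat
            + self.transport_mat_to_cyt
        )


@dataclass
class EventLog:
    """Recorded trajectory of one stochastic run.

    times/transitions list every event (time in s, directed transition id in
    the network's expanded transition table). Counters are filled lazily on
    classification and cover only events after the burn-in window.
    """

    seed: int
    t_total: float
    burn_in: float
    initial_state: int
    times: np.ndarray
    transitions: np.ndarray
    terminated_early: bool = False
    counts: dict[str, EpisodeCounts] = field(default_factory=dict)
    truncated_episodes: int = 0
    orphan_releases: int = 0

    @property
    def n_events(self) -> int:
        return len(self.times)

    def to_csv(self, path, network: ReactionNetwork) -> None:
        labels = _transition_labels(network)
        pd.DataFrame(
            {"time_s": self.times, "reaction": [labels[t] for t in self.transitions]}
        ).to_csv(path, index=False)

    def summary(self, network: ReactionNetwork) -> dict:
        if not self.counts:
            classify_events(self, network)
        t_counted = self.t_total - self.burn_in
        per_species = {}
        for name, c in self.counts.items():
            per_species[name] = {
                "transport_cyt_to_mat": c.transport_cyt_to_mat,
                "returned_to_cyt": c.returned_to_cyt,
                "returned_to_mat": c.returned_to_mat,
                "transport_mat_to_cyt": c.transport_mat_to_cyt,
                "net_rate_per_s": (c.transport_cyt_to_mat - c.transport_mat_to_cyt) / t_counted,
            }
        return {
            "seed": self.seed,
            "t_total_s": self.t_total,
            "burn_in_s": self.burn_in,
            "n_events": self.n_events,
            "terminated_early": self.terminated_early,
            "truncated_episodes": self.truncated_episodes,
            "orphan_releases": self.orphan_releases,
            "species": per_species,
        }

    def summary_json(self, network: ReactionNetwork) -> str:
        return json.dumps(self.summary(network), indent=2)


def _expand_transitions(network: ReactionNetwork):
    """Directed transition table: 2 entries per reaction pair."""
    frm, to, rate, kind, side, species = [], [], [], [], [], []
    for r in network.reactions:
        # forward i->j, reverse j->i
        for a, b, k in ((r.i, r.j, r.forward), (r.j, r.i, r.reverse)):
            frm.append(a)
            to.append(b)
            rate.append(k)
            if r.kind == "bind":
                kind.append("bind" if a == r.i else "release")
            else:
                kind.append("conf")
            side.append(r.side)
            species.append(r.species)
    return (
        np.array(frm),
        np.array(to),
        np.array(rate),
        kind,
        side,
        species,
    )


def _transition_labels(network: ReactionNetwork) -> list[str]:
    frm, to, _, kind, side, species = _expand_transitions(network)
    labels = []
    for a, b, k in zip(frm, to, kind):
        labels.append(f"{network.states[a].label(network.params)}->{network.states[b].label(network.params)}")
    return labels


def simulate(
    network: ReactionNetwork,
    t_max: float | None = None,
    n_events: int | None = None,
    seed: int = 0,
    start: tuple[int, str | None] | None = None,
    burn_in_frac: float = 0.1,
) -> EventLog:
    """Run the exact SSA until ``t_max`` seconds or ``n_events`` events.

    The default initial state is the empty carrier in the cytoplasmic
    conformation; the first 10% of the horizon is treated as burn-in by the
    downstream counters. Fixed seeds reproduce bit-identical logs.
    """
    if t_max is None and n_events is None:
        raise ValueError("provide t_max or n_events")
    if (t_max is not None and t_max <= 0) or (n_events is not None and n_events <= 0):
        raise ValueError("horizon must be positive")

    p = network.params
    if start is None:
        start = (-p.n_half, None)
    s0 = network.state_index(*start)

    frm, to, rate, *_ = _expand_transitions(network)
    ns = network.n_states
    # per-state outgoing transitions
    out_ids: list[np.ndarray] = [np.where(frm == i)[0] for i in range(ns)]
    out_cum = [np.cumsum(rate[ids]) for ids in out_ids]
    out_total = np.array([c[-1] if len(c) else 0.0 for c in out_cum])
    out_to = [to[ids] for ids in out_ids]

    rng = np.random.default_rng(seed)
    times: list[np.ndarray] = []
    trans: list[np.ndarray] = []
    t = 0.0
    state = s0
    total_events = 0
    terminated = False
    cap = n_events if n_events is not None else None

    done = False
    while not done:
        m = _CHUNK if cap is None else min(_CHUNK, cap - total_events)
        if m <= 0:
            break
        u_t = rng.random(m)
        u_r = rng.random(m)
        t_chunk = np.empty(m)
        tr_chunk = np.empty(m, dtype=np.int32)
        filled = 0
        for k in range(m):
            a0 = out_total[state]
            if a0 <= 0.0:
                terminated = True
                done = True
                break
            t += -math.log(u_t[k]) / a0
            if t_max is not None and t > t_max:
                done = True
                break
            cum = out_cum[state]
            idx = int(np.searchsorted(cum, u_r[k] * a0))
            idx = min(idx, len(cum) - 1)
            t_chunk[filled] = t
            tid = out_ids[state][idx]
            tr_chunk[filled] = tid
            state = out_to[state][idx]
            filled += 1
        if filled:
            times.append(t_chunk[:filled])
            trans.append(tr_chunk[:filled])
            total_events += filled
        if cap is not None and total_events >= cap:
            done = True

    all_times = np.concatenate(times) if times else np.empty(0)
    all_trans = np.concatenate(trans) if trans else np.empty(0, dtype=np.int32)
    t_total = t_max if t_max is not None else (float(all_times[-1]) if len(all_times) else 0.0)
    return EventLog(
        seed=seed,
        t_total=t_total,
        burn_in=burn_in_frac * t_total,
        initial_state=s0,
        times=all_times,
        transitions=all_trans,
        terminated_early=terminated,
    )


def classify_events(log: EventLog, network: ReactionNetwork) -> dict[str, EpisodeCounts]:
    """Assign each completed bind->release episode to one of the 4 fates.

    Episodes whose binding happened before burn-in (or before the log began)
    are excluded and counted as orphans; an episode still open at the horizon
    is counted as truncated.
    """
    frm, to, _, kind, side, species = _expand_transitions(network)
    counts = {s.name: EpisodeCounts() for s in network.params.substrates}
    bind_side: str | None = None
    bind_species: int | None = None
    # was the run started in a bound state?
    started_bound = network.states[log.initial_state].s is not None
    open_unknown = started_bound
    truncated = 0
    orphans = 0
    burn = log.burn_in
    for t, tid in zip(log.times, log.transitions):
        k = kind[tid]
        if k == "conf":
            continue
        if k == "bind":
            bind_side = side[tid]
            bind_species = species[tid]
            open_unknown = False
        else:  # release
            if t < burn:
                bind_side = None
                bind_species = None
                open_unknown = False
                continue
            if open_unknown or bind_side is None:
                orphans += 1
                open_unknown = False
                continue
            name = network.params.substrates[bind_species].name
            rel = side[tid]
            c = counts[name]
            if bind_side == "cytoplasmic" and rel == "matrix":
                c.transport_cyt_to_mat += 1
            elif bind_side == "cytoplasmic" and rel == "cytoplasmic":
                c.returned_to_cyt += 1
            elif bind_side == "matrix" and rel == "matrix":
                c.returned_to_mat += 1
            else:
                c.transport_mat_to_cyt += 1
            bind_side = None
            bind_species = None
    if bind_side is not None or open_unknown:
        truncated = 1
    log.counts = counts
    log.truncated_episodes = truncated
    log.orphan_releases = orphans
    return counts


def flux_from_events(
    log: EventLog, network: ReactionNetwork, species: str | None = None
) -> tuple[float, float]:
    """Net transport estimate (class1 - class4)/t with episode-count SE.

    Returns (rate, standard error) in 1/s for the tracked species. With zero
    completed transport episodes the SE is undefined (nan) and a warning is
    issued.
    """
    if not log.counts:
        classify_events(log, network)
    if species is None:
        names = [s.name for s in network.params.substrates]
        species = "labelled" if "labelled" in names else names[0]
    c = log.counts[species]
    t_counted = log.t_total - log.burn_in
    if t_counted <= 0:
        raise ValueError("no counting window after burn-in")
    n1, n4 = c.transport_cyt_to_mat, c.transport_mat_to_cyt
    rate = (n1 - n4) / t_counted
    if n1 + n4 == 0:
        warnings.warn("zero transport episodes; standard error undefined", stacklevel=2)
        return rate, float("nan")
    se = math.sqrt(n1 + n4) / t_counted
    return rate, se


def occupancy_fractions(log: EventLog, network: ReactionNetwork) -> np.ndarray:
    """Time-weighted state occupancy fractions after burn-in.

    Comparable directly with the master-equation stationary distribution.
    """
    frm, to, *_ = _expand_transitions(network)
    dwell = np.zeros(network.n_states)
    state = log.initial_state
    t_prev = 0.0
    burn = log.burn_in
    for t, tid in zip(log.times, log.transitions):
        t0 = max(t_prev, burn)
        if t > t0:
            dwell[state] += t - t0
        state = to[tid]
        t_prev = t
    if log.t_total > max(t_prev, burn):
        dwell[state] += log.t_total - max(t_prev, burn)
    total = dwell.sum()
    return dwell / total if total > 0 else dwell


def occupancy_batches(log: EventLog, network: ReactionNetwork, n_batches: int = 20) -> np.ndarray:
    """Per-batch time-weighted occupancy fractions (n_batches x n_states).

    The counting window (after burn-in) is split into equal time batches;
    the batch mean and its standard error give a correlation-robust estimate
    of the sampling uncertainty of the occupancy, suitable for z-score
    comparison against the master-equation stationary distribution.
    """
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    frm, to, *_ = _expand_transitions(network)
    edges = np.linspace(log.burn_in, log.t_total, n_batches + 1)
    occ = np.zeros((n_batches, network.n_states))

    def deposit(a: float, b: float, state: int) -> None:
        if b <= a:
            return
        i0 = max(int(np.searchsorted(edges, a, side="right")) - 1, 0)
        i1 = min(int(np.searchsorted(edges, b, side="right")) - 1, n_batches - 1)
        for k in range(i0, i1 + 1):
            lo, hi = max(a, edges[k]), min(b, edges[k + 1])
            if hi > lo:
                occ[k, state] += hi - lo

    state = log.initial_state
    t_prev = 0.0
    for t, tid in zip(log.times, log.transitions):
        deposit(max(t_prev, log.burn_in), min(t, log.t_total), state)
        state = to[tid]
        t_prev = t
    deposit(max(t_prev, log.burn_in), log.t_total, state)
    totals = occ.sum(axis=1, keepdims=True)
    np.divide(occ, totals, out=occ, where=totals > 0)
    return occ
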