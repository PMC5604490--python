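"""State/reaction enumeration, master-equation assembly and steady state.

The carrier is a continuous-time Markov chain over states <c, s> where c is
the conformational coordinate and s the binding-site occupancy (empty or one
of N substrates). With the default 21-conformation grid there are 21*(N+1)
states connected by 20*(N+1) conformational reaction pairs plus 2*N binding
reaction pairs at the two end conformations. The stationary distribution is
obtained by direct linear solve of the chemical master equation, and the
transport rate is the net flux of the tracked species across any
conformational boundary (identical across boundaries at steady state).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .energy_model import (
    ModelParams,
    binding_rates,
    conformational_rates,
)

__all__ = [
    "State",
    "Reaction",
    "ReactionNetwork",
    "SteadyStateResult",
    "build_network",
    "generator_matrix",
    "solve_steady_state",
    "net_flux",
    "transport_rate",
]

EMPTY = None  # occupancy marker for the unbound carrier


@dataclass(frozen=True)
class State:
    """A carrier state: conformation c and occupancy s (None = empty)."""

    c: int
    s: int | None

    def label(self, params: ModelParams) -> str:
        occ = "empty" if self.s is None else params.substrates[self.s].name
        return f"c={self.c:+d},{occ}"


@dataclass(frozen=True)
class Reaction:
    """A bidirectional reaction pair between two states.

    kind is 'conf' for a conformational step (j = i with c+1) or 'bind' for
    substrate binding (i empty end state, j bound end state). Rates are
    forward (i -> j) and reverse (j -> i), in 1/s.
    """

    i: int
    j: int
    forward: float
    reverse: float
    kind: str
    side: str | None = None  # binding side for kind='bind'
    species: int | None = None  # substrate index for kind='bind'


class ReactionNetwork:
    """Enumerated states and reactions with rates drawn from the energy model."""

    def __init__(self, params: ModelParams):
        self.params = params
        self.states: list[State] = []
        self.index: dict[State, int] = {}
        n = params.n_half
        occupancies: list[int | None] = [EMPTY] + list(range(len(params.substrates)))
        for s in occupancies:
            for c in range(-n, n + 1):
                st = State(c, s)
                self.index[st] = len(self.states)
                self.states.append(st)

        self.reactions: list[Reaction] = []
        for s in occupancies:
            bound = s is not EMPTY
            for c in range(-n, n):
                fwd, rev = conformational_rates(c, params, bound=bound)
                self.reactions.append(
                    Reaction(self.index[State(c, s)], self.index[State(c + 1, s)], fwd, rev, "conf")
                )
        for k, sub in enumerate(params.substrates):
            for side, c_end in (("cytoplasmic", -n), ("matrix", n)):
                on, off = binding_rates(side, sub, params)
                self.reactions.append(
                    Reaction(
                        self.index[State(c_end, EMPTY)],
                        self.index[State(c_end, k)],
                        on,
                        off,
                        "bind",
                        side=side,
                        species=k,
                    )
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_substrates(self) -> int:
        return len(self.params.substrates)

    def state_index(self, c: int, species: str | None) -> int:
        s = None if species is None else self.params.substrate_index(species)
        return self.index[State(c, s)]

    def unreachable_states(self) -> list[int]:
        """Bound ladders of substrates absent from both compartments.

        Such states have zero inbound binding rate everywhere and carry zero
        stationary probability; they are pruned before the linear solve.
        """
        out: list[int] = []
        for k, sub in enumerate(self.params.substrates):
            if sub.cyt_M == 0 and sub.mat_M == 0:
                out.extend(
                    self.index[State(c, k)]
                    for c in range(-self.params.n_half, self.params.n_half + 1)
                )
        return out


def build_network(params: ModelParams) -> ReactionNetwork:
    """Enumerate all states and reactions for the given parameters."""
    return ReactionNetwork(params)


def generator_matrix(network: ReactionNetwork, keep: Iterable[int] | None = None) -> np.ndarray:
    """Dense generator Q with Q[i, j] = rate j -> i; columns sum to zero.

    ``keep`` optionally restricts to a subset of state indices (used when
    pruning unreachable states).
    """
    n = network.n_states
    Q = np.zeros((n, n))
    for r in network.reactions:
        Q[r.j, r.i] += r.forward
        Q[r.i, r.i] -= r.forward
        Q[r.i, r.j] += r.reverse
        Q[r.j, r.j] -= r.reverse
    if keep is not None:
        keep = np.asarray(list(keep))
        Q = Q[np.ix_(keep, keep)]
    return Q


@dataclass
class SteadyStateResult:
    """Stationary distribution, boundary fluxes and derived transport rate.

    P is indexed like network.states; J maps substrate name -> net flux (1/s)
    across each of the 2*n_half boundaries c -> c+1, positive in the
    cytoplasmic -> matrix direction; transport_rate is the flux of the
    tracked species; residual is the infinity norm of Q @ P.
    """

    P: np.ndarray
    J: dict[str, np.ndarray]
    transport_rate: float
    residual: float
    pruned: list[int]

    def species_flux(self, name: str) -> float:
        return float(np.mean(self.J[name]))

    def to_json(self, network: ReactionNetwork) -> str:
        payload = {
            "states": [st.label(network.params) for st in network.states],
            "P": self.P.tolist(),
            "fluxes_per_boundary": {k: v.tolist() for k, v in self.J.items()},
            "transport_rate_per_s": self.transport_rate,
            "residual": self.residual,
        }
        return json.dumps(payload, indent=2)

    def state_frame(self, network: ReactionNetwork) -> pd.DataFrame:
        rows = [
            {
                "c": st.c,
                "occupancy": "empty" if st.s is None else network.params.substrates[st.s].name,
                "P": p,
            }
            for st, p in zip(network.states, self.P)
        ]
        return pd.DataFrame(rows)

    def flux_frame(self, network: ReactionNetwork) -> pd.DataFrame:
        n = network.params.n_half
        rows = []
        for name, arr in self.J.items():
            for b, val in enumerate(arr):
                rows.append(
                    {"species": name, "boundary": f"{b - n:+d}->{b - n + 1:+d}", "J_per_s": val}
                )
        return pd.DataFrame(rows)


def solve_steady_state(
    network: ReactionNetwork, tracked: str | None = None
) -> SteadyStateResult:
    """Solve generator @ P = 0 with sum(P) = 1 by dense linear algebra.

    One balance row is replaced by the normalisation row (the 63-state
    default system is tiny and well conditioned); the residual of the full
    balance equations is reported. Bound states of substrates absent from
    both compartments are pruned with a warning.
    """
    pruned = network.unreachable_states()
    if pruned:
        warnings.warn(
            f"pruning {len(pruned)} unreachable bound states "
            "(substrate absent from both compartments)",
            stacklevel=2,
        )
    keep = [i for i in range(network.n_states) if i not in set(pruned)]
    Q = generator_matrix(network, keep=keep)
    m = len(keep)
    A = Q.copy()
    A[-1, :] = 1.0
    b = np.zeros(m)
    b[-1] = 1.0
    p_kept = np.linalg.solve(A, b)
    residual = float(np.max(np.abs(Q @ p_kept)))

    P = np.zeros(network.n_states)
    P[keep] = p_kept
    tol = 1e-12 * P.max()
    if P.min() < -tol:
        raise RuntimeError(f"steady-state solve produced negative probability {P.min():g}")
    np.clip(P, 0.0, None, out=P)
    P /= P.sum()

    n = network.params.n_half
    J: dict[str, np.ndarray] = {}
    conf_rates: dict[tuple[int, int | None], tuple[float, float]] = {}
    for r in network.reactions:
        if r.kind == "conf":
            st = network.states[r.i]
            conf_rates[(st.c, st.s)] = (r.forward, r.reverse)
    for k, sub in enumerate(network.params.substrates):
        flux = np.empty(2 * n)
        for b_idx, c in enumerate(range(-n, n)):
            fwd, rev = conf_rates[(c, k)]
            i, j = network.index[State(c, k)], network.index[State(c + 1, k)]
            flux[b_idx] = P[i] * fwd - P[j] * rev
        J[sub.name] = flux

    result = SteadyStateResult(P=P, J=J, transport_rate=float("nan"), residual=residual, pruned=pruned)
    if network.params.substrates:
        result.transport_rate = transport_rate(result, network, tracked)
    return result


def net_flux(result: SteadyStateResult, network: ReactionNetwork, boundary: int, species: str) -> float:
    """Net flux (1/s) of ``species`` across the boundary c -> c+1.

    Positive flux is directed from the cytoplasmic (c = -n_half) towards the
    matrix (c = +n_half) conformation.
    """
    n = network.params.n_half
    if not -n <= boundary < n:
        raise ValueError(f"boundary must satisfy -{n} <= c < {n}, got {boundary}")
    return float(result.J[species][boundary + n])


def transport_rate(
    result: SteadyStateResult, network: ReactionNetwork, species: str | None = None
) -> float:
    """Transport metric: net flux of the tracked (labelled) species.

    Defaults to the substrate named 'labelled', else the first substrate.
    At steady state this influx equals the efflux of the counter-substrate
    in the symmetric exchange scenario.
    """
    if species is None:
        names = [s.name for s in network.params.substrates]
        if not names:
            raise ValueError("network has no substrates to track")
        species = "labelled" if "labelled" in names else names[0]
    if species not in result.J:
        raise ValueError(f"no such species {species!r}")
    return result.species_flux(species)
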