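"""Analytic companions to the full kinetic model.

These closed-form estimates explain why the full model behaves as it does:
the conformational distribution of the carrier is Boltzmann in the no-
induced-fit limit, the transport rate is set by the probability of reaching
the top of the free-energy profile, and the Michaelis constants follow from
a three-way decomposition of the partition function into unbound
cytoplasmic-side, unbound matrix-side and substrate-bound terms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .energy_model import ModelParams, conformations, energy_profile

__all__ = [
    "BarrierReport",
    "PartitionDecomposition",
    "boltzmann_profile",
    "forward_flux_estimate",
    "energy_barrier",
    "partition_decomposition",
    "km_from_partition",
    "saltbridges_to_mv",
    "mv_to_saltbridges",
]


def boltzmann_profile(mu0: np.ndarray, kBT: float) -> np.ndarray:
    """Equilibrium conformational probabilities P_c ~ exp(-mu0_c / kBT).

    Normalised over the supplied profile; computed with log-sum-exp so that
    profiles spanning many hundreds of mV do not overflow.
    """
    mu0 = np.asarray(mu0, dtype=float)
    if not np.all(np.isfinite(mu0)):
        raise ValueError("profile must be finite")
    log_w = -mu0 / kBT
    return np.exp(log_w - logsumexp(log_w))


def forward_flux_estimate(params: ModelParams, method: str = "boltzmann") -> float:
    """Limiting forward flux J_F = F * P_I * k_c with F = 1/2.

    F = 1/2 is the fraction of bound carrier holding the tracked (labelled)
    species under symmetric exchange. P_I, the probability of the
    intermediate conformation, is either the exact Boltzmann weight of the
    energy profile (``method="boltzmann"``, used for the sweep comparison
    against the full model) or the two-well closed form
    P_I = 1/2 * exp(-(mu_I - mu_N)/kBT) (``method="barrier"``), where mu_N is
    the end-conformation potential. The profile is the bound "net" potential
    (networks + induced fit); with no induced fit it coincides with the empty
    carrier profile.
    """
    profile = energy_profile(params, bound=True)
    n = params.n_half
    if method == "boltzmann":
        P_I = float(boltzmann_profile(profile, params.kBT)[n])
    elif method == "barrier":
        mu_I = profile[n]
        mu_N = min(profile[0], profile[-1])
        P_I = 0.5 * math.exp(-(mu_I - mu_N) / params.kBT)
    else:
        raise ValueError(f"unknown method {method!r}")
    return 0.5 * P_I * params.k_c


@dataclass(frozen=True)
class BarrierReport:
    """Max - min of a chemical-potential profile with their locations."""

    profile: np.ndarray
    conformations: np.ndarray
    max_mV: float
    min_mV: float
    barrier_mV: float
    argmax: tuple[int, ...]
    argmin: tuple[int, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "max_mV": self.max_mV,
                "min_mV": self.min_mV,
                "barrier_mV": self.barrier_mV,
                "argmax_conformations": list(self.argmax),
                "argmin_conformations": list(self.argmin),
            },
            indent=2,
        )


def energy_barrier(profile: np.ndarray, confs: np.ndarray | None = None, tie_tol: float = 1e-9) -> BarrierReport:
    """Transport energy barrier: difference between profile maximum and minimum.

    Ties within ``tie_tol`` mV are all reported (a symmetric profile has two
    equal minima at the end conformations, and with a strong induced fit two
    equal maxima flanking the intermediate conformation).
    """
    profile = np.asarray(profile, dtype=float)
    if confs is None:
        n = (len(profile) - 1) // 2
        confs = np.arange(-n, n + 1)
    hi, lo = float(profile.max()), float(profile.min())
    argmax = tuple(int(c) for c, v in zip(confs, profile) if hi - v <= tie_tol)
    argmin = tuple(int(c) for c, v in zip(confs, profile) if v - lo <= tie_tol)
    return BarrierReport(
        profile=profile,
        conformations=np.asarray(confs),
        max_mV=hi,
        min_mV=lo,
        barrier_mV=hi - lo,
        argmax=argmax,
        argmin=argmin,
    )


@dataclass(frozen=True)
class PartitionDecomposition:
    """Partial partition sums of the carrier at saturating reference.

    Z_s sums Boltzmann weights of the bound "net" profile over all
    conformations; Z_c and Z_m sum the unbound profile over the cytoplasmic
    (c < 0) and matrix (c > 0) halves, with the intermediate conformation
    split equally. The substrate-concentration factors K_d/[S] are carried
    separately so the sums are concentration-independent.
    """

    Z_c: float
    Z_m: float
    Z_s: float
    log_Z_c: float
    log_Z_m: float
    log_Z_s: float
    states_c: tuple[int, ...]
    states_m: tuple[int, ...]
    states_s: tuple[int, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "Z_c": self.Z_c,
                "Z_m": self.Z_m,
                "Z_s": self.Z_s,
                "states_c": list(self.states_c),
                "states_m": list(self.states_m),
                "states_s": list(self.states_s),
            },
            indent=2,
        )


def partition_decomposition(
    params: ModelParams, intermediate_split: float = 0.5
) -> PartitionDecomposition:
    """Decompose the partition function into Z_c, Z_m and Z_s.

    ``intermediate_split`` is the fraction of the unbound intermediate
    conformation assigned to the cytoplasmic side (the rest goes to the
    matrix side); the unbound weight is concentrated at the ends, so this
    choice perturbs the derived K_M by well under 1% at realistic strengths.
    """
    if not 0.0 <= intermediate_split <= 1.0:
        raise ValueError("intermediate_split must be in [0, 1]")
    kBT = params.kBT
    confs = conformations(params)
    log_w_empty = -energy_profile(params, bound=False) / kBT
    log_w_bound = -energy_profile(params, bound=True) / kBT

    n = params.n_half
    cyt = confs < 0
    mat = confs > 0
    mid = confs == 0
    with np.errstate(divide="ignore"):
        log_split_c = math.log(intermediate_split) if intermediate_split > 0 else -np.inf
        log_split_m = math.log(1 - intermediate_split) if intermediate_split < 1 else -np.inf
    log_Z_c = logsumexp(np.concatenate([log_w_empty[cyt], log_w_empty[mid] + log_split_c]))
    log_Z_m = logsumexp(np.concatenate([log_w_empty[mat], log_w_empty[mid] + log_split_m]))
    log_Z_s = logsumexp(log_w_bound)
    return PartitionDecomposition(
        Z_c=float(np.exp(log_Z_c)),
        Z_m=float(np.exp(log_Z_m)),
        Z_s=float(np.exp(log_Z_s)),
        log_Z_c=float(log_Z_c),
        log_Z_m=float(log_Z_m),
        log_Z_s=float(log_Z_s),
        states_c=tuple(int(c) for c in confs[cyt | mid]),
        states_m=tuple(int(c) for c in confs[mat | mid]),
        states_s=tuple(int(c) for c in confs),
    )


def km_from_partition(decomp: PartitionDecomposition, Kd: float) -> tuple[float, float]:
    """Michaelis constants (M) from the partition decomposition.

    K_M^cyt = (Z_c / Z_s) * K_d and K_M^mat = (Z_m / Z_s) * K_d: the
    substrate-side K_M shrinks below K_d exactly when the bound sum Z_s
    dominates the unbound sum on that side.
    """
    if Kd <= 0:
        raise ValueError("Kd must be > 0")
    km_c = Kd * math.exp(decomp.log_Z_c - decomp.log_Z_s)
    km_m = Kd * math.exp(decomp.log_Z_m - decomp.log_Z_s)
    return km_c, km_m


def saltbridges_to_mv(n_bridges: float) -> float:
    """Map a network strength in salt-bridge equivalents to millivolts.

    Linear registration of the experimental mutant series against the model:
    dE(mV) = -130 * N - 240.
    """
    return -130.0 * n_bridges - 240.0


def mv_to_saltbridges(dE_mV: float) -> float:
    """Inverse of :func:`saltbridges_to_mv`: N = -(dE + 240)/130."""
    return -(dE_mV + 240.0) / 130.0
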