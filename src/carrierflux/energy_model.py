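"""Free-energy profile and rate constants of the alternating-access carrier.

The carrier's conformational change from the cytoplasmic conformation
(c = -n_half) through the intermediate (c = 0) to the matrix conformation
(c = +n_half) is discretised into 2*n_half + 1 steps. The standard chemical
potential of each state is the sum of Gaussian contributions from the matrix
and cytoplasmic salt-bridge networks and, for substrate-bound states, a
conformation-dependent induced-fit term plus the concentration-dependent
binding energy. Rate constants between neighbouring conformations follow from
a symmetric Boltzmann split of the free-energy difference, which guarantees
detailed balance along the conformational ladder.

All energies are expressed in millivolts (single elementary charge scale,
10.36 mV per kJ/mol), concentrations in molar, rates in 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "Substrate",
    "ModelParams",
    "thermal_energy_mv",
    "kjmol_to_mv",
    "network_energy",
    "binding_energy",
    "chemical_potential",
    "energy_profile",
    "conformations",
    "conformational_rates",
    "binding_rates",
]

GAS_CONSTANT = 8.31446261815324  # J / (mol K)
FARADAY = 96485.33212331001  # C / mol
ABSOLUTE_ZERO_C = -273.15


def thermal_energy_mv(temperature: float) -> float:
    """Thermal energy k_B*T on the millivolt scale (1000*R*T/F).

    Parameters
    ----------
    temperature : float
        Temperature in degrees Celsius; must exceed absolute zero.

    Returns
    -------
    float
        k_B*T in mV (26.73 mV at 37 degC).
    """
    if temperature < ABSOLUTE_ZERO_C:
        raise ValueError(
            f"temperature {temperature} degC is below absolute zero ({ABSOLUTE_ZERO_C})"
        )
    kelvin = temperature - ABSOLUTE_ZERO_C
    return 1000.0 * GAS_CONSTANT * kelvin / FARADAY


def kjmol_to_mv(energy_kjmol: float) -> float:
    """Convert a molar energy in kJ/mol to millivolts (1 kJ/mol = 10.36 mV)."""
    return 1000.0 * energy_kjmol * 1000.0 / FARADAY


@dataclass(frozen=True)
class Substrate:
    """A transportable species with per-compartment concentrations (molar)."""

    name: str
    cyt_M: float
    mat_M: float

    def __post_init__(self) -> None:
        if self.cyt_M < 0 or self.mat_M < 0:
            raise ValueError(f"substrate {self.name!r}: concentrations must be >= 0")


def _default_substrates() -> tuple[Substrate, ...]:
    # Exchange conditions: labelled ADP outside, unlabelled inside, 5 mM each.
    return (
        Substrate("labelled", cyt_M=5e-3, mat_M=0.0),
        Substrate("unlabelled", cyt_M=0.0, mat_M=5e-3),
    )


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the carrier model.

    Defaults are the published calibration for the fungal ADP/ATP carrier:
    network and induced-fit strengths of -550 mV, K_d = 40 uM,
    k_f = 2.5e10 /M/s (25 /ns/M), k_r = 1e6 /s, k_c = 5.66e6 /s at 37 degC.

    Attributes
    ----------
    dE_M, dE_C : float
        Energy scales (mV) of the matrix and cytoplasmic salt-bridge
        networks; negative values are stabilising. The matrix network is
        engaged in the cytoplasmic conformation and vice versa.
    dE_S : float
        Induced-fit substrate binding energy scale (mV), peaked at the
        intermediate conformation.
    Kd : float
        Substrate dissociation constant (M) in the end conformations,
        without the induced fit.
    k_f, k_r : float
        Substrate binding (per molar per second) and release (per second)
        rate constants; k_r = k_f * Kd is enforced.
    k_c : float
        Base conformational rate (per second) at zero free-energy change.
    temperature : float
        Temperature in degrees Celsius.
    n_half : int
        Half-width of the conformational grid; 2*n_half + 1 conformations.
    w_M, w_C, w_S : float
        Gaussian width denominators; default None scales them with n_half
        (n_half/2, n_half/2, 0.4*n_half -> 5, 5, 4 on the default grid).
    substrates : tuple of Substrate
        Species that bind mutually exclusively; identical rate constants.
    consistent_binding_edges : bool
        If True, fold the induced-fit tail at the end conformations into the
        release rate so the binding step exactly matches the bound-state
        chemical potential; default False keeps the literal k_f*[S] / k_r.
    """

    dE_M: float = -550.0
    dE_C: float = -550.0
    dE_S: float = -550.0
    Kd: float = 4e-5
    k_f: float = 2.5e10
    k_r: float = 1e6
    k_c: float = 5.66e6
    temperature: float = 37.0
    n_half: int = 10
    w_M: float | None = None
    w_C: float | None = None
    w_S: float | None = None
    substrates: tuple[Substrate, ...] = field(default_factory=_default_substrates)
    consistent_binding_edges: bool = False

    def __post_init__(self) -> None:
        errors: list[str] = []
        if self.n_half < 1:
            errors.append(f"n_half must be >= 1, got {self.n_half}")
        if self.Kd <= 0:
            errors.append(f"Kd must be > 0, got {self.Kd}")
        for key in ("k_f", "k_r", "k_c"):
            if getattr(self, key) <= 0:
                errors.append(f"{key} must be > 0, got {getattr(self, key)}")
        if self.temperature <= ABSOLUTE_ZERO_C:
            errors.append(f"temperature must exceed {ABSOLUTE_ZERO_C} degC")
        # apply default width scaling before validating widths
        if self.w_M is None:
            object.__setattr__(self, "w_M", self.n_half / 2.0)
        if self.w_C is None:
            object.__setattr__(self, "w_C", self.n_half / 2.0)
        if self.w_S is None:
            object.__setattr__(self, "w_S", 0.4 * self.n_half)
        for key in ("w_M", "w_C", "w_S"):
            if getattr(self, key) <= 0:
                errors.append(f"{key} must be > 0, got {getattr(self, key)}")
        if not isinstance(self.substrates, tuple):
            object.__setattr__(self, "substrates", tuple(self.substrates))
        names = [s.name for s in self.substrates]
        if len(set(names)) != len(names):
            errors.append(f"duplicate substrate names in {names}")
        # Eq. 5 consistency: the release rate is fixed by k_f and Kd.
        if self.k_f > 0 and self.Kd > 0 and self.k_r > 0:
            if abs(self.k_r - self.k_f * self.Kd) > 1e-6 * self.k_r:
                errors.append(
                    f"k_r must equal k_f*Kd = {self.k_f * self.Kd:g} /s "
                    f"(got {self.k_r:g} /s)"
                )
        if errors:
            raise ValueError("; ".join(errors))

    @property
    def kBT(self) -> float:
        """Thermal energy in mV at the model temperature."""
        return thermal_energy_mv(self.temperature)

    @property
    def n_conformations(self) -> int:
        return 2 * self.n_half + 1

    def substrate_index(self, name: str) -> int:
        for i, s in enumerate(self.substrates):
            if s.name == name:
                return i
        raise KeyError(f"unknown substrate {name!r}")

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with fields replaced (validation re-runs)."""
        return replace(self, **changes)

    def with_networks(
        self,
        dE_M: float | None = None,
        dE_C: float | None = None,
        dE_S: float | None = None,
    ) -> "ModelParams":
        changes = {}
        if dE_M is not None:
            changes["dE_M"] = dE_M
        if dE_C is not None:
            changes["dE_C"] = dE_C
        if dE_S is not None:
            changes["dE_S"] = dE_S
        return replace(self, **changes)

    def with_substrates(self, substrates: Sequence[Substrate]) -> "ModelParams":
        return replace(self, substrates=tuple(substrates))


def conformations(params: ModelParams) -> np.ndarray:
    """Integer conformational coordinate grid, -n_half .. +n_half."""
    return np.arange(-params.n_half, params.n_half + 1)


def network_energy(c, scale: float, center: float, width: float):
    """Gaussian interaction energy scale*exp(-((c-center)/width)^2) in mV."""
    if width <= 0:
        raise ValueError(f"width must be > 0, got {width}")
    c = np.asarray(c, dtype=float)
    out = scale * np.exp(-(((c - center) / width) ** 2))
    return out if out.ndim else float(out)


def binding_energy(concentration: float, Kd: float, kBT: float) -> float:
    """Concentration-dependent binding free energy -kBT*ln([S]/Kd) in mV.

    Zero concentration returns +inf (an unbindable substrate); rate
    calculations never use this path because the on-rate k_f*[S] is then 0.
    """
    if Kd <= 0:
        raise ValueError(f"Kd must be > 0, got {Kd}")
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    if concentration == 0:
        return math.inf
    return -kBT * math.log(concentration / Kd)


def chemical_potential(
    c,
    params: ModelParams,
    bound: bool = False,
    concentration: float | None = None,
):
    """Standard chemical potential mu0(c, s) in mV.

    The empty carrier feels only the two network terms. A bound carrier
    additionally feels the induced-fit Gaussian dE_S*exp(-(c/w_S)^2) and,
    when ``concentration`` is given, the binding energy -kBT*ln([S]/Kd).
    Omitting ``concentration`` yields the "net" bound potential used by the
    barrier and partition analyses, where the concentration factor is carried
    separately as Kd/[S].
    """
    n = params.n_half
    c_arr = np.asarray(c)
    if np.any(np.abs(c_arr) > n):
        raise ValueError(f"conformation out of range [-{n}, {n}]")
    mu = network_energy(c, params.dE_M, -n, params.w_M) + network_energy(
        c, params.dE_C, +n, params.w_C
    )
    if bound:
        mu = mu + network_energy(c, params.dE_S, 0.0, params.w_S)
        if concentration is not None:
            mu = mu + binding_energy(concentration, params.Kd, params.kBT)
    return mu


def energy_profile(
    params: ModelParams,
    bound: bool = False,
    concentration: float | None = None,
) -> np.ndarray:
    """Chemical-potential profile (mV) over the full conformational grid."""
    return chemical_potential(conformations(params), params, bound, concentration)


def conformational_rates(c: int, params: ModelParams, bound: bool = False):
    """Forward/reverse rates (1/s) for the step c -> c+1 at occupancy s.

    The free-energy change dG0 = mu0(c+1) - mu0(c) (the concentration term
    cancels) is split symmetrically: forward = k_c*exp(-dG0/2kBT),
    reverse = k_c*exp(+dG0/2kBT), so forward/reverse = exp(-dG0/kBT).
    """
    n = params.n_half
    if not -n <= c < n:
        raise ValueError(f"step start must satisfy -{n} <= c < {n}, got {c}")
    dG0 = chemical_potential(c + 1, params, bound) - chemical_potential(c, params, bound)
    x = 0.5 * dG0 / params.kBT
    return params.k_c * math.exp(-x), params.k_c * math.exp(x)


def binding_rates(side: str, substrate: Substrate, params: ModelParams):
    """On/off rates (1/s) for binding at an end conformation.

    Binding is only allowed in the cytoplasmic (c = -n_half) and matrix
    (c = +n_half) conformations: on = k_f*[S]_side, off = k_r. With
    ``consistent_binding_edges`` the release rate absorbs the (tiny)
    induced-fit tail so the edge thermodynamics match the bound profile.
    """
    if side == "cytoplasmic":
        conc = substrate.cyt_M
    elif side == "matrix":
        conc = substrate.mat_M
    else:
        raise ValueError(f"side must be 'cytoplasmic' or 'matrix', got {side!r}")
    on = params.k_f * conc
    off = params.k_r
    if params.consistent_binding_edges:
        tail = params.dE_S * math.exp(-((params.n_half / params.w_S) ** 2))
        off = off * math.exp(tail / params.kBT)
    return on, off
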