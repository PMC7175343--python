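"""Pairwise and surface interaction energies.

All energies are returned in units of kBT.  The model contains four terms:

* screened Coulomb (Debye–Hückel) between point charges at sphere centers,
  with a hard core at contact and the finite-size ``1/(1+kappa*sigma)``
  correction;
* a harmonic bond between consecutive beads of a flexible chain;
* a weak Lennard-Jones well between non-bonded chain beads;
* a Gouy–Chapman diffuse-double-layer potential between each charged bead
  and a uniformly charged planar wall.

Nanoparticles are charged spheres whose total charge matches the wall's
surface charge density; they interact with beads through the same screened
Coulomb term with the contact distance equal to the sum of the radii.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conditions import SolutionConditions
from .constants import (
    AVOGADRO,
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    VACUUM_PERMITTIVITY,
)

__all__ = [
    "BondSpec", "PairParams", "SurfaceField",
    "dh_pair_energy", "bond_energy", "lj_energy",
    "gc_gamma0", "gc_energy", "np_charge", "np_bead_energy",
]


@dataclass(frozen=True)
class BondSpec:
    """Harmonic bond: w = kh (Rb - Req)^2, kh in kBT/Å^2, Req in Å."""

    kh: float = 0.76
    req: float = 4.1

    def __post_init__(self) -> None:
        if self.kh <= 0 or self.req <= 0:
            raise ValueError("bond constants must be positive")


@dataclass(frozen=True)
class PairParams:
    """Lennard-Jones well depth (kBT); contact distance is radius sum."""

    eps_nb: float = 0.05

    def __post_init__(self) -> None:
        if self.eps_nb < 0:
            raise ValueError("LJ strength must be non-negative")


@dataclass(frozen=True)
class SurfaceField:
    """Precomputed Gouy-Chapman field of a uniformly charged wall.

    ``rho`` is the surface charge density in e/Å^2 (signed), ``gamma0`` the
    dimensionless surface term and ``kappa`` the inverse Debye length in
    Å^-1.  ``gamma0`` and ``rho`` always share a sign and |gamma0| < 1.
    """

    rho: float
    gamma0: float
    kappa: float

    @classmethod
    def from_conditions(
        cls, rho: float, cond: SolutionConditions
    ) -> "SurfaceField":
        return cls(
            rho=rho,
            gamma0=gc_gamma0(rho, cond.salt_molar, cond),
            kappa=cond.kappa,
        )


def dh_pair_energy(
    zi: float, zj: float, rij: float, sigma_ij: float,
    kappa: float, cond: SolutionConditions,
) -> float:
    """Screened Coulomb energy of two charges at separation ``rij`` (kBT).

    Hard spheres: returns +inf for ``rij < sigma_ij``.  In the unscreened
    limit (kappa -> 0) this reduces to the bare Coulomb energy
    ``lB zi zj / rij``.
    """
    if rij < sigma_ij:
        return math.inf
    if zi == 0.0 or zj == 0.0:
        return 0.0
    lb = cond.bjerrum_length()
    return (
        lb * zi * zj
        * math.exp(-kappa * (rij - sigma_ij))
        / (rij * (1.0 + kappa * sigma_ij))
    )


def dh_pair_energy_array(
    qq: np.ndarray, rij: np.ndarray, sigma_ij: np.ndarray,
    kappa: float, bjerrum: float,
) -> np.ndarray:
    """Vectorized screened Coulomb; ``qq`` is the charge product array.

    Overlapping pairs (rij < sigma_ij) map to +inf.
    """
    rij = np.asarray(rij, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (
            bjerrum * qq * np.exp(-kappa * (rij - sigma_ij))
            / (rij * (1.0 + kappa * sigma_ij))
        )
    return np.where(rij < sigma_ij, np.inf, w)


def bond_energy(rb: float, spec: BondSpec) -> float:
    """Harmonic bond energy kh (Rb - Req)^2 in kBT."""
    return spec.kh * (rb - spec.req) ** 2


def lj_energy(rij: float, sigma_ij: float, pp: PairParams) -> float:
    """Lennard-Jones energy 4 eps [(sigma/r)^12 - (sigma/r)^6] in kBT."""
    sr6 = (sigma_ij / rij) ** 6
    return 4.0 * pp.eps_nb * (sr6 * sr6 - sr6)


def gc_gamma0(rho: float, c0: float, cond: SolutionConditions) -> float:
    """Dimensionless Gouy-Chapman surface term for a 1:1 salt.

    ``rho`` in e/Å^2 and ``c0`` in mol/L are converted to SI internally:
    Gamma0 = tanh( (1/2) asinh( rho / sqrt(8 kB T c0 eps0 epsr) ) ) with
    rho in C/m^2 and c0 as an ion number density in 1/m^3.  Odd in rho and
    strictly inside (-1, 1).
    """
    if c0 <= 0:
        raise ValueError("salt concentration must be positive")
    rho_si = rho * ELEMENTARY_CHARGE * 1.0e20  # C/m^2
    n0 = c0 * 1.0e3 * AVOGADRO                 # ions/m^3 per species
    denom = math.sqrt(
        8.0 * BOLTZMANN * cond.temperature * n0
        * VACUUM_PERMITTIVITY * cond.rel_permittivity
    )
    return math.tanh(0.5 * math.asinh(rho_si / denom))


def gc_energy(
    zi: float, rs: float, field: SurfaceField,
    hard_wall_at: float = 0.0,
) -> float:
    """Charge-wall energy 2 zi ln[(1+G e^-kr)/(1-G e^-kr)] in kBT.

    ``rs`` is the distance from the wall plane to the bead center; beads
    closer than ``hard_wall_at`` (typically their radius) see +inf.
    """
    if rs < hard_wall_at:
        return math.inf
    if zi == 0.0:
        return 0.0
    g = field.gamma0 * math.exp(-field.kappa * rs)
    return 2.0 * zi * math.log((1.0 + g) / (1.0 - g))


def gc_energy_array(
    charges: np.ndarray, rs: np.ndarray, field: SurfaceField,
    hard_wall_at: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Vectorized charge-wall energy; overlap with the wall maps to +inf."""
    rs = np.asarray(rs, dtype=float)
    g = field.gamma0 * np.exp(-field.kappa * rs)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 2.0 * charges * np.log((1.0 + g) / (1.0 - g))
    w = np.where(charges == 0.0, 0.0, w)
    return np.where(rs < hard_wall_at, np.inf, w)


def np_charge(rho: float, radius: float) -> int:
    """Nanoparticle charge 4 pi R^2 rho rounded to an integer (e)."""
    if radius <= 0:
        raise ValueError("nanoparticle radius must be positive")
    return int(round(4.0 * math.pi * radius**2 * rho))


def np_bead_energy(
    np_charge_e: float, np_radius: float, np_center: np.ndarray,
    bead_charge: float, bead_radius: float, bead_pos: np.ndarray,
    kappa: float, cond: SolutionConditions,
    displacement=None,
) -> float:
    """Screened Coulomb energy between a nanoparticle and one bead (kBT).

    The contact distance is the sum of the two radii, so a bead center
    inside the nanoparticle surface shell is a hard-core overlap (+inf).
    ``displacement`` may provide a minimum-image displacement function.
    """
    d = np.asarray(bead_pos, float) - np.asarray(np_center, float)
    if displacement is not None:
        d = displacement(np.asarray(np_center, float), np.asarray(bead_pos, float))
    rij = float(np.linalg.norm(d))
    return dh_pair_energy(
        np_charge_e, bead_charge, rij, np_radius + bead_radius, kappa, cond
    )
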