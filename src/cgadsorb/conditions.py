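"""Solution conditions: temperature, permittivity and screening.

The electrolyte enters the model only through two derived quantities, the
Bjerrum length and the Debye screening length.  Both are computed here in SI
and returned in Å so that the rest of the package never touches SI units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    VACUUM_PERMITTIVITY,
)

__all__ = ["SolutionConditions", "debye_length", "bjerrum_length"]


@dataclass(frozen=True)
class SolutionConditions:
    """Aqueous 1:1 electrolyte at fixed temperature.

    Parameters
    ----------
    temperature:
        Absolute temperature in K.  Defaults to 298.15 K.
    rel_permittivity:
        Relative permittivity of the solvent (78.5 for water).
    salt_molar:
        Concentration of 1:1 salt in mol/L; for a pure 1:1 salt the ionic
        strength equals the concentration.
    ionic_strength:
        Ionic strength in mol/L; defaults to ``salt_molar``.
    """

    temperature: float = 298.15
    rel_permittivity: float = 78.5
    salt_molar: float = 0.025
    ionic_strength: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.rel_permittivity <= 0:
            raise ValueError("relative permittivity must be positive")
        if self.ionic_strength is None:
            object.__setattr__(self, "ionic_strength", self.salt_molar)

    @property
    def kT_joule(self) -> float:
        return BOLTZMANN * self.temperature

    def debye_length(self) -> float:
        """Debye screening length kappa^-1 in Å."""
        return debye_length(self)

    @property
    def kappa(self) -> float:
        """Inverse Debye length in Å^-1."""
        return 1.0 / self.debye_length()

    def bjerrum_length(self) -> float:
        """Bjerrum length in Å (≈7.1 Å in water at room temperature)."""
        return bjerrum_length(self)

    def to_dict(self) -> dict:
        return {
            "temperature_K": self.temperature,
            "rel_permittivity": self.rel_permittivity,
            "salt_molar_M": self.salt_molar,
            "ionic_strength_M": self.ionic_strength,
            "debye_length_A": self.debye_length(),
            "bjerrum_length_A": self.bjerrum_length(),
        }


def debye_length(cond: SolutionConditions) -> float:
    """Debye length kappa^-1 = sqrt(eps0*epsr*kB*T / (2e3*NA*e^2*I)), in Å.

    ``I`` is the ionic strength in mol/L; the factor 1e3 converts it to
    mol/m^3.  Raises ``ValueError`` for non-positive ionic strength.
    """
    if cond.ionic_strength <= 0:
        raise ValueError("ionic strength must be positive for a Debye length")
    num = VACUUM_PERMITTIVITY * cond.rel_permittivity * cond.kT_joule
    den = 2.0e3 * AVOGADRO * ELEMENTARY_CHARGE**2 * cond.ionic_strength
    return math.sqrt(num / den) * 1.0e10


def bjerrum_length(cond: SolutionConditions) -> float:
    """Bjerrum length e^2/(4 pi eps0 epsr kB T) in Å."""
    num = ELEMENTARY_CHARGE**2
    den = (
        4.0 * math.pi * VACUUM_PERMITTIVITY * cond.rel_permittivity
        * cond.kT_joule
    )
    return num / den * 1.0e10
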