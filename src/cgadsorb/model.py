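"""Bead models: the coarse-grained representation of proteins and ions.

A :class:`BeadModel` is an ordered set of spheres, each carrying a position,
radius, point charge (in elementary charges, located at the sphere center),
mass and a label.  Rigid bodies (one bead per resolved residue of a crystal
structure) have no bonds; flexible chains are linear bead-spring polymers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ION_MASSES, RESIDUE_MASSES, TERMINAL_MASSES

logger = logging.getLogger(__name__)

__all__ = ["ResidueRecord", "BeadModel", "ChargeRules", "net_charge"]


@dataclass
class ResidueRecord:
    """One residue (or hetero ion) of a parsed structure.

    ``resolved`` distinguishes residues present in the coordinate section
    from residues known only from the sequence records (unresolved in the
    electron density).  ``atoms`` maps atom names to (element, position).
    """

    chain_id: str
    residue_index: int
    residue_name: str
    atoms: list[tuple[str, str, np.ndarray]] = field(default_factory=list)
    resolved: bool = True
    is_ion: bool = False

    def atom_position(self, name: str) -> np.ndarray | None:
        for atom_name, _el, pos in self.atoms:
            if atom_name == name:
                return pos
        return None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class BeadModel:
    """Ordered collection of charged spheres, optionally bonded.

    Invariants: ``rigid`` models have no bonds; every radius is positive;
    in a linear flexible chain every bead except the two ends has exactly
    two bonds.
    """

    positions: np.ndarray          # (N, 3) Å
    radii: np.ndarray              # (N,) Å
    charges: np.ndarray            # (N,) e
    masses: np.ndarray             # (N,) Da
    labels: list[str]              # residue 3-letter code, ION:<el>, NTERM, CTERM
    bonds: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.intp)
    )
    rigid: bool = True

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        self.masses = np.asarray(self.masses, dtype=float).ravel()
        self.bonds = np.asarray(self.bonds, dtype=np.intp).reshape(-1, 2)
        n = len(self.positions)
        if not (len(self.radii) == len(self.charges) == len(self.masses)
                == len(self.labels) == n):
            raise ValueError("inconsistent bead array lengths")
        if np.any(self.radii <= 0):
            raise ValueError("all bead radii must be positive")
        if self.rigid and len(self.bonds):
            raise ValueError("a rigid model cannot carry bonds")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def center_of_mass(self, positions: np.ndarray | None = None) -> np.ndarray:
        pos = self.positions if positions is None else positions
        return np.average(pos, axis=0, weights=self.masses)

    def max_extent(self) -> float:
        """Largest pairwise bead center separation, in Å."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return float(np.sqrt((d ** 2).sum(axis=-1)).max())

    def with_positions(self, positions: np.ndarray) -> "BeadModel":
        return replace(self, positions=np.asarray(positions, dtype=float))

    def copy(self) -> "BeadModel":
        return BeadModel(
            positions=self.positions.copy(),
            radii=self.radii.copy(),
            charges=self.charges.copy(),
            masses=self.masses.copy(),
            labels=list(self.labels),
            bonds=self.bonds.copy(),
            rigid=self.rigid,
        )


@dataclass(frozen=True)
class ChargeRules:
    """Integer charges of titratable groups at a given pH (default 7.4).

    Asp and Glu are fully deprotonated (−1), Lys and Arg fully protonated
    (+1); His is taken as neutral, as are Cys and Tyr.  Chain termini carry
    +1 (N) and −1 (C) unless the terminus is truncated in the coordinates,
    in which case it is neutral.  Bound ions carry their formal charge.
    """

    residue_charges: dict = field(default_factory=lambda: {
        "ASP": -1.0, "GLU": -1.0, "LYS": +1.0, "ARG": +1.0, "HIS": 0.0,
    })
    n_terminal_charge: float = +1.0
    c_terminal_charge: float = -1.0
    ion_charges: dict = field(default_factory=lambda: {
        "CA": +2.0, "MG": +2.0, "ZN": +2.0, "NA": +1.0, "K": +1.0,
        "CL": -1.0,
    })

    def residue_charge(self, residue_name: str) -> float:
        name = residue_name.upper()
        if name in self.residue_charges:
            return self.residue_charges[name]
        if name in RESIDUE_MASSES:
            return 0.0
        logger.warning("unknown residue label %r: assigning charge 0", name)
        return 0.0

    def ion_charge(self, element: str) -> float:
        el = element.upper()
        if el not in self.ion_charges:
            logger.warning("unknown ion element %r: assigning charge 0", el)
            return 0.0
        return self.ion_charges[el]


def assign_charges(model: BeadModel, rules: ChargeRules | None = None) -> BeadModel:
    """Return a copy of ``model`` with charges set from ``rules``.

    Idempotent: labels fully determine the charges, so reapplying the rules
    leaves a previously charged model unchanged.  Labels of the form
    ``CTERM:truncated`` (emitted by the structure builder for chains whose
    terminal residues are unresolved) receive charge 0.
    """
    rules = rules or ChargeRules()
    out = model.copy()
    for i, label in enumerate(out.labels):
        if label.startswith("ION:"):
            out.charges[i] = rules.ion_charge(label.split(":", 1)[1])
        elif label == "NTERM":
            out.charges[i] = rules.n_terminal_charge
        elif label == "CTERM":
            out.charges[i] = rules.c_terminal_charge
        elif label.startswith(("NTERM:", "CTERM:")):
            out.charges[i] = 0.0
        else:
            out.charges[i] = rules.residue_charge(label)
    return out


def net_charge(model: BeadModel) -> float:
    """Total charge of the model in elementary charges."""
    return float(model.charges.sum())


def bead_mass(label: str) -> float:
    """Mass in Da for a bead label (residue code, ION:<el>, NTERM, CTERM)."""
    if label.startswith("ION:"):
        return ION_MASSES.get(label.split(":", 1)[1].upper(), 0.0)
    base = label.split(":", 1)[0]
    if base in TERMINAL_MASSES:
        return TERMINAL_MASSES[base]
    return RESIDUE_MASSES.get(label.upper(), 110.0)
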