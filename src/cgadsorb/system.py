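"""Assembled simulation systems and total-energy evaluation.

An :class:`AdsorptionSystem` couples one bead model (rigid body or flexible
chain) to solution conditions, a simulation cell and a surface layout, and
evaluates total energies in kBT:

* rigid bodies: wall (Gouy-Chapman) + nanoparticle (screened Coulomb) terms
  plus hard-core checks — no intramolecular terms;
* flexible chains: additionally harmonic bonds plus screened Coulomb and
  Lennard-Jones over non-bonded bead pairs.

The xy minimum-image convention applies throughout; +inf from any hard-core
overlap propagates to the total.  ``energy_delta`` provides exact
incremental differences for Monte Carlo moves (it recomputes every term
that touches a moved bead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditions import SolutionConditions
from .geometry import SimulationCell, SurfaceLayout, min_image_displacement
from .interactions import (
    BondSpec,
    PairParams,
    SurfaceField,
    dh_pair_energy_array,
    gc_energy_array,
)
from .model import BeadModel

__all__ = ["AdsorptionSystem"]


@dataclass
class AdsorptionSystem:
    model: BeadModel
    conditions: SolutionConditions
    cell: SimulationCell
    layout: SurfaceLayout
    bond_spec: BondSpec = field(default_factory=BondSpec)
    pair_params: PairParams = field(default_factory=PairParams)
    use_lj: bool = True            # LJ between non-bonded chain beads
    use_intra_dh: bool = True      # screened Coulomb between chain beads
    exclude_bonded: bool = True    # bonded neighbors skip DH/LJ (keep hard core)
    dh_cutoff: float | None = None  # optional interaction cutoff, Å
    intra_hard_core: bool = True   # phantom chains (ideal-limit checks) set False

    def __post_init__(self) -> None:
        self.field = SurfaceField.from_conditions(
            self.layout.rho, self.conditions
        )
        self.kappa = self.conditions.kappa
        self.bjerrum = self.conditions.bjerrum_length()
        self._np_centers, self._np_radii, self._np_charges = (
            self.layout.np_arrays()
        )
        # bonded-pair lookup for nonbonded exclusions
        self._bond_set = {tuple(sorted(b)) for b in map(tuple, self.model.bonds)}
        self._excl = np.zeros(
            (self.model.n_beads, self.model.n_beads), dtype=bool
        )
        if self.exclude_bonded:
            for i, j in self._bond_set:
                self._excl[i, j] = self._excl[j, i] = True
        np.fill_diagonal(self._excl, True)

    # -- geometry helpers -------------------------------------------------

    def displacement(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        if self.layout.kind == "single_np":
            return np.asarray(b, float) - np.asarray(a, float)
        return min_image_displacement(a, b, self.cell)

    # -- energy terms ------------------------------------------------------

    def wall_energy(self, positions: np.ndarray, idx=None) -> float:
        """Gouy-Chapman wall term + floor/ceiling hard walls, in kBT."""
        if not self.layout.has_wall:
            return 0.0
        pos = positions if idx is None else positions[idx]
        radii = self.model.radii if idx is None else self.model.radii[idx]
        charges = self.model.charges if idx is None else self.model.charges[idx]
        z = pos[:, 2]
        if np.any(z < radii) or np.any(z > self.cell.lz - radii):
            return np.inf
        if self.field.gamma0 == 0.0:
            return 0.0
        w = gc_energy_array(charges, z, self.field, hard_wall_at=0.0)
        return float(w.sum())

    def np_energy(self, positions: np.ndarray, idx=None) -> float:
        """Nanoparticle-bead screened Coulomb + hard cores, in kBT."""
        if len(self._np_centers) == 0:
            return 0.0
        pos = positions if idx is None else positions[idx]
        radii = self.model.radii if idx is None else self.model.radii[idx]
        charges = self.model.charges if idx is None else self.model.charges[idx]
        d = self.displacement(self._np_centers[:, None, :], pos[None, :, :])
        rij = np.sqrt((d ** 2).sum(axis=-1))            # (K, n)
        sigma = self._np_radii[:, None] + radii[None, :]
        if np.any(rij < sigma):
            return np.inf
        qq = self._np_charges[:, None] * charges[None, :]
        w = dh_pair_energy_array(qq, rij, sigma, self.kappa, self.bjerrum)
        if self.dh_cutoff is not None:
            w = np.where(rij - sigma > self.dh_cutoff, 0.0, w)
        return float(w.sum())

    def confinement_energy(self, positions: np.ndarray) -> float:
        """Hard spherical confinement for single-nanoparticle systems."""
        if self.layout.kind != "single_np" or self.layout.confine_radius is None:
            return 0.0
        com = self.model.center_of_mass(positions)
        center = self._np_centers[0]
        if np.linalg.norm(com - center) > self.layout.confine_radius:
            return np.inf
        return 0.0

    def external_energy(self, positions: np.ndarray, idx=None) -> float:
        e = self.wall_energy(positions, idx)
        if not np.isfinite(e):
            return np.inf
        e2 = self.np_energy(positions, idx)
        return e + e2

    def bond_energies(self, positions: np.ndarray, bond_mask=None) -> float:
        bonds = self.model.bonds
        if len(bonds) == 0:
            return 0.0
        if bond_mask is not None:
            bonds = bonds[bond_mask]
            if len(bonds) == 0:
                return 0.0
        d = self.displacement(positions[bonds[:, 0]], positions[bonds[:, 1]])
        rb = np.sqrt((d ** 2).sum(axis=-1))
        return float(
            (self.bond_spec.kh * (rb - self.bond_spec.req) ** 2).sum()
        )

    def _pair_energy_block(
        self, positions: np.ndarray, ii: np.ndarray, jj: np.ndarray
    ) -> float:
        """Summed DH + LJ + hard core over the pair lists (ii[k], jj[k])."""
        if len(ii) == 0 or not (
            self.use_intra_dh or self.use_lj or self.intra_hard_core
        ):
            return 0.0
        d = self.displacement(positions[ii], positions[jj])
        rij = np.sqrt((d ** 2).sum(axis=-1))
        radii = self.model.radii
        sigma = radii[ii] + radii[jj]
        if self.intra_hard_core and np.any(rij < sigma):
            return np.inf
        rij = np.maximum(rij, 1e-12)
        total = 0.0
        if self.use_intra_dh:
            qq = self.model.charges[ii] * self.model.charges[jj]
            w = dh_pair_energy_array(qq, rij, sigma, self.kappa, self.bjerrum)
            if self.dh_cutoff is not None:
                w = np.where(rij - sigma > self.dh_cutoff, 0.0, w)
            total += float(w.sum())
        if self.use_lj:
            sr6 = (sigma / rij) ** 6
            total += float(
                (4.0 * self.pair_params.eps_nb * (sr6 * sr6 - sr6)).sum()
            )
        return total

    def _hard_core_only_block(
        self, positions: np.ndarray, ii: np.ndarray, jj: np.ndarray
    ) -> float:
        """Hard-core check for excluded (bonded) pairs: 0 or +inf."""
        if len(ii) == 0:
            return 0.0
        if not self.intra_hard_core:
            return 0.0
        d = self.displacement(positions[ii], positions[jj])
        rij = np.sqrt((d ** 2).sum(axis=-1))
        sigma = self.model.radii[ii] + self.model.radii[jj]
        return np.inf if np.any(rij < sigma) else 0.0

    def nonbonded_energy(self, positions: np.ndarray) -> float:
        """All intra-chain pair terms (full upper triangle)."""
        n = self.model.n_beads
        iu, ju = np.triu_indices(n, k=1)
        keep = ~self._excl[iu, ju]
        e = self._pair_energy_block(positions, iu[keep], ju[keep])
        if not np.isfinite(e):
            return np.inf
        e += self._hard_core_only_block(positions, iu[~keep], ju[~keep])
        return e

    def internal_energy(self, positions: np.ndarray) -> float:
        if self.model.rigid:
            return 0.0
        e = self.nonbonded_energy(positions)
        if not np.isfinite(e):
            return np.inf
        return e + self.bond_energies(positions)

    def total_energy(self, positions: np.ndarray | None = None) -> float:
        """Full system energy in kBT; +inf on any hard-core overlap."""
        pos = self.model.positions if positions is None else positions
        e = self.confinement_energy(pos)
        if not np.isfinite(e):
            return np.inf
        e += self.external_energy(pos)
        if not np.isfinite(e):
            return np.inf
        e += self.internal_energy(pos)
        return e

    # -- incremental bookkeeping -------------------------------------------

    def _moved_pair_energy(
        self, positions: np.ndarray, moved: np.ndarray
    ) -> float:
        """Pair + bond terms touching the moved set, for old or new state."""
        if self.model.rigid:
            return 0.0
        if not (self.use_intra_dh or self.use_lj or self.intra_hard_core):
            # non-interacting (phantom) chain: only bonds remain
            if len(self.model.bonds) == 0:
                return 0.0
            in_moved = np.zeros(self.model.n_beads, dtype=bool)
            in_moved[moved] = True
            bonds = self.model.bonds
            mask = in_moved[bonds[:, 0]] | in_moved[bonds[:, 1]]
            return self.bond_energies(positions, bond_mask=mask)
        n = self.model.n_beads
        in_moved = np.zeros(n, dtype=bool)
        in_moved[moved] = True
        rest = np.where(~in_moved)[0]
        # cross moved x rest
        ii = np.repeat(moved, len(rest))
        jj = np.tile(rest, len(moved))
        keep = ~self._excl[ii, jj]
        e = self._pair_energy_block(positions, ii[keep], jj[keep])
        if not np.isfinite(e):
            return np.inf
        e += self._hard_core_only_block(positions, ii[~keep], jj[~keep])
        if not np.isfinite(e):
            return np.inf
        # within moved set
        if len(moved) > 1:
            iu, ju = np.triu_indices(len(moved), k=1)
            mi, mj = moved[iu], moved[ju]
            keep = ~self._excl[mi, mj]
            e2 = self._pair_energy_block(positions, mi[keep], mj[keep])
            if not np.isfinite(e2):
                return np.inf
            e2 += self._hard_core_only_block(positions, mi[~keep], mj[~keep])
            e += e2
        if not np.isfinite(e):
            return np.inf
        if len(self.model.bonds):
            bonds = self.model.bonds
            mask = in_moved[bonds[:, 0]] | in_moved[bonds[:, 1]]
            e += self.bond_energies(positions, bond_mask=mask)
        return e

    def energy_delta(
        self,
        old_positions: np.ndarray,
        new_positions: np.ndarray,
        moved: np.ndarray,
    ) -> float:
        """Exact E(new) - E(old) restricted to terms touching ``moved``.

        Assumes the old configuration has finite energy.  Returns +inf if
        the new configuration creates any hard-core overlap.
        """
        moved = np.asarray(moved, dtype=np.intp)
        e_new = self.confinement_energy(new_positions)
        if not np.isfinite(e_new):
            return np.inf
        ext_new = self.external_energy(new_positions, idx=moved)
        if not np.isfinite(ext_new):
            return np.inf
        e_new += ext_new + self._moved_pair_energy(new_positions, moved)
        if not np.isfinite(e_new):
            return np.inf
        e_old = (
            self.confinement_energy(old_positions)
            + self.external_energy(old_positions, idx=moved)
            + self._moved_pair_energy(old_positions, moved)
        )
        return e_new - e_old
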