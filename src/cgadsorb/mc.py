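"""Metropolis Monte Carlo sampling in the NVT ensemble.

Five symmetric trial moves are provided: whole-body translation and
rotation for rigid models, and crankshaft, pivot and single-bead
translation for flexible chains.  Acceptance follows the Metropolis
criterion ``accept iff u < exp(-dE/kBT)``; hard-core overlaps (dE = +inf)
are always rejected, so no sampled configuration ever contains an overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .system import AdsorptionSystem

logger = logging.getLogger(__name__)

__all__ = [
    "MoveSpec", "RunSchedule", "SampleSet", "metropolis_accept",
    "rigid_translate", "rigid_rotate", "crankshaft", "pivot",
    "bead_translate", "default_moves", "run",
]

RIGID_MOVES = ("rigid_translate", "rigid_rotate")
CHAIN_MOVES = ("crankshaft", "pivot", "bead_translate")


@dataclass
class MoveSpec:
    """One trial-move type with its maximum step and relative weight."""

    kind: str
    max_step: float          # Å for translations, rad for rotations
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in RIGID_MOVES + CHAIN_MOVES:
            raise ValueError(f"unknown move kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError("move weight must be positive")


@dataclass
class RunSchedule:
    """MC run lengths in sweeps.

    One sweep is N attempted moves, with N the bead count for flexible
    chains and 2 (translate + rotate) for rigid bodies.
    """

    equilibration: int = 1000
    production: int = 10000
    sample_interval: int = 10
    seed: int = 0
    adapt_steps: bool = False
    check_interval: int = 10_000   # sweeps between full-energy validations

    def __post_init__(self) -> None:
        if min(self.equilibration, self.production, self.sample_interval) < 0:
            raise ValueError("schedule counts must be non-negative")


@dataclass
class SampleSet:
    """Recorded configurations and energies from one MC run."""

    positions: np.ndarray          # (S, N, 3)
    energies: np.ndarray           # (S,)
    provenance: dict = field(default_factory=dict)
    acceptance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.energies)


def metropolis_accept(delta_e: float, rng_draw: float) -> bool:
    """Metropolis criterion: accept iff draw < min(1, exp(-dE))."""
    if np.isnan(delta_e):
        return False
    if delta_e == np.inf:
        return False
    if delta_e <= 0.0:
        return True
    return rng_draw < np.exp(-delta_e)


def _random_axis(rng: np.random.Generator) -> np.ndarray:
    """Uniform direction on the sphere via a normalized 3-normal draw."""
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotate_about(
    positions: np.ndarray, point: np.ndarray, axis: np.ndarray, angle: float
) -> np.ndarray:
    # Rodrigues rotation; axis must be unit length
    d = positions - point
    c, s = np.cos(angle), np.sin(angle)
    return (
        point + c * d + s * np.cross(axis, d)
        + (1.0 - c) * np.outer(d @ axis, axis)
    )


def rigid_translate(
    positions: np.ndarray, max_disp: float, rng: np.random.Generator,
    masses: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Displace every bead by one uniform draw from [-d, d]^3."""
    shift = rng.uniform(-max_disp, max_disp, size=3)
    return positions + shift, np.arange(len(positions))


def rigid_rotate(
    positions: np.ndarray, max_angle: float, rng: np.random.Generator,
    masses: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the whole body about a random axis through its mass center."""
    axis = _random_axis(rng)
    angle = rng.uniform(-max_angle, max_angle)
    if masses is None:
        com = positions.mean(axis=0)
    else:
        com = np.average(positions, axis=0, weights=masses)
    return (
        _rotate_about(positions, com, axis, angle),
        np.arange(len(positions)),
    )


def _pick_two(n: int, rng: np.random.Generator) -> tuple[int, int]:
    i, j = rng.choice(n, size=2, replace=False)
    return (int(i), int(j)) if i < j else (int(j), int(i))


def crankshaft(
    positions: np.ndarray, max_angle: float, rng: np.random.Generator,
    masses=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the beads between two randomly picked beads about their axis.

    The picked beads stay fixed, so bond lengths outside the rotated
    segment are untouched; the segment rotates rigidly.  Picking adjacent
    beads yields the identity.
    """
    n = len(positions)
    i, j = _pick_two(n, rng)
    moved = np.arange(i + 1, j)
    if len(moved) == 0:
        return positions.copy(), moved
    axis = positions[j] - positions[i]
    norm = np.linalg.norm(axis)
    if norm == 0.0:
        return positions.copy(), np.empty(0, dtype=np.intp)
    angle = rng.uniform(-max_angle, max_angle)
    out = positions.copy()
    out[moved] = _rotate_about(positions[moved], positions[i], axis / norm, angle)
    return out, moved


def pivot(
    positions: np.ndarray, max_angle: float, rng: np.random.Generator,
    masses=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate one chain end about the axis through two picked beads.

    The rotated set runs from a randomly chosen end up to (excluding) the
    picked bead nearer that end.
    """
    n = len(positions)
    i, j = _pick_two(n, rng)
    axis = positions[j] - positions[i]
    norm = np.linalg.norm(axis)
    if norm == 0.0:
        return positions.copy(), np.empty(0, dtype=np.intp)
    if rng.integers(2) == 0:
        moved = np.arange(0, i)
        pivot_point = positions[i]
    else:
        moved = np.arange(j + 1, n)
        pivot_point = positions[j]
    if len(moved) == 0:
        return positions.copy(), moved
    angle = rng.uniform(-max_angle, max_angle)
    out = positions.copy()
    out[moved] = _rotate_about(positions[moved], pivot_point, axis / norm, angle)
    return out, moved


def bead_translate(
    positions: np.ndarray, max_disp: float, rng: np.random.Generator,
    masses=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Displace one uniformly chosen bead within [-d, d]^3."""
    k = int(rng.integers(len(positions)))
    out = positions.copy()
    out[k] = out[k] + rng.uniform(-max_disp, max_disp, size=3)
    return out, np.array([k], dtype=np.intp)


_MOVE_FUNCS = {
    "rigid_translate": rigid_translate,
    "rigid_rotate": rigid_rotate,
    "crankshaft": crankshaft,
    "pivot": pivot,
    "bead_translate": bead_translate,
}


def default_moves(rigid: bool) -> list[MoveSpec]:
    """Equal-weight default move set for a rigid body or a flexible chain."""
    if rigid:
        return [
            MoveSpec("rigid_translate", 5.0),
            MoveSpec("rigid_rotate", 0.3),
        ]
    return [
        MoveSpec("crankshaft", 1.0),
        MoveSpec("pivot", 1.0),
        MoveSpec("bead_translate", 2.0),
    ]


def _validate_moves(system: AdsorptionSystem, moves: list[MoveSpec]) -> None:
    for m in moves:
        if system.model.rigid and m.kind in CHAIN_MOVES:
            raise ValueError(f"chain move {m.kind!r} on a rigid model")
        if not system.model.rigid and m.kind in RIGID_MOVES:
            raise ValueError(f"rigid move {m.kind!r} on a flexible chain")
    if not moves:
        raise ValueError("at least one move type is required")


def run(
    system: AdsorptionSystem,
    moves: list[MoveSpec] | None = None,
    schedule: RunSchedule | None = None,
) -> SampleSet:
    """Metropolis MC run; reproducible bit-for-bit given the seed.

    Total energy is tracked incrementally and validated against a full
    recompute every ``schedule.check_interval`` sweeps (drift tolerance
    1e-6 kBT).  Step sizes may be auto-tuned toward 30-50% acceptance
    during equilibration only.
    """
    schedule = schedule or RunSchedule()
    moves = moves if moves is not None else default_moves(system.model.rigid)
    _validate_moves(system, moves)
    rng = np.random.default_rng(schedule.seed)

    positions = system.model.positions.copy()
    energy = system.total_energy(positions)
    if not np.isfinite(energy):
        raise ValueError(
            "starting configuration has non-finite energy (hard-core "
            "overlap); re-initialize the configuration before running"
        )

    weights = np.array([m.weight for m in moves], dtype=float)
    weights /= weights.sum()
    steps = np.array([m.max_step for m in moves], dtype=float)
    attempts = np.zeros(len(moves), dtype=np.int64)
    accepts = np.zeros(len(moves), dtype=np.int64)
    masses = system.model.masses

    per_sweep = system.model.n_beads if not system.model.rigid else 2
    snapshots: list[np.ndarray] = []
    energies: list[float] = []
    total_sweeps = schedule.equilibration + schedule.production

    for sweep in range(total_sweeps):
        in_production = sweep >= schedule.equilibration
        for _ in range(per_sweep):
            mi = int(rng.choice(len(moves), p=weights))
            attempts[mi] += 1
            func = _MOVE_FUNCS[moves[mi].kind]
            new_positions, moved = func(positions, steps[mi], rng, masses)
            draw = rng.random()
            if len(moved) == 0:
                continue  # identity proposal: nothing to accept
            if system.model.rigid:
                # whole-body moves: E(new) is one external evaluation and
                # the current energy is already known
                de = system.total_energy(new_positions) - energy
            else:
                de = system.energy_delta(positions, new_positions, moved)
            if metropolis_accept(de, draw):
                positions = new_positions
                energy += de
                accepts[mi] += 1
        if schedule.adapt_steps and not in_production and sweep % 50 == 49:
            frac = np.where(attempts > 0, accepts / np.maximum(attempts, 1), 0.4)
            steps = np.clip(
                steps * np.where(frac < 0.3, 0.9, np.where(frac > 0.5, 1.1, 1.0)),
                1e-3, 1e4,
            )
        if (sweep + 1) % schedule.check_interval == 0:
            full = system.total_energy(positions)
            drift = abs(full - energy)
            if drift > 1e-6:
                logger.warning("energy drift %.3g kBT; resynchronizing", drift)
            energy = full
        if in_production and (
            (sweep - schedule.equilibration) % schedule.sample_interval
            == schedule.sample_interval - 1
        ):
            snapshots.append(positions.copy())
            energies.append(energy)

    acc = {
        m.kind: (accepts[k] / attempts[k] if attempts[k] else 0.0)
        for k, m in enumerate(moves)
    }
    logger.info("acceptance rates: %s", acc)
    provenance = {
        "seed": schedule.seed,
        "equilibration_sweeps": schedule.equilibration,
        "production_sweeps": schedule.production,
        "sample_interval": schedule.sample_interval,
        "moves": [
            {"kind": m.kind, "max_step": float(steps[k]), "weight": m.weight}
            for k, m in enumerate(moves)
        ],
        "conditions": system.conditions.to_dict(),
        "surface": {
            "kind": system.layout.kind,
            "rho_e_per_A2": system.layout.rho,
            "n_nanoparticles": len(system.layout.nanoparticles),
            "spacing_A": system.layout.spacing,
        },
        "cell_A": [system.cell.lx, system.cell.ly, system.cell.lz],
    }
    return SampleSet(
        positions=(
            np.array(snapshots) if snapshots
            else np.empty((0, system.model.n_beads, 3))
        ),
        energies=np.array(energies),
        provenance=provenance,
        acceptance=acc,
    )
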