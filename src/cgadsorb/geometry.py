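"""Simulation cell and surface layouts.

Three geometries are supported: a bare charged wall at z = 0, a wall
decorated with a hexagonal (triangular) lattice of charged nanoparticles
resting on it, and a single free nanoparticle at the center of a spherical
sampling region.  The cell is periodic in x and y; z is bounded by a hard
floor at 0 and a hard ceiling at Lz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .interactions import np_charge

__all__ = [
    "SimulationCell", "Nanoparticle", "SurfaceLayout",
    "hex_lattice", "coverage", "spacing_from_coverage",
    "min_image_displacement",
]

HEX_MAX_COVERAGE = math.pi / (2.0 * math.sqrt(3.0))  # ≈0.9069, disk close packing


@dataclass(frozen=True)
class SimulationCell:
    """Periodic-in-xy box; z in [0, lz] with hard floor and ceiling."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        if min(self.lx, self.ly, self.lz) <= 0:
            raise ValueError("cell dimensions must be positive")

    def wrap_xy(self, positions: np.ndarray) -> np.ndarray:
        """Wrap x, y into [0, L); z untouched."""
        out = np.array(positions, dtype=float)
        out[..., 0] %= self.lx
        out[..., 1] %= self.ly
        return out


@dataclass(frozen=True)
class Nanoparticle:
    center: np.ndarray
    radius: float
    charge: float  # elementary charges

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "center", np.asarray(self.center, dtype=float)
        )
        if self.radius <= 0:
            raise ValueError("nanoparticle radius must be positive")


@dataclass
class SurfaceLayout:
    """A surface geometry: ``flat``, ``flat+lattice`` or ``single_np``.

    ``rho`` (e/Å^2) applies to the wall and, through
    :func:`~cgadsorb.interactions.np_charge`, to every nanoparticle.
    For ``single_np`` there is no wall and the molecule is confined to a
    sphere of radius ``confine_radius`` around the particle.
    """

    kind: str = "flat"
    rho: float = -0.005
    nanoparticles: list[Nanoparticle] = field(default_factory=list)
    spacing: float | None = None
    confine_radius: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "flat+lattice", "single_np"):
            raise ValueError(f"unknown surface kind {self.kind!r}")

    @property
    def has_wall(self) -> bool:
        return self.kind in ("flat", "flat+lattice")

    def np_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(centers (K,3), radii (K,), charges (K,)) as arrays."""
        if not self.nanoparticles:
            z = np.zeros(0)
            return np.zeros((0, 3)), z, z
        centers = np.array([p.center for p in self.nanoparticles])
        radii = np.array([p.radius for p in self.nanoparticles])
        charges = np.array([p.charge for p in self.nanoparticles])
        return centers, radii, charges


def min_image_displacement(
    a: np.ndarray, b: np.ndarray, cell: SimulationCell
) -> np.ndarray:
    """Displacement b - a with x and y wrapped to (-L/2, L/2]; z unwrapped.

    Broadcasts over leading axes.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    out = np.array(d, dtype=float)
    for axis, length in ((0, cell.lx), (1, cell.ly)):
        w = out[..., axis] - length * np.round(out[..., axis] / length)
        # round() maps exactly -L/2 to -L/2; shift to +L/2 for the half-open
        # convention (-L/2, L/2]
        w = np.where(w == -length / 2.0, length / 2.0, w)
        out[..., axis] = w
    return out


def coverage(radius: float, spacing: float) -> float:
    """Projected-area fraction of a hexagonal sphere lattice.

    Each lattice site occupies an area (sqrt(3)/2) d^2, so the coverage is
    2 pi R^2 / (sqrt(3) d^2), capped at 1 once projected disks overlap and
    tile the plane completely.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    phi = 2.0 * math.pi * radius**2 / (math.sqrt(3.0) * spacing**2)
    return min(phi, 1.0)


def spacing_from_coverage(radius: float, phi: float) -> float:
    """Invert :func:`coverage`: d = R sqrt(2 pi / (sqrt(3) phi)).

    Valid for 0 < phi <= pi/(2 sqrt(3)) ≈ 0.9069 (disk close packing).
    """
    if not 0.0 < phi <= HEX_MAX_COVERAGE + 1e-12:
        raise ValueError(
            f"coverage must be in (0, {HEX_MAX_COVERAGE:.4f}], got {phi}"
        )
    return radius * math.sqrt(2.0 * math.pi / (math.sqrt(3.0) * phi))


def commensurate_cell(
    spacing: float, min_lx: float = 0.0, min_ly: float = 0.0
) -> SimulationCell:
    """Smallest hexagonal-commensurate cell at least ``min_lx`` x ``min_ly``.

    Lx must be a multiple of d and Ly a multiple of sqrt(3) d; lz is set to
    a placeholder 1.0 and should be replaced by the caller.
    """
    n = max(1, math.ceil(min_lx / spacing - 1e-9))
    m = max(1, math.ceil(min_ly / (math.sqrt(3.0) * spacing) - 1e-9))
    return SimulationCell(n * spacing, m * math.sqrt(3.0) * spacing, 1.0)


def hex_lattice(
    radius: float, spacing: float, cell: SimulationCell, rho: float,
    tol: float = 1e-6,
) -> SurfaceLayout:
    """Hexagonally packed nanoparticles resting on the wall.

    The triangular lattice has nearest-neighbor center distance ``spacing``;
    rows are offset by d/2 and separated by (sqrt(3)/2) d; every center sits
    at z = R (tangent to the floor).  The cell must hold an integer number
    of lattice repeats: Lx = n d and Ly = m sqrt(3) d.  A non-commensurate
    cell raises ``ValueError`` naming the nearest valid dimensions.
    """
    n = cell.lx / spacing
    m = cell.ly / (math.sqrt(3.0) * spacing)
    if abs(n - round(n)) > tol or abs(m - round(m)) > tol or round(n) < 1 or round(m) < 1:
        nn = max(1, round(n))
        mm = max(1, round(m))
        raise ValueError(
            "cell is not commensurate with the hexagonal lattice: need "
            f"Lx = n*d and Ly = m*sqrt(3)*d; nearest valid cell is "
            f"Lx = {nn * spacing:.6g}, Ly = {mm * math.sqrt(3.0) * spacing:.6g}"
        )
    n, m = round(n), round(m)
    charge = np_charge(rho, radius)
    particles = []
    row_h = math.sqrt(3.0) / 2.0 * spacing
    for j in range(2 * m):          # 2 rows per sqrt(3) d of Ly
        y = j * row_h
        x_off = 0.0 if j % 2 == 0 else spacing / 2.0
        for i in range(n):
            particles.append(Nanoparticle(
                center=np.array([x_off + i * spacing, y, radius]),
                radius=radius,
                charge=charge,
            ))
    return SurfaceLayout(
        kind="flat+lattice", rho=rho, nanoparticles=particles,
        spacing=spacing,
    )
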