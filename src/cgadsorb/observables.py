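"""Analysis of sampled configurations.

Implements the study's reported quantities: adsorption free-energy profiles
F(z) = -ln P(z) zeroed at the bulk plateau, orientation statistics (cosine
of the angle between the molecule's long axis and the local surface
normal), the nanoparticle-surface radial distribution function g(r),
adsorbed fractions, and polymer shape descriptors (mass-weighted radius of
gyration and the shape factor Ree^2/Rg^2).
"""

from __future__ import annotations

import numpy as np

from .geometry import Nanoparticle, SimulationCell, min_image_displacement
from .mc import SampleSet
from .model import BeadModel
from .profiles import Profile

__all__ = [
    "free_energy_profile", "radial_g", "axis_vector",
    "cos_to_surface_normal", "cos_to_np", "adsorbed_fraction",
    "rg", "end_to_end", "shape_factor", "block_stderr",
    "min_surface_separation", "surface_excess",
]


def block_stderr(values: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error of the mean from block averaging."""
    values = np.asarray(values, dtype=float)
    if len(values) < n_blocks:
        return float(np.std(values) / np.sqrt(max(len(values), 1)))
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


def _com_trajectory(samples: SampleSet, masses: np.ndarray) -> np.ndarray:
    return np.average(samples.positions, axis=1, weights=masses)


def free_energy_profile(
    samples: SampleSet,
    masses: np.ndarray,
    bin_width: float = 2.0,
    z_max: float | None = None,
    plateau_fraction: float = 0.2,
) -> Profile:
    """F(z) = -ln P(z) of the mass-center height, zeroed at the bulk plateau.

    The additive constant is chosen so that the mean of F over the outer
    ``plateau_fraction`` of the sampled z-range is zero; if no bin out
    there is populated, the outermost populated quartile is used instead
    (with a warning flag in the profile metadata).  Empty bins are NaN.
    """
    com_z = _com_trajectory(samples, masses)[:, 2]
    lo, hi = 0.0, (z_max if z_max is not None else float(com_z.max()))
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(com_z, bins=edges)
    p = counts / counts.sum()
    with np.errstate(divide="ignore"):
        f = -np.log(p)
    f[counts == 0] = np.nan
    plateau = edges[:-1] >= hi - plateau_fraction * (hi - lo)
    usable = plateau & (counts > 0)
    meta = {"zero_point": "outer_plateau"}
    if not usable.any():
        populated = np.where(counts > 0)[0]
        usable = np.zeros_like(plateau)
        usable[populated[-max(1, len(populated) // 4):]] = True
        meta["zero_point"] = "outermost_populated_quartile"
    f = f - np.nanmean(f[usable])
    return Profile(edges, f, kind="free_energy_kBT",
                   n_samples=len(com_z), meta=meta)


def radial_g(
    samples: SampleSet,
    masses: np.ndarray,
    nanoparticle: Nanoparticle,
    bin_width: float = 2.0,
    r_max: float | None = None,
) -> Profile:
    """g(r) between the nanoparticle surface and the molecule mass center.

    r is the center distance minus the particle radius.  Shell counts are
    divided by shell volume and by the overall number concentration of the
    molecule in the sampling volume (one molecule per accessible volume),
    matching normalization by the box concentration rather than a local
    bulk estimate.
    """
    com = _com_trajectory(samples, masses)
    dist = np.linalg.norm(com - nanoparticle.center, axis=1)
    r = dist - nanoparticle.radius
    if r_max is None:
        r_max = float(r.max())
    n_bins = max(1, int(np.ceil(r_max / bin_width)))
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(r, bins=edges)
    shell_vol = (4.0 / 3.0) * np.pi * (
        (edges[1:] + nanoparticle.radius) ** 3
        - (edges[:-1] + nanoparticle.radius) ** 3
    )
    # accessible volume spanned by the histogram (one molecule inside it)
    v_total = (4.0 / 3.0) * np.pi * (
        (r_max + nanoparticle.radius) ** 3 - nanoparticle.radius ** 3
    )
    conc = len(r) / v_total
    g = counts / shell_vol / conc
    return Profile(edges, g, kind="g_of_r", n_samples=len(r))


def axis_vector(positions: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Long axis: top eigenvector of the gyration tensor, z-component >= 0.

    Raises for sphere-like bodies whose top two eigenvalues are degenerate
    (the long axis is then undefined); rod-like molecules never hit this.
    """
    pos = np.asarray(positions, dtype=float)
    w = np.ones(len(pos)) if masses is None else np.asarray(masses, float)
    com = np.average(pos, axis=0, weights=w)
    d = pos - com
    gyr = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / w.sum()
    evals, evecs = np.linalg.eigh(gyr)
    if evals[-1] - evals[-2] < 1e-9 * max(evals[-1], 1e-30):
        raise ValueError("degenerate principal axes: long axis undefined")
    axis = evecs[:, -1]
    if axis[2] < 0 or (axis[2] == 0 and axis[0] < 0):
        axis = -axis
    return axis


def cos_to_surface_normal(
    positions: np.ndarray, masses: np.ndarray | None = None
) -> float:
    """|cos| of the angle between the long axis and the z-axis, in [0, 1].

    0: lying flat on the surface; 1: standing up along the normal.
    """
    return float(abs(axis_vector(positions, masses)[2]))


def cos_to_np(
    positions: np.ndarray,
    nanoparticle: Nanoparticle,
    masses: np.ndarray | None = None,
    cell: SimulationCell | None = None,
) -> float:
    """|cos| between the long axis and the particle-to-molecule direction.

    The direction runs from the nanoparticle center to the molecule mass
    center (minimum image if a cell is given); 1 means the molecule points
    radially away from the particle, 0 means it lies tangentially.
    """
    w = np.ones(len(positions)) if masses is None else np.asarray(masses, float)
    com = np.average(np.asarray(positions, float), axis=0, weights=w)
    if cell is not None:
        u = min_image_displacement(nanoparticle.center, com, cell)
    else:
        u = com - nanoparticle.center
    norm = np.linalg.norm(u)
    if norm == 0.0:
        raise ValueError("molecule mass center coincides with the particle")
    return float(abs(axis_vector(positions, masses) @ (u / norm)))


def min_surface_separation(
    positions: np.ndarray,
    radii: np.ndarray,
    layout,
    cell: SimulationCell,
) -> float:
    """Smallest bead-surface gap over wall and nanoparticles, in Å.

    Measured from the bead *surface* (center minus bead radius) to the wall
    plane or nanoparticle surface; 0 means contact.
    """
    gaps = []
    if layout.has_wall:
        gaps.append(positions[:, 2] - radii)
    centers, np_radii, _ = layout.np_arrays()
    if len(centers):
        if layout.kind == "single_np":
            d = positions[None, :, :] - centers[:, None, :]
        else:
            d = min_image_displacement(
                centers[:, None, :], positions[None, :, :], cell
            )
        dist = np.sqrt((d ** 2).sum(axis=-1))
        gaps.append((dist - np_radii[:, None] - radii[None, :]).ravel())
    if not gaps:
        raise ValueError("layout has no surface to measure against")
    return float(np.concatenate([np.atleast_1d(g).ravel() for g in gaps]).min())


def adsorbed_fraction(
    samples: SampleSet,
    model: BeadModel,
    layout,
    cell: SimulationCell,
    cutoff: float,
) -> tuple[float, np.ndarray]:
    """Fraction of samples with min bead-surface separation <= cutoff.

    Returns the fraction and the per-sample boolean flags.  The default
    cutoff used throughout the package is two Debye lengths, which spans
    the width of the screened-electrostatic adsorption well.
    """
    flags = np.array([
        min_surface_separation(pos, model.radii, layout, cell) <= cutoff
        for pos in samples.positions
    ])
    frac = float(flags.mean()) if len(flags) else 0.0
    return frac, flags


def surface_excess(
    adsorbed_frac: float, cell: SimulationCell, layout
) -> float:
    """Box-independent adsorbed amount per unit wall area, in Å.

    The raw adsorbed fraction of a single molecule depends on how much bulk
    volume the box offers: frac = W_ads / (W_ads + V_bulk), so systems with
    different nanoparticle packing (hence different accessible volume) are
    not directly comparable.  The surface excess removes that confound:

        Gamma = frac/(1-frac) * V_accessible / A_wall

    where V_accessible subtracts the nanoparticle volumes from the box.
    Returns +inf when every sample is adsorbed.
    """
    if not 0.0 <= adsorbed_frac <= 1.0:
        raise ValueError("adsorbed fraction must lie in [0, 1]")
    area = cell.lx * cell.ly
    v_np = sum(
        (4.0 / 3.0) * np.pi * p.radius**3 for p in layout.nanoparticles
    )
    v_acc = area * cell.lz - v_np
    if adsorbed_frac == 1.0:
        return np.inf
    return adsorbed_frac / (1.0 - adsorbed_frac) * v_acc / area


def rg(positions: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration in Å."""
    pos = np.asarray(positions, dtype=float)
    m = np.asarray(masses, dtype=float)
    com = np.average(pos, axis=0, weights=m)
    return float(np.sqrt(
        (m * ((pos - com) ** 2).sum(axis=1)).sum() / m.sum()
    ))


def end_to_end(positions: np.ndarray) -> float:
    """Distance between the first and last bead, in Å."""
    return float(np.linalg.norm(positions[-1] - positions[0]))


def shape_factor(positions: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Ree^2 / Rg^2: 6 for a Gaussian chain, 12 for a rigid rod."""
    m = (np.ones(len(positions)) if masses is None
         else np.asarray(masses, float))
    return end_to_end(positions) ** 2 / rg(positions, m) ** 2
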