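"""Deterministic synthetic fixtures: chains, rods, toy structures.

Everything here is generated in memory from a seed and a spec — no
downloads.  The generators emulate the statistical structure the analysis
assumes: freely-jointed chains for ideal-polymer limiting laws, rigid rods
with a fibrinogen-like longitudinal charge pattern (nearly neutral ends
carrying positive patches, negative middle), small PDB files with
unresolved residues and bound calcium, and a two-state toy for validating
the Metropolis engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import ONE_TO_THREE
from .mc import metropolis_accept
from .model import BeadModel, assign_charges

__all__ = [
    "RodSpec", "make_ideal_chain", "make_charged_rod",
    "fibrinogen_mimic_rod", "make_toy_pdb", "make_two_state_toy",
    "TwoStateToy", "synthetic_fibrinogen_pdb",
]


# ---------------------------------------------------------------------------
# ideal chains

def make_ideal_chain(
    n_beads: int, bond_length: float = 4.1, seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Freely-jointed chain: bond directions uniform on the sphere.

    Returns (n_beads, 3) positions with fixed bond length; the closed-form
    references are <Ree^2> = (N-1) b^2 and <Rg^2> = (N^2-1) b^2 / (6N).
    """
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    rng = rng if rng is not None else np.random.default_rng(seed)
    v = rng.normal(size=(n_beads - 1, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pos = np.zeros((n_beads, 3))
    pos[1:] = np.cumsum(bond_length * v, axis=0)
    return pos


# ---------------------------------------------------------------------------
# charged rods

@dataclass
class RodSpec:
    """Collinear rigid rod with a longitudinal charge pattern.

    ``segments`` is a list of (length fraction, per-bead charge) tuples
    whose fractions partition [0, 1].
    """

    n_beads: int = 90
    spacing: float = 5.0
    bead_radius: float = 2.5
    segments: list = field(
        default_factory=lambda: [(0.15, 0.0), (0.70, -0.15), (0.15, 0.0)]
    )

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        total = sum(f for f, _ in self.segments)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("segment fractions must partition [0, 1]")


def make_charged_rod(spec: RodSpec | None = None) -> BeadModel:
    """Rigid collinear rod with the requested per-segment charges.

    With no spec, returns the fibrinogen-mimic rod (see
    :func:`fibrinogen_mimic_rod`).
    """
    if spec is None:
        return fibrinogen_mimic_rod()
    n = spec.n_beads
    positions = np.zeros((n, 3))
    positions[:, 0] = spec.spacing * np.arange(n)
    charges = np.zeros(n)
    start = 0
    for k, (frac, q) in enumerate(spec.segments):
        stop = n if k == len(spec.segments) - 1 else start + int(round(frac * n))
        charges[start:stop] = q
        start = stop
    return BeadModel(
        positions=positions,
        radii=np.full(n, spec.bead_radius),
        charges=charges,
        masses=np.full(n, 110.0),
        labels=["BEAD"] * n,
        rigid=True,
    )


def fibrinogen_mimic_rod(
    n_axis: int = 90,
    spacing: float = 5.0,
    bead_radius: float = 2.5,
    foot_offset: float = 25.0,
    n_feet_per_end: int = 3,
) -> BeadModel:
    """Rigid rod emulating the fibrinogen main body's charge architecture.

    A 445 Å axis of beads carries the negative charges: a net negative
    middle (10 unit charges spread over the central 70%) and two weakly
    negative ends (2 unit charges each).  Near each end, ``n_feet_per_end``
    positive beads sit ``foot_offset`` Å off-axis, emulating the positive
    surface patches that the thick end domains expose: when the rod lies
    with its positive face toward a surface, those charges reach contact
    while the negative axis stays roughly one domain radius away.  The net
    charge is 2*3 - 2*2 - 10 = -8.

    The model is a synthetic stand-in, not a structure-derived molecule.
    """
    positions = [np.array([spacing * i, 0.0, 0.0]) for i in range(n_axis)]
    charges = [0.0] * n_axis
    # negative middle: 10 charges spread over the central 70%
    mid_lo, mid_hi = int(0.15 * n_axis), int(0.85 * n_axis)
    for i in np.linspace(mid_lo, mid_hi - 1, 10).round().astype(int):
        charges[i] -= 1.0
    # weakly negative ends (inboard of the positive patches)
    end_span = max(int(0.15 * n_axis), 2)
    for i in (end_span - 2, end_span - 1):
        charges[i] -= 1.0
        charges[n_axis - 1 - i] -= 1.0
    # positive feet, off-axis, near each end
    foot_axis_idx = np.linspace(1, end_span - 2, n_feet_per_end).round().astype(int)
    for i in foot_axis_idx:
        for j in (i, n_axis - 1 - i):
            positions.append(np.array([spacing * j, 0.0, -foot_offset]))
            charges.append(+1.0)
    n = len(positions)
    return BeadModel(
        positions=np.array(positions),
        radii=np.full(n, bead_radius),
        charges=np.array(charges),
        masses=np.full(n, 110.0),
        labels=["BEAD"] * n,
        rigid=True,
    )


# ---------------------------------------------------------------------------
# toy PDB fixtures

def _format_atom(
    serial: int, name: str, res_name: str, chain: str, res_seq: int,
    pos: np.ndarray, element: str, hetatm: bool = False,
) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    return (
        f"{record}{serial:>5d} {name:<4.4s} {res_name:>3.3s} {chain:1.1s}"
        f"{res_seq:>4d}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2.2s}\n"
    )


def _seqres_lines(chain: str, residues: list[str]) -> list[str]:
    lines = []
    for k in range(0, len(residues), 13):
        chunk = " ".join(f"{r:>3.3s}" for r in residues[k:k + 13])
        lines.append(
            f"SEQRES {k // 13 + 1:>3d} {chain:1.1s} {len(residues):>4d}  {chunk}\n"
        )
    return lines


def _remark465_lines(entries: list[tuple[str, str, int]]) -> list[str]:
    lines = [
        "REMARK 465\n",
        "REMARK 465 MISSING RESIDUES\n",
        "REMARK 465   M RES C SSSEQI\n",
    ]
    for res_name, chain, seq in entries:
        lines.append(f"REMARK 465     {res_name:>3.3s} {chain:1.1s} {seq:>5d}\n")
    return lines


def make_toy_pdb(
    chains: dict[str, tuple[str, list[bool]]] | None = None,
    ions: list[tuple[str, tuple[float, float, float]]] | None = None,
    spacing: float = 3.8,
) -> str:
    """Well-formed PDB text with resolved/unresolved residues and ions.

    ``chains`` maps a chain id to (one-letter sequence, resolved mask).
    The default fixture has two chains, one unresolved residue and one
    bound calcium.  Resolved residues get N, CA and C atoms along a
    straight backbone.  Output is deterministic.
    """
    if chains is None:
        chains = {
            "A": ("DKE", [True, True, True]),
            "B": ("AKAG", [True, True, True, False]),
        }
    if ions is None:
        ions = [("CA", (0.0, 10.0, 0.0))]

    seqres, remark, atoms = [], [], []
    serial = 1
    missing: list[tuple[str, str, int]] = []
    for ci, (chain_id, (sequence, mask)) in enumerate(sorted(chains.items())):
        three = [ONE_TO_THREE[c] for c in sequence.upper()]
        seqres.extend(_seqres_lines(chain_id, three))
        for ri, (res, ok) in enumerate(zip(three, mask)):
            if not ok:
                missing.append((res, chain_id, ri + 1))
                continue
            base = np.array([spacing * ri, 8.0 * ci, 0.0])
            for name, off, el in (
                ("N", (-1.2, 0.3, 0.0), "N"),
                ("CA", (0.0, 0.0, 0.0), "C"),
                ("C", (1.2, 0.3, 0.0), "C"),
            ):
                atoms.append(_format_atom(
                    serial, name, res, chain_id, ri + 1,
                    base + np.array(off), el,
                ))
                serial += 1
    remark = _remark465_lines(missing) if missing else []
    het = []
    for k, (element, pos) in enumerate(ions):
        het.append(_format_atom(
            serial, element, element, "Z", k + 1, np.asarray(pos, float),
            element, hetatm=True,
        ))
        serial += 1
    return "".join(
        ["HEADER    SYNTHETIC FIXTURE\n"] + remark + seqres + atoms + het
        + ["END\n"]
    )


# ---------------------------------------------------------------------------
# two-state toy

@dataclass
class TwoStateToy:
    """One particle hopping between two sites with an energy gap (kBT).

    Analytic occupancies are 1/(1+e^-gap) for the ground state and
    e^-gap/(1+e^-gap) for the excited state.
    """

    gap: float = 1.0

    def analytic_occupancies(self) -> tuple[float, float]:
        w = math.exp(-self.gap) if np.isfinite(self.gap) else 0.0
        return 1.0 / (1.0 + w), w / (1.0 + w)

    def sample(self, n_steps: int, seed: int = 0) -> np.ndarray:
        """Metropolis trajectory of site indices (0 = ground, 1 = excited)."""
        rng = np.random.default_rng(seed)
        energies = (0.0, self.gap)
        state = 0
        states = np.empty(n_steps, dtype=np.int8)
        draws = rng.random(n_steps)
        for t in range(n_steps):
            proposal = 1 - state
            de = energies[proposal] - energies[state]
            if metropolis_accept(de, draws[t]):
                state = proposal
            states[t] = state
        return states


def make_two_state_toy(gap: float = 1.0) -> TwoStateToy:
    return TwoStateToy(gap=gap)


# ---------------------------------------------------------------------------
# synthetic fibrinogen stand-in

_AA_FILLER = "AGSVLTNQ"  # neutral residues used to pad synthetic sequences


def _synthetic_half_sequences() -> dict[str, dict]:
    """Per-chain sequence/charge design for one half of the stand-in.

    Charged residues are placed deterministically so that the resolved
    side chains of the whole molecule sum to -16 e (net -8 with the four
    calcium ions and the truncation-neutralized termini), each unresolved
    Aα tail sums to -1 e, and the end domains expose positive patches
    while the middle is net negative.
    """
    def padded(n: int, placements: dict[int, str]) -> str:
        seq = [(_AA_FILLER[i % len(_AA_FILLER)]) for i in range(n)]
        for pos, aa in placements.items():
            seq[pos] = aa
        return "".join(seq)

    # Aα: 610 residues; resolved 11..200; unresolved 1..10 and 201..610.
    # Resolved part: 2 x D (net -2).  Tail 201..610: 20 D + 19 K (net -1).
    aa_placements = {100: "D", 150: "D"}
    for k in range(20):
        aa_placements[210 + 18 * k] = "D"
    for k in range(19):
        aa_placements[219 + 18 * k] = "K"
    # Bβ: 461 residues; resolved 71..461 (C-terminus resolved, -1 terminal).
    # Resolved part: 6 D, 4 K -> net -2.
    bb_placements = {}
    for k in range(6):
        bb_placements[120 + 50 * k] = "D"
    for k in range(4):
        bb_placements[145 + 60 * k] = "K"
    # γ: 411 residues; resolved 1..389 (N-terminus resolved, +1 terminal).
    # Resolved: 12 K positive patch near the distal D domain (sequence end),
    # 14 D in the coil/middle, 2 E near the patch -> net -4.
    g_placements = {}
    for k in range(12):
        g_placements[330 + 4 * k] = "K"
    for k in range(14):
        g_placements[60 + 18 * k] = "D"
    g_placements[320] = "E"
    g_placements[384] = "E"
    return {
        "Aalpha": {
            "n": 610, "seq": padded(610, aa_placements),
            "resolved": (11, 200),
        },
        "Bbeta": {
            "n": 461, "seq": padded(461, bb_placements),
            "resolved": (71, 461),
        },
        "gamma": {
            "n": 411, "seq": padded(411, g_placements),
            "resolved": (1, 389),
        },
    }


def _half_geometry(
    design: dict, x_center: float, x_end: float, phase: float,
) -> dict[str, np.ndarray]:
    """Cα positions for one half: chains run from the center to one end.

    The rod is thick at the end (D domain, radius 25 Å) and center
    (E domain, radius 20 Å) and thin in between (radius 8 Å); beads wind
    around the axis on a deterministic helix.  The γ positive patch winds
    at full domain radius so that it can reach a surface at contact.
    """
    out = {}
    golden = 2.399963229728653
    for ci, (name, spec) in enumerate(sorted(design.items())):
        lo, hi = spec["resolved"]
        n_res = hi - lo + 1
        t = np.linspace(0.0, 1.0, n_res)
        x = x_center + (x_end - x_center) * t
        # radius profile along the half-rod
        dist_from_center = np.abs(x - x_center)
        radius = np.where(
            dist_from_center > 160.0, 25.0,
            np.where(dist_from_center < 30.0, 20.0, 8.0),
        )
        theta = golden * np.arange(n_res) + phase + 2.0 * ci
        y = radius * np.cos(theta)
        z = radius * np.sin(theta)
        out[name] = np.column_stack([x, y, z])
    return out


def synthetic_fibrinogen_pdb() -> str:
    """PDB text of a synthetic fibrinogen main-body stand-in.

    This is NOT the crystal structure: it is a deterministic synthetic
    molecule built to carry the documented bookkeeping of the real one —
    six chains (2x610 + 2x461 + 2x411 residues), ≈35% of residues
    unresolved (including the two 410-residue Aα C-terminal tails), four
    bound calcium ions, a ≈450 Å maximum extent, resolved-part net charge
    -8 e (with the ions) and -12 e when the unresolved Aα tail charges and
    their chain termini are counted.  End domains expose positive patches;
    the middle is net negative.
    """
    design = _synthetic_half_sequences()
    chain_ids = {("Aalpha", 0): "A", ("Aalpha", 1): "B",
                 ("Bbeta", 0): "C", ("Bbeta", 1): "D",
                 ("gamma", 0): "E", ("gamma", 1): "F"}
    halves = [
        _half_geometry(design, 225.0, 0.0, 0.0),
        _half_geometry(design, 225.0, 450.0, 1.0),
    ]

    seqres, missing, atoms = [], [], []
    serial = 1
    for half_idx, geom in enumerate(halves):
        for name in sorted(design):
            spec = design[name]
            chain = chain_ids[(name, half_idx)]
            three = [ONE_TO_THREE[c] for c in spec["seq"]]
            seqres.extend(_seqres_lines(chain, three))
            lo, hi = spec["resolved"]
            for ri in range(1, spec["n"] + 1):
                if not (lo <= ri <= hi):
                    missing.append((three[ri - 1], chain, ri))
            coords = geom[name]
            for k, ri in enumerate(range(lo, hi + 1)):
                ca = coords[k]
                direction = (coords[min(k + 1, len(coords) - 1)]
                             - coords[max(k - 1, 0)])
                nrm = np.linalg.norm(direction)
                step = direction / nrm * 1.2 if nrm > 0 else np.zeros(3)
                for atom_name, pos, el in (
                    ("N", ca - step, "N"), ("CA", ca, "C"), ("C", ca + step, "C"),
                ):
                    atoms.append(_format_atom(
                        serial, atom_name, three[ri - 1], chain, ri, pos, el,
                    ))
                    serial += 1

    het = []
    ca_sites = [(60.0, 26.0, 0.0), (60.0, -26.0, 0.0),
                (390.0, 26.0, 0.0), (390.0, -26.0, 0.0)]
    for k, pos in enumerate(ca_sites):
        het.append(_format_atom(
            serial, "CA", "CA", "Z", k + 1, np.asarray(pos), "CA", hetatm=True,
        ))
        serial += 1
    return "".join(
        ["HEADER    SYNTHETIC FIBRINOGEN STAND-IN\n"]
        + _remark465_lines(missing) + seqres + atoms + het + ["END\n"]
    )


def alpha_c_tail_sequence() -> str:
    """One-letter sequence of the synthetic Aα tail (residues 201-610)."""
    design = _synthetic_half_sequences()
    return design["Aalpha"]["seq"][200:610]
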