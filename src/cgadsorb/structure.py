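"""From crystal structures and sequences to coarse-grained bead models.

The rigid model places one 2.5 Å sphere per resolved residue at its Cα
position, one sphere per bound ion, and one extra sphere per chain terminus
whose terminal residue is resolved (at the backbone N / C atom).  Charges
are integer values at pH 7.4 assigned from the residue identity; unresolved
residues contribute no beads, and a truncated terminus carries no terminal
charge bead.  Flexible chains are built from a one-letter sequence as a
bead-spring polymer with 2.0 Å beads.
"""

from __future__ import annotations

import io
import logging
import warnings

import numpy as np

from .constants import (
    HYDROPHOBIC_RESIDUES,
    ION_MASSES,
    MAX_SASA_GXG,
    ONE_TO_THREE,
    RESIDUE_MASSES,
    TERMINAL_MASSES,
)
from .model import BeadModel, ChargeRules, ResidueRecord, assign_charges, bead_mass
from .profiles import Profile

logger = logging.getLogger(__name__)

__all__ = [
    "load_structure", "coarse_grain_rigid", "build_flexible_chain",
    "longitudinal_profile", "hydrophobic_surface_fraction",
    "residue_bead_indices", "principal_axis",
]

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _looks_like_cif(text: str) -> bool:
    head = text.lstrip()[:500]
    return head.startswith("data_") or "_atom_site." in text[:20000]


def load_structure(structure_text: str, assembly: str = "1") -> list[ResidueRecord]:
    """Parse PDB or mmCIF text into per-residue records.

    Returns records for all polymer chains plus hetero ions.  Residues
    listed in the sequence records (SEQRES / entity sequence) or in the
    missing-residue remarks but absent from the coordinates are returned
    with ``resolved=False`` and no atoms.  For mmCIF input the requested
    biological assembly is expanded; PDB input is taken as already being
    the assembly of interest (true of RCSB assembly PDB files and of the
    fixtures generated here).
    """
    if _looks_like_cif(structure_text):
        return _load_cif(structure_text, assembly)
    return _load_pdb(structure_text)


def _load_pdb(text: str) -> list[ResidueRecord]:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("model", io.StringIO(text))
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"malformed PDB input: {exc}") from exc
    header = structure.header or {}

    records: list[ResidueRecord] = []
    model = next(iter(structure))
    resolved_keys = set()
    for chain in model:
        for residue in chain:
            hetflag, resseq, _icode = residue.id
            if hetflag == "W" or residue.get_resname().strip() in _WATER_NAMES:
                continue
            atoms = [
                (a.get_name(), (a.element or "").strip().upper(),
                 np.asarray(a.get_coord(), dtype=float))
                for a in residue
            ]
            name = residue.get_resname().strip()
            is_ion = bool(hetflag.strip()) and len(atoms) == 1 and (
                name in ION_MASSES or atoms[0][1] in ION_MASSES
            )
            records.append(ResidueRecord(
                chain_id=chain.id, residue_index=resseq, residue_name=name,
                atoms=atoms, resolved=True, is_ion=is_ion,
            ))
            resolved_keys.add((chain.id, resseq))

    for miss in header.get("missing_residues", []) or []:
        key = (miss.get("chain"), miss.get("ssseq"))
        if key in resolved_keys:
            continue
        records.append(ResidueRecord(
            chain_id=miss.get("chain"), residue_index=miss.get("ssseq"),
            residue_name=(miss.get("res_name") or "UNK").strip(),
            atoms=[], resolved=False,
        ))
    records.sort(key=lambda r: (str(r.chain_id), r.is_ion, r.residue_index))
    return records


def _load_cif(text: str, assembly: str) -> list[ResidueRecord]:
    import gemmi

    try:
        block = gemmi.cif.read_string(text).sole_block()
        st = gemmi.make_structure_from_block(block)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed mmCIF input: {exc}") from exc
    st.setup_entities()

    names = [a.name for a in st.assemblies]
    if names:
        if str(assembly) not in names:
            raise ValueError(
                f"assembly {assembly!r} not found; available: {names}"
            )
        model = gemmi.make_assembly(
            st.assemblies[names.index(str(assembly))], st[0],
            gemmi.HowToNameCopiedChain.AddNumber,
        )
    else:
        model = _expand_assembly_from_block(block, st[0], str(assembly))

    records: list[ResidueRecord] = []
    for chain in model:
        for residue in chain:
            name = residue.name.strip()
            if name in _WATER_NAMES:
                continue
            atoms = [
                (a.name, a.element.name.upper(),
                 np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in residue
            ]
            is_ion = len(atoms) == 1 and (
                name in ION_MASSES or atoms[0][1] in ION_MASSES
            )
            records.append(ResidueRecord(
                chain_id=chain.name, residue_index=residue.seqid.num,
                residue_name=name, atoms=atoms, resolved=True, is_ion=is_ion,
            ))

    unobs = _cif_unobserved(text)
    resolved_keys = {(r.chain_id, r.residue_index) for r in records}
    for chain_id, idx, name in unobs:
        # assembly copies share the unobserved list of the source chain
        for rec_chain in {r.chain_id for r in records}:
            if rec_chain == chain_id or rec_chain.startswith(chain_id):
                if (rec_chain, idx) not in resolved_keys:
                    records.append(ResidueRecord(
                        chain_id=rec_chain, residue_index=idx,
                        residue_name=name, atoms=[], resolved=False,
                    ))
    records.sort(key=lambda r: (str(r.chain_id), r.is_ion, r.residue_index))
    return records


def _expand_assembly_from_block(block, model, assembly: str):
    """Expand a biological assembly from the raw mmCIF categories.

    Fallback used when the structure reader exposes no assembly list: reads
    ``_pdbx_struct_assembly`` / ``_pdbx_struct_assembly_gen`` /
    ``_pdbx_struct_oper_list`` directly and applies the operators to the
    listed asym chains.  Without any assembly categories the deposited
    model is returned as-is.
    """
    import gemmi

    ids = [row.str(0) for row in block.find("_pdbx_struct_assembly.", ["id"])]
    if not ids:
        return model
    if assembly not in ids:
        raise ValueError(
            f"assembly {assembly!r} not found; available: {ids}"
        )
    opers: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tags = ["id"] + [
        f"matrix[{i}][{j}]" for i in (1, 2, 3) for j in (1, 2, 3)
    ] + [f"vector[{i}]" for i in (1, 2, 3)]
    for row in block.find("_pdbx_struct_oper_list.", tags):
        mat = np.array([float(row[1 + k]) for k in range(9)]).reshape(3, 3)
        vec = np.array([float(row[10 + k]) for k in range(3)])
        opers[row.str(0)] = (mat, vec)

    out = gemmi.Model(model.num)
    copy_no = 0
    for row in block.find(
        "_pdbx_struct_assembly_gen.",
        ["assembly_id", "oper_expression", "asym_id_list"],
    ):
        if row.str(0) != assembly:
            continue
        asym_ids = {s.strip() for s in row.str(2).split(",")}
        oper_ids = [
            s.strip() for s in
            row.str(1).replace("(", "").replace(")", "").split(",")
        ]
        for oper_id in oper_ids:
            mat, vec = opers.get(oper_id, (np.eye(3), np.zeros(3)))
            copy_no += 1
            for chain in model:
                sub_ids = {chain.name} | {
                    res.subchain for res in chain if res.subchain
                }
                if not (sub_ids & asym_ids):
                    continue
                new_chain = gemmi.Chain(
                    chain.name if copy_no == 1
                    else f"{chain.name}{copy_no}"
                )
                for res in chain:
                    new_res = gemmi.Residue()
                    new_res.name = res.name
                    new_res.seqid = res.seqid
                    for atom in res:
                        a = gemmi.Atom()
                        a.name = atom.name
                        a.element = atom.element
                        p = mat @ np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z]
                        ) + vec
                        a.pos = gemmi.Position(*p)
                        new_res.add_atom(a)
                    new_chain.add_residue(new_res)
                out.add_chain(new_chain)
    return out if len(out) else model


def _cif_unobserved(text: str) -> list[tuple[str, int, str]]:
    import gemmi

    block = gemmi.cif.read_string(text).sole_block()
    table = block.find(
        "_pdbx_unobs_or_zero_occ_residues.",
        ["auth_asym_id", "auth_seq_id", "auth_comp_id"],
    )
    out = []
    for row in table:
        try:
            out.append((row[0], int(row[1]), row[2]))
        except (ValueError, IndexError):
            continue
    return out


def _chain_terminal_beads(
    chain_records: list[ResidueRecord],
) -> list[tuple[str, np.ndarray]]:
    """Terminal charge beads for one chain, where the terminus is resolved.

    A chain truncated in the coordinates (its first/last sequence residue
    unresolved) gets no terminal bead there, so the truncated terminus
    carries no charge.
    """
    residues = [r for r in chain_records if not r.is_ion]
    if not residues:
        return []
    by_index = sorted(residues, key=lambda r: r.residue_index)
    first, last = by_index[0], by_index[-1]
    out = []
    if first.resolved:
        pos = first.atom_position("N")
        if pos is None:
            pos = first.atom_position("CA")
        if pos is not None:
            out.append(("NTERM", pos))
    if last.resolved:
        pos = last.atom_position("C")
        if pos is None:
            pos = last.atom_position("CA")
        if pos is not None:
            out.append(("CTERM", pos))
    return out


def coarse_grain_rigid(
    records: list[ResidueRecord],
    bead_radius: float = 2.5,
    exclude_chains: tuple[str, ...] = (),
    charge_rules: ChargeRules | None = None,
) -> BeadModel:
    """One bead per resolved residue (at Cα) plus ion and terminal beads.

    ``exclude_chains`` removes co-crystallized synthetic peptide chains.
    Charges are assigned immediately from ``charge_rules``.  Raises if a
    resolved non-ion residue has no Cα atom.
    """
    records = [r for r in records if r.chain_id not in exclude_chains]
    if not any(r.resolved for r in records):
        raise ValueError("no resolved residues to coarse-grain")

    positions, labels = [], []
    chains: dict[str, list[ResidueRecord]] = {}
    for rec in records:
        chains.setdefault(rec.chain_id, []).append(rec)

    for chain_id, chain_records in chains.items():
        for rec in chain_records:
            if not rec.resolved or rec.is_ion:
                continue
            ca = rec.atom_position("CA")
            if ca is None:
                raise ValueError(
                    f"residue {rec.residue_name} {rec.residue_index} of "
                    f"chain {chain_id} has no CA atom and is not an ion"
                )
            positions.append(ca)
            labels.append(rec.residue_name.upper())
        for label, pos in _chain_terminal_beads(chain_records):
            positions.append(pos)
            labels.append(label)

    for rec in records:
        if rec.is_ion and rec.resolved:
            element = rec.atoms[0][1] or rec.residue_name.upper()
            positions.append(rec.atoms[0][2])
            labels.append(f"ION:{element}")

    n = len(positions)
    model = BeadModel(
        positions=np.array(positions, dtype=float),
        radii=np.full(n, bead_radius),
        charges=np.zeros(n),
        masses=np.array([bead_mass(lb) for lb in labels]),
        labels=labels,
        rigid=True,
    )
    return assign_charges(model, charge_rules)


def build_flexible_chain(
    sequence: str,
    bead_radius: float = 2.0,
    bond_length: float = 4.1,
    charge_rules: ChargeRules | None = None,
) -> BeadModel:
    """Bead-spring chain from a one-letter sequence, plus terminal beads.

    The initial configuration is a straight line along +z at the bond
    equilibrium length (self-avoiding since the bond length exceeds the
    bead contact distance); equilibration sweeps erase it.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    labels = ["NTERM"]
    for k, letter in enumerate(sequence.upper()):
        if letter not in ONE_TO_THREE:
            raise ValueError(
                f"invalid residue letter {letter!r} at position {k + 1}"
            )
        labels.append(ONE_TO_THREE[letter])
    labels.append("CTERM")

    n = len(labels)
    positions = np.zeros((n, 3))
    positions[:, 2] = bond_length * np.arange(n)
    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    model = BeadModel(
        positions=positions,
        radii=np.full(n, bead_radius),
        charges=np.zeros(n),
        masses=np.array([bead_mass(lb) for lb in labels]),
        labels=labels,
        bonds=bonds,
        rigid=False,
    )
    return assign_charges(model, charge_rules)


def residue_bead_indices(model: BeadModel) -> np.ndarray:
    """Indices of residue beads (excluding termini and ions)."""
    return np.array([
        i for i, lb in enumerate(model.labels)
        if not lb.startswith(("NTERM", "CTERM", "ION:"))
    ], dtype=np.intp)


def principal_axis(
    positions: np.ndarray, masses: np.ndarray | None = None
) -> np.ndarray:
    """Longitudinal axis: top gyration-tensor eigenvector (z >= 0 sign)."""
    from .observables import axis_vector

    return axis_vector(positions, masses)


def _binned_projection(
    positions: np.ndarray, n_bins: int, masses: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Project beads on the principal axis; equal-width bin edges."""
    axis = principal_axis(positions, masses)
    proj = positions @ axis
    edges = np.linspace(proj.min(), proj.max(), n_bins + 1)
    return proj, edges


def longitudinal_profile(
    model: BeadModel, n_bins: int = 20, prop: str = "charge"
) -> Profile:
    """Per-bin summed charge or hydrophobic-residue count along the rod.

    Bins are equal-width between the extreme bead projections on the
    principal axis; the summed charge profile conserves the net charge for
    any bin count.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if model.n_beads < n_bins:
        raise ValueError("need at least n_bins beads")
    proj, edges = _binned_projection(model.positions, n_bins, model.masses)
    if prop == "charge":
        weights = model.charges
    elif prop == "hydrophobic_count":
        weights = np.array([
            1.0 if lb in HYDROPHOBIC_RESIDUES else 0.0 for lb in model.labels
        ])
    else:
        raise ValueError(f"unknown profile property {prop!r}")
    values, _ = np.histogram(proj, bins=edges, weights=weights)
    return Profile(edges, values, kind="raw_sum",
                   meta={"property": prop, "axis": "principal"})


def hydrophobic_surface_fraction(
    records: list[ResidueRecord],
    rel_sasa_threshold: float = 0.20,
    n_bins: int = 20,
    point_number: int = 960,
    probe_radius: float = 1.4,
) -> Profile:
    """Per-bin fraction of solvent-accessible residues that are hydrophobic.

    Solvent accessibility is computed with the Shrake-Rupley algorithm on
    heavy atoms (Bondi radii) and made relative to the extended Gly-X-Gly
    maximum of each residue type; residues at or above the threshold count
    as accessible.  Bins run along the molecule's principal axis; bins
    without accessible residues are NaN.
    """
    import biotite.structure as struc

    resolved = [
        r for r in records
        if r.resolved and not r.is_ion and r.residue_name in MAX_SASA_GXG
    ]
    resolved = [r for r in resolved if r.n_atoms > 0]
    if not resolved:
        raise ValueError("no resolved residues with atoms for SASA")

    atoms_per_res, kept = [], []
    for rec in resolved:
        heavy = [(nm, el, pos) for nm, el, pos in rec.atoms if el != "H"]
        if not heavy:
            warnings.warn(
                f"residue {rec.residue_name} {rec.residue_index} has no "
                "heavy atoms; skipped", stacklevel=2,
            )
            continue
        kept.append(rec)
        atoms_per_res.append(heavy)

    n_atoms = sum(len(a) for a in atoms_per_res)
    arr = struc.AtomArray(n_atoms)
    coords = np.zeros((n_atoms, 3))
    k = 0
    for ri, (rec, atom_list) in enumerate(zip(kept, atoms_per_res)):
        for nm, el, pos in atom_list:
            arr.chain_id[k] = str(rec.chain_id)[:4]
            arr.res_id[k] = ri + 1
            arr.res_name[k] = rec.residue_name
            arr.atom_name[k] = nm
            arr.element[k] = el
            arr.hetero[k] = False
            coords[k] = pos
            k += 1
    arr.coord = coords
    atom_sasa = struc.sasa(
        arr, probe_radius=probe_radius, point_number=point_number,
        vdw_radii="Single",
    )
    atom_sasa = np.nan_to_num(atom_sasa)

    res_sasa = np.zeros(len(kept))
    for ri in range(len(kept)):
        res_sasa[ri] = atom_sasa[arr.res_id == ri + 1].sum()
    rel = res_sasa / np.array([MAX_SASA_GXG[r.residue_name] for r in kept])
    accessible = rel >= rel_sasa_threshold
    hydrophobic = np.array([
        r.residue_name in HYDROPHOBIC_RESIDUES for r in kept
    ])

    ca = np.array([
        r.atom_position("CA") if r.atom_position("CA") is not None
        else np.mean([p for _, _, p in r.atoms], axis=0)
        for r in kept
    ])
    proj, edges = _binned_projection(ca, n_bins)
    values = np.full(n_bins, np.nan)
    idx = np.clip(np.digitize(proj, edges) - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = (idx == b) & accessible
        if sel.any():
            values[b] = hydrophobic[sel].mean()
    return Profile(
        edges, values, kind="probability",
        meta={"property": "hydrophobic_surface_fraction",
              "rel_sasa_threshold": rel_sasa_threshold},
    )
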