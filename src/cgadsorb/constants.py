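"""Physical constants (CODATA 2018 exact values where defined).

All internal energies are expressed in units of kBT, lengths in Å and
charges in elementary charges; SI conversion happens only where the
electrolyte theory requires it (Debye length, Gouy-Chapman surface term).
The table below is serialized into every run summary so that a stored
trajectory is reproducible from its metadata alone.
"""

from __future__ import annotations

ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol

ANGSTROM = 1.0e-10  # m

CONSTANTS_TABLE = {
    "elementary_charge_C": ELEMENTARY_CHARGE,
    "vacuum_permittivity_F_per_m": VACUUM_PERMITTIVITY,
    "boltzmann_J_per_K": BOLTZMANN,
    "avogadro_per_mol": AVOGADRO,
}

# Average residue masses in Da (amino acid minus one water, i.e. the mass a
# residue contributes inside a chain).  Used for mass-weighted radii of
# gyration; observables on homogeneous chains are insensitive to them.
RESIDUE_MASSES = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09,
    "CYS": 103.14, "GLN": 128.13, "GLU": 129.12, "GLY": 57.05,
    "HIS": 137.14, "ILE": 113.16, "LEU": 113.16, "LYS": 128.17,
    "MET": 131.19, "PHE": 147.18, "PRO": 97.12, "SER": 87.08,
    "THR": 101.10, "TRP": 186.21, "TYR": 163.18, "VAL": 99.13,
}

# Formula masses for the non-residue beads.
TERMINAL_MASSES = {"NTERM": 1.008, "CTERM": 17.007}
ION_MASSES = {"CA": 40.078, "ZN": 65.38, "MG": 24.305, "NA": 22.990,
              "K": 39.098, "CL": 35.45}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Theoretical maximum solvent accessibility of residue X in an extended
# Gly-X-Gly tripeptide (Tien et al. 2013, theoretical set), in Å^2.  Used to
# convert absolute SASA into relative accessibility.
MAX_SASA_GXG = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# Hydrophobic residue set used for the longitudinal hydrophobicity profiles.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "GLY", "ILE", "LEU", "MET", "PHE", "PRO", "VAL"}
)
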