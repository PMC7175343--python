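import numpy as np
import pytest

import cgadsorb as cg
from cgadsorb.synthetic import (
    fibrinogen_mimic_rod,
    make_toy_pdb,
    synthetic_fibrinogen_pdb,
)


@pytest.fixture(scope="session")
def conditions():
    """Reference solution: 25 mM 1:1 salt, water at 298.15 K."""
    return cg.SolutionConditions()


@pytest.fixture(scope="session")
def toy_pdb_text():
    return make_toy_pdb()


@pytest.fixture(scope="session")
def toy_records(toy_pdb_text):
    return cg.load_structure(toy_pdb_text)


@pytest.fixture(scope="session")
def standin_records():
    """Parsed synthetic fibrinogen stand-in (generated, not downloaded)."""
    return cg.load_structure(synthetic_fibrinogen_pdb())


@pytest.fixture(scope="session")
def standin_body(standin_records):
    return cg.coarse_grain_rigid(standin_records)


@pytest.fixture(scope="session")
def mimic_rod():
    return fibrinogen_mimic_rod()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


_MINIMAL_CIF = """\
data_test
loop_
_pdbx_struct_assembly.id
_pdbx_struct_assembly.details
1 author_defined_assembly
2 software_defined_assembly
loop_
_pdbx_struct_assembly_gen.assembly_id
_pdbx_struct_assembly_gen.oper_expression
_pdbx_struct_assembly_gen.asym_id_list
1 1 A
2 1 A
loop_
_pdbx_struct_oper_list.id
_pdbx_struct_oper_list.type
_pdbx_struct_oper_list.matrix[1][1]
_pdbx_struct_oper_list.matrix[1][2]
_pdbx_struct_oper_list.matrix[1][3]
_pdbx_struct_oper_list.vector[1]
_pdbx_struct_oper_list.matrix[2][1]
_pdbx_struct_oper_list.matrix[2][2]
_pdbx_struct_oper_list.matrix[2][3]
_pdbx_struct_oper_list.vector[2]
_pdbx_struct_oper_list.matrix[3][1]
_pdbx_struct_oper_list.matrix[3][2]
_pdbx_struct_oper_list.matrix[3][3]
_pdbx_struct_oper_list.vector[3]
1 'identity operation' 1 0 0 0 0 1 0 0 0 0 1 0
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
ATOM 1 C CA . ALA A 1 1 1 A 0.0 0.0 0.0
"""


@pytest.fixture(scope="session")
def minimal_cif():
    return _MINIMAL_CIF
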