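import numpy as np
import pytest

from catsom.building_blocks import BuildingBlock, detect_role
from catsom.molecules import parse_smiles
from catsom.synthetic_data import gen_building_blocks

COMPOUND_1_SMILES = "CC1=C(C(c2ccccc2)NC(=O)N1)C(=O)Nc1ccc(OC)cc1"


def make_block(smiles: str, block_id: str) -> BuildingBlock:
    mol = parse_smiles(smiles)
    role, matches = detect_role(mol)
    assert role is not None, f"{smiles} has no single reactive role"
    return BuildingBlock(
        molecule=mol, id=block_id, role=role, reactive_sites=tuple(matches)
    )


@pytest.fixture(scope="session")
def benzaldehyde():
    return make_block("O=Cc1ccccc1", "benzaldehyde")


@pytest.fixture(scope="session")
def p_acetoacetaniside():
    return make_block("CC(=O)CC(=O)Nc1ccc(OC)cc1", "p-acetoacetaniside")


@pytest.fixture(scope="session")
def compound_1(benzaldehyde, p_acetoacetaniside):
    from catsom.enumeration import biginelli_product

    return biginelli_product(benzaldehyde, p_acetoacetaniside)


@pytest.fixture(scope="session")
def molecule_pool():
    """A diverse pool of valid molecules: building blocks, products and a
    handful of hand-picked structures covering charges, rings and
    heteroatoms.  Used by property and oracle tests."""
    from catsom.enumeration import enumerate_library

    alds, dics = gen_building_blocks(10, 8, seed=7)
    mols = [b.molecule for b in alds + dics]
    mols += [p.molecule for p in enumerate_library(alds[:5], dics[:5])]
    extra = [
        "c1ccccc1", "CO", "CC(=O)O", "CCN", "c1ccncc1", "C[N+](C)(C)C",
        "CC(=O)[O-]", "NCC(=O)O", "c1cc[nH]c1", "CS(=O)(=O)O", "OCC(O)CO",
        "ClCCCl", "CSC", "NC(=N)N", "c1cnc2[nH]ccc2c1", "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",
    ]
    mols += [parse_smiles(s) for s in extra]
    return mols
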