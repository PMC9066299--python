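import numpy as np
import pytest

from pdecif import (
    build_protein_type_table,
    load_ligand_vocabulary,
    make_complex,
    template_ligand,
    SyntheticComplexSpec,
)


@pytest.fixture(scope="session")
def protein_table():
    return build_protein_type_table()


@pytest.fixture(scope="session")
def ligand_vocab():
    return load_ligand_vocabulary()


@pytest.fixture(scope="session")
def acetone():
    return template_ligand("acetone")


@pytest.fixture(scope="session")
def benzene():
    return template_ligand("benzene")


@pytest.fixture(scope="session")
def ethanol():
    return template_ligand("ethanol")


@pytest.fixture(scope="session")
def small_complex():
    """20 protein / 8 ligand heavy atoms, seeded random placement."""
    return make_complex(SyntheticComplexSpec(n_protein_atoms=20, n_ligand_atoms=8, seed=7))


def pdb_line(
    serial: int,
    name: str,
    resname: str,
    resseq: int,
    xyz,
    altloc: str = " ",
    element: str = "",
    record: str = "ATOM",
    chain: str = "A",
) -> str:
    """Hand-format one wwPDB v3.3 coordinate line for parser tests."""
    x, y, z = xyz
    padded = f" {name:<3s}" if len(name) < 4 else name
    element = element or name[0]
    return (
        f"{record:<6s}{serial:5d} {padded:<4s}{altloc}{resname:<3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )
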