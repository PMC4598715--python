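import random

import pytest

from gnp.scaffold_builder import MonomerTable, default_monomers


@pytest.fixture(scope="session")
def monomers() -> MonomerTable:
    return default_monomers()


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20150928)


def make_peptide_smiles(codes, table) -> str:
    """Linear peptide SMILES from monomer codes (chainable fragments)."""
    return "".join(table[c].fragment for c in codes) + "O"
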