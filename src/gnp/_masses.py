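"""Monoisotopic mass constants and helpers (CODATA-standard values)."""

from __future__ import annotations

from rdkit import Chem
from rdkit.Chem.Descriptors import ExactMolWt

#: Monoisotopic mass of hydrogen-1.
H = 1.00782503207
#: Monoisotopic mass of the water neutral loss.
H2O = 18.0105646863
#: Monoisotopic mass of the ammonia neutral loss.
NH3 = 17.0265491015
#: Mass of a proton (charge carrier for positive-mode adducts).
PROTON = 1.007276466

_PT = Chem.GetPeriodicTable()


def monoisotopic_mass(smiles: str) -> float:
    """Neutral monoisotopic mass of a SMILES string.

    Raises ``ValueError`` for unparseable SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return ExactMolWt(mol)


def atom_base_mass(atom: Chem.Atom) -> float:
    """Most-common-isotope mass of one atom plus its attached hydrogens."""
    return _PT.GetMostCommonIsotopeMass(atom.GetSymbol()) + atom.GetTotalNumHs() * H


def mz_from_neutral(neutral_mass: float, charge: int) -> float:
    """m/z of a protonated ion [M+zH]^z+ from the neutral mass."""
    return (neutral_mass + charge * PROTON) / charge


def neutral_from_mz(mz: float, charge: int) -> float:
    """Neutral mass implied by an observed m/z at the given charge."""
    return mz * charge - charge * PROTON
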