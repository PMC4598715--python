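"""Small RDKit helpers shared by the chemistry modules."""

from __future__ import annotations

from rdkit import Chem
from rdkit import RDLogger

# RDKit is chatty about sanitization on partially-built molecules.
RDLogger.DisableLog("rdApp.warning")


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonical(smiles: str) -> str:
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def attach_substituent(mol: Chem.Mol, atom_idx: int, substituent_smiles: str) -> Chem.Mol:
    """Bond a one-attachment-point substituent to ``atom_idx`` of ``mol``.

    The substituent carries exactly one dummy atom ([*] or [*:n]) marking
    its attachment point; the dummy is removed and a single bond formed.
    """
    sub = mol_from_smiles(substituent_smiles)
    dummies = [a.GetIdx() for a in sub.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise ValueError(
            f"substituent {substituent_smiles!r} must have exactly one attachment atom"
        )
    dummy = dummies[0]
    anchor_nbrs = sub.GetAtomWithIdx(dummy).GetNeighbors()
    if len(anchor_nbrs) != 1:
        raise ValueError(f"attachment atom of {substituent_smiles!r} must have one neighbour")
    anchor = anchor_nbrs[0].GetIdx()

    combined = Chem.RWMol(Chem.CombineMols(mol, sub))
    offset = mol.GetNumAtoms()
    combined.AddBond(atom_idx, offset + anchor, Chem.BondType.SINGLE)
    combined.RemoveAtom(offset + dummy)
    target = combined.GetAtomWithIdx(atom_idx)
    if target.GetNumExplicitHs() > 0:
        target.SetNumExplicitHs(target.GetNumExplicitHs() - 1)
    out = combined.GetMol()
    Chem.SanitizeMol(out)
    return out


def substitute_sites(scaffold: Chem.Mol, assignments: dict[int, str]) -> Chem.Mol:
    """Replace atom-mapped dummy atoms by substituents.

    ``assignments`` maps dummy atom-map numbers (the R-site labels) to
    substituent SMILES carrying a dummy atom with the matching map number;
    RDKit's molzip performs the merges. A substituent of ``"[H]"`` (or a
    dummy-H pair) deletes the site, restoring a hydrogen.
    """
    frags = [scaffold]
    for site, sub_smiles in assignments.items():
        sub = Chem.MolFromSmiles(sub_smiles, sanitize=False)
        if sub is None:
            raise ValueError(f"axis substituent {sub_smiles!r} for site {site} unparseable")
        Chem.SanitizeMol(sub, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_ADJUSTHS)
        frags.append(sub)
    combined = frags[0]
    for f in frags[1:]:
        combined = Chem.CombineMols(combined, f)
    zipped = Chem.molzip(combined)
    zipped = Chem.RemoveHs(zipped)
    Chem.SanitizeMol(zipped)
    return zipped
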