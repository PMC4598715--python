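"""Predicted chemical scaffolds from ordered assembly-line modules.

Modules are applied in genomic order under the co-linearity assumption:
amino-acid monomers condense as amides (optionally N-methylated), ketide
units extend by two carbons with the beta-carbon oxidation state set by the
module's reductive loop (none -> ketone, KR -> hydroxyl, KR+DH ->
alpha,beta-alkene, KR+DH+ER -> methylene), and an acylating starter
condensation prepends a fatty acyl (or an open acyl R-site when the starter
substrate is unresolved). Release is a linear carboxylic acid;
macrocyclization is a combinatorialization axis, not asserted here.
Stereochemistry is never predicted: all centres are emitted unspecified.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from rdkit import Chem

from ._chem import mol_from_smiles
from ._masses import monoisotopic_mass
from .cluster_assembly import AssemblyModule


class ChemistryError(ValueError):
    """Requested bond formation is not available on this chain."""


@dataclass(frozen=True)
class Monomer:
    code: str
    name: str
    monomer_class: str  # amino_acid | ketide_unit | fatty_acyl | sugar
    fragment: str  # chainable SMILES piece
    monoisotopic_mass: float  # of the free (fragment + OH) form


class MonomerTable:
    """The packaged monomer dictionary, keyed by code and by full name."""

    def __init__(self, monomers: Sequence[Monomer]):
        self._by_key: dict[str, Monomer] = {}
        self.monomers = list(monomers)
        for m in monomers:
            self._by_key[m.code] = m
            self._by_key[m.name] = m

    def __getitem__(self, key: str) -> Monomer:
        try:
            return self._by_key[key]
        except KeyError:
            raise KeyError(f"unknown monomer {key!r}") from None

    def __contains__(self, key: str) -> bool:
        return key in self._by_key

    @classmethod
    def load(cls, path: str | Path | None = None) -> "MonomerTable":
        if path is None:
            path = resources.files("gnp.data").joinpath("monomers.tsv")
        monomers = []
        with open(str(path), newline="") as fh:
            rows = [r for r in fh if not r.startswith("#")]
        for row in csv.DictReader(rows, delimiter="\t"):
            frag = row["fragment"]
            monomers.append(
                Monomer(
                    code=row["code"],
                    name=row["name"],
                    monomer_class=row["class"],
                    fragment=frag,
                    monoisotopic_mass=monoisotopic_mass(frag + "O"),
                )
            )
        return cls(monomers)


_DEFAULT_TABLE: Optional[MonomerTable] = None


def default_monomers() -> MonomerTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = MonomerTable.load()
    return _DEFAULT_TABLE


_ALLOWED_REDUCTIVE = [frozenset(), frozenset({"KR"}), frozenset({"KR", "DH"}), frozenset({"KR", "DH", "ER"})]


@dataclass
class Scaffold:
    """A growing (or finished) predicted structure.

    The chain is stored as ordered SMILES fragments whose concatenation,
    terminated by a hydroxyl, is the released linear molecule. Numbered
    R-sites appear as atom-mapped dummy atoms in the SMILES.
    """

    fragments: list[str] = field(default_factory=list)
    site_labels: list[tuple[str, str]] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    n_condensations: int = 0

    def copy(self) -> "Scaffold":
        return Scaffold(
            list(self.fragments),
            list(self.site_labels),
            list(self.provenance),
            list(self.notes),
            self.n_condensations,
        )

    @property
    def raw_smiles(self) -> str:
        """Released (linear free acid) SMILES, un-canonicalized."""
        if not self.fragments:
            raise ChemistryError("empty scaffold")
        return "".join(self.fragments) + "O"

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(mol_from_smiles(self.raw_smiles))

    @property
    def has_open_sites(self) -> bool:
        return any(a.GetAtomicNum() == 0 for a in mol_from_smiles(self.raw_smiles).GetAtoms())

    @property
    def monoisotopic_mass(self) -> float:
        if self.has_open_sites:
            raise ChemistryError("mass undefined while R-sites remain open")
        return monoisotopic_mass(self.raw_smiles)


def extend_peptide(chain: Scaffold, monomer: Monomer, n_methylated: bool = False) -> Scaffold:
    """Condense one amino-acid monomer onto the chain's carboxyl terminus.

    Forms an amide (loss of water in the mass bookkeeping); when
    ``n_methylated`` the new amide nitrogen carries a methyl group.
    """
    if monomer.monomer_class != "amino_acid":
        raise ChemistryError(f"{monomer.name} is not an amino acid")
    frag = monomer.fragment
    if not frag.startswith("N"):
        raise ChemistryError(f"{monomer.name} lacks a free amine")
    if n_methylated:
        if frag.startswith("N1"):
            raise ChemistryError(f"{monomer.name} has a secondary amine; cannot N-methylate")
        frag = "N(C)" + frag[1:]
    out = chain.copy()
    if out.fragments:
        out.n_condensations += 1
    out.fragments.append(frag)
    out.provenance.append(monomer.code + ("+nMe" if n_methylated else ""))
    return out


def extend_ketide(
    chain: Scaffold, at_substrate: str, reductive_state: frozenset[str] | set[str] = frozenset()
) -> Scaffold:
    """Extend the chain by one ketide unit.

    ``at_substrate`` is ``malonate`` or ``methylmalonate`` (codes mal/mmal
    accepted); the reductive state sets the oxidation level of the previous
    carbonyl carbon, which becomes this unit's beta position.
    """
    state = frozenset(reductive_state)
    if state not in _ALLOWED_REDUCTIVE:
        raise ChemistryError(f"chemically unreachable reductive state {set(state) or '{}'}")
    sub = {"malonate": "mal", "methylmalonate": "mmal", "mal": "mal", "mmal": "mmal"}.get(at_substrate)
    if sub is None:
        raise ChemistryError(f"unknown acyltransferase substrate {at_substrate!r}")
    out = chain.copy()
    alpha = "C(C)" if sub == "mmal" else "C"
    if not out.fragments:
        # PKS-initiated chain: the unit itself starts the chain
        out.fragments.append(alpha + "C(=O)")
        out.provenance.append(sub)
        return out
    last = out.fragments[-1]
    if not last.endswith("C(=O)"):
        raise ChemistryError("chain terminus is not a thioester-equivalent carboxyl")
    stem = last[: -len("C(=O)")]
    if state == frozenset({"KR"}):
        out.fragments[-1] = stem + "C(O)"
    elif state == frozenset({"KR", "DH"}):
        out.fragments[-1] = stem + "C"
        alpha = "=C(C)" if sub == "mmal" else "=C"
    elif state == frozenset({"KR", "DH", "ER"}):
        out.fragments[-1] = stem + "C"
    out.n_condensations += 1
    out.fragments.append(alpha + "C(=O)")
    out.provenance.append(sub + (f"+{'+'.join(sorted(state))}" if state else ""))
    return out


#: Atom-map number used for the open acyl R-site of unresolved starters.
ACYL_SITE_MAP = 99


def attach_starter(chain: Scaffold, starter: Monomer | None) -> Scaffold:
    """Acylate the chain's free N-terminal amine with a fatty acyl starter.

    With no resolved starter substrate (FAAL without a specificity call) an
    open R-site labelled ``R_acyl`` is emitted instead.
    """
    out = chain.copy()
    if not out.fragments or not out.fragments[0].startswith("N"):
        raise ChemistryError("chain N-terminus is not free")
    if starter is None:
        out.fragments.insert(0, f"[*:{ACYL_SITE_MAP}]C(=O)")
        out.site_labels.append(("R_acyl", "unresolved fatty acyl starter"))
        out.provenance.insert(0, "R_acyl")
        return out
    if starter.monomer_class != "fatty_acyl":
        raise ChemistryError(f"{starter.name} is not a fatty acyl starter")
    out.fragments.insert(0, starter.fragment)
    out.provenance.insert(0, starter.code)
    out.n_condensations += 1
    return out


_WILDCARD_MAP_BASE = 90


def build_scaffold(
    modules: Sequence[AssemblyModule],
    monomer_table: MonomerTable | None = None,
    starter: str | None = None,
) -> Scaffold:
    """Apply an ordered module list to produce the predicted scaffold.

    Trans-acting modules are excluded (noted for user-directed placement).
    A module with an unknown substrate contributes a wildcard residue whose
    side chain is an unlabelled attachment site. ``starter`` optionally
    names a fatty acyl monomer for a starter-acylated module 1; when module
    1 is starter-flagged but no substrate is given, an open acyl R-site is
    emitted.
    """
    table = monomer_table or default_monomers()
    chain = Scaffold()
    wildcard_n = 0
    starter_flagged = False
    for module in modules:
        if module.trans_acting:
            chain.notes.append(
                f"trans-acting module ({module.substrate}) surfaced, not placed in chain"
            )
            continue
        if module.is_starter:
            starter_flagged = True
        if module.kind == "PKS":
            sub = module.substrate if module.substrate in ("mal", "mmal") else None
            if sub is None and module.substrate in table:
                sub = table[module.substrate].code
            if sub not in ("mal", "mmal"):
                sub = "mal"
                chain.notes.append(f"module {module.index}: AT substrate defaulted to malonate")
            chain = extend_ketide(chain, sub, module.reductive_state)
        else:
            if module.substrate == "X" or module.substrate not in table:
                wildcard_n += 1
                frag = f"NC([*:{_WILDCARD_MAP_BASE + wildcard_n}])C(=O)"
                if chain.fragments:
                    chain.n_condensations += 1
                chain.fragments.append(frag)
                chain.provenance.append("X")
                chain.site_labels.append(
                    (f"R{_WILDCARD_MAP_BASE + wildcard_n}", f"module {module.index}: unknown substrate")
                )
                chain.notes.append(f"module {module.index}: unknown substrate, wildcard emitted")
            else:
                chain = extend_peptide(chain, table[module.substrate], module.n_methylated)
    if starter_flagged:
        chain = attach_starter(chain, table[starter] if starter else None)
    if not chain.fragments:
        raise ChemistryError("no modules could be applied")
    return chain


def emit_structure(scaffold: Scaffold) -> tuple[str, str]:
    """Canonical SMILES and MDL Molfile (V2000) for a scaffold.

    R-site dummy atoms are preserved in both serializations.
    """
    mol = mol_from_smiles(scaffold.raw_smiles)
    smiles = Chem.MolToSmiles(mol)
    molblock = Chem.MolToMolBlock(mol, forceV3000=False)
    return smiles, molblock
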