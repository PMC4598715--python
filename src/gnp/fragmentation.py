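"""In-silico MS/MS fragmentation along documented cleavage pathways.

Cleavable bonds (amide, ester, inverse ester, thioether, glycosidic) are
detected by substructure patterns; every combination of cleavage counts
within per-channel budgets is applied, with combinatorial water/ammonia
losses. Hydrogen-transfer bookkeeping is symmetric: each broken bond moves
one hydrogen from the acyl/alkyl (donor) side to the amine/alkoxy/thio
(acceptor) side, so the neutral fragments of any cleavage set sum exactly
to the parent neutral mass. The first cleavage of a ring bond yields a
ring-opened species of unchanged mass; glycosidic cleavage is gated on an
oxan-2-ol-compatible (pyranose-like) ring around the anomeric carbon.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

from rdkit import Chem

from ._chem import mol_from_smiles
from ._masses import H, H2O, NH3, atom_base_mass, mz_from_neutral
from .combinatorial import CandidateStructure

CLEAVAGE_CHANNELS = ("amide", "ester", "inverse_ester", "thioether", "glycosidic")
#: Rings smaller than this are not opened by amide/ester cleavage.
MIN_CLEAVABLE_RING = 8


@dataclass(frozen=True)
class CleavageSettings:
    """Per-channel (min, max) cleavage counts and neutral-loss budgets."""

    amide: tuple[int, int] = (0, 0)
    ester: tuple[int, int] = (0, 0)
    inverse_ester: tuple[int, int] = (0, 0)
    thioether: tuple[int, int] = (0, 0)
    glycosidic: tuple[int, int] = (0, 0)
    water_loss: tuple[int, int] = (0, 0)
    ammonia_loss: tuple[int, int] = (0, 0)
    max_total_cleavages: int = 6

    def __post_init__(self) -> None:
        for name in CLEAVAGE_CHANNELS + ("water_loss", "ammonia_loss"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name}: need 0 <= min <= max, got ({lo}, {hi})")
        total_max = sum(getattr(self, c)[1] for c in CLEAVAGE_CHANNELS)
        if total_max > self.max_total_cleavages:
            raise ValueError(
                f"sum of channel maxima ({total_max}) exceeds the global cleavage "
                f"bound ({self.max_total_cleavages})"
            )

    @property
    def sum_max(self) -> int:
        return sum(getattr(self, c)[1] for c in CLEAVAGE_CHANNELS)


@dataclass(frozen=True)
class CleavableBond:
    bond_idx: int
    bond_type: str
    donor_atom: int  # acyl/alkyl side end
    acceptor_atom: int  # amine/alkoxy/thio side end (gains the hydrogen)
    in_ring: bool


@dataclass(frozen=True)
class FragmentIon:
    neutral_mass: float
    cleaved_bonds: tuple[tuple[str, int], ...]
    losses: tuple[str, ...]
    side: str  # parent | ring_opened_full | n_terminal_like | c_terminal_like | internal
    substructure_smiles: str
    mz: float = 0.0
    charge: int = 0


_AMIDE = Chem.MolFromSmarts("[CX3](=[OX1])[NX3]")
_ESTER = Chem.MolFromSmarts("[CX3](=[OX1])[OX2][#6]")
_THIOETHER = Chem.MolFromSmarts("[#6][SX2][#6]")
_GLYCOSIDIC = Chem.MolFromSmarts("[CX4;R]([OX2;R])[OX2;!R][#6]")


def _ring_ok(mol: Chem.Mol, bond_idx: int) -> bool:
    """Bond is acyclic or only in rings large enough to open (macrocycles)."""
    ri = mol.GetRingInfo()
    sizes = [len(r) for r in ri.BondRings() if bond_idx in r]
    return not sizes or min(sizes) >= MIN_CLEAVABLE_RING


def _is_pyranose_like(mol: Chem.Mol, anomeric_c: int, ring_o: int) -> bool:
    """The anomeric carbon sits in a six-membered ring with its oxygen."""
    for ring in mol.GetRingInfo().AtomRings():
        if anomeric_c in ring and ring_o in ring and len(ring) == 6:
            return True
    return False


def detect_cleavable_bonds(
    structure: Union[CandidateStructure, str, Chem.Mol]
) -> list[CleavableBond]:
    """Typed table of cleavable bonds in a structure.

    Amide and ester bonds inside rings smaller than eight atoms are not
    cleavable; macrocycle bonds are (ring opening). Classification priority
    when patterns overlap: glycosidic, ester, inverse ester, amide,
    thioether.
    """
    if isinstance(structure, Chem.Mol):
        mol = structure
    else:
        smiles = structure if isinstance(structure, str) else structure.smiles
        mol = mol_from_smiles(smiles)

    table: dict[int, CleavableBond] = {}

    def add(bond_type: str, donor: int, acceptor: int) -> None:
        bond = mol.GetBondBetweenAtoms(donor, acceptor)
        if bond is None or bond.GetIdx() in table:
            return
        if not _ring_ok(mol, bond.GetIdx()):
            return
        table[bond.GetIdx()] = CleavableBond(
            bond.GetIdx(), bond_type, donor, acceptor, bond.IsInRing()
        )

    for m in mol.GetSubstructMatches(_GLYCOSIDIC):
        anomeric, ring_o, exo_o, _aglycone = m
        if _is_pyranose_like(mol, anomeric, ring_o):
            add("glycosidic", anomeric, exo_o)
    for m in mol.GetSubstructMatches(_ESTER):
        add("ester", m[0], m[2])
    for m in mol.GetSubstructMatches(_ESTER):
        add("inverse_ester", m[3], m[2])
    for m in mol.GetSubstructMatches(_AMIDE):
        add("amide", m[0], m[2])
    for m in mol.GetSubstructMatches(_THIOETHER):
        add("thioether", m[0], m[1])
        add("thioether", m[2], m[1])
    return sorted(table.values(), key=lambda b: b.bond_idx)


_HYDROXYL_O = Chem.MolFromSmarts("[OX2H]")
_AMINE_N = Chem.MolFromSmarts("[NX3;H1,H2,H3]")


def _components(n_atoms: int, adjacency: dict[int, list[int]], removed: set[int],
                bond_atoms: dict[int, tuple[int, int]]) -> list[set[int]]:
    seen: set[int] = set()
    comps = []
    blocked = {bond_atoms[b] for b in removed}
    blocked |= {(b2, b1) for b1, b2 in blocked}
    for start in range(n_atoms):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        seen.add(start)
        while stack:
            a = stack.pop()
            for nb in adjacency[a]:
                if nb not in seen and (a, nb) not in blocked:
                    seen.add(nb)
                    comp.add(nb)
                    stack.append(nb)
        comps.append(comp)
    return comps


def enumerate_fragments(
    structure: Union[CandidateStructure, str],
    settings: CleavageSettings,
) -> list[FragmentIon]:
    """Enumerate neutral fragment species under the cleavage budgets.

    Duplicate masses are collapsed, keeping the first provenance. Internal
    fragments (two or more broken ends on an acyclic parent) enter the
    universe only when the summed channel maxima reach three.
    """
    smiles = structure if isinstance(structure, str) else structure.smiles
    mol = mol_from_smiles(smiles)
    n_atoms = mol.GetNumAtoms()
    base = [atom_base_mass(a) for a in mol.GetAtoms()]
    parent_mass = sum(base)

    bonds = detect_cleavable_bonds(mol)
    by_channel: dict[str, list[CleavableBond]] = defaultdict(list)
    for b in bonds:
        by_channel[b.bond_type].append(b)

    adjacency: dict[int, list[int]] = {i: [] for i in range(n_atoms)}
    bond_atoms: dict[int, tuple[int, int]] = {}
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[a].append(b)
        adjacency[b].append(a)
        bond_atoms[bond.GetIdx()] = (a, b)

    hydroxyl_atoms = {m[0] for m in mol.GetSubstructMatches(_HYDROXYL_O)}
    amine_atoms = {m[0] for m in mol.GetSubstructMatches(_AMINE_N)}
    allow_internal = settings.sum_max >= 3

    # channel count vectors within budgets
    ranges = []
    for ch in CLEAVAGE_CHANNELS:
        lo, hi = getattr(settings, ch)
        hi = min(hi, len(by_channel.get(ch, [])))
        lo = min(lo, hi)
        ranges.append(range(lo, hi + 1))

    out: dict[float, FragmentIon] = {}

    def emit(mass: float, cleaved: tuple, losses: tuple, side: str, atoms: Optional[set[int]]) -> None:
        key = round(mass, 6)
        if key in out:
            return
        if atoms is None or len(atoms) == n_atoms:
            sub = Chem.MolToSmiles(mol)
        else:
            sub = Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms))
        out[key] = FragmentIon(mass, cleaved, losses, side, sub)

    def emit_with_losses(mass: float, cleaved: tuple, side: str, atoms: Optional[set[int]],
                         n_oh: int, n_nh: int) -> None:
        wlo, whi = settings.water_loss
        alo, ahi = settings.ammonia_loss
        for w in range(wlo, min(whi, n_oh) + 1):
            for a in range(alo, min(ahi, n_nh) + 1):
                losses = ("H2O",) * w + ("NH3",) * a
                emit(mass - w * H2O - a * NH3, cleaved, losses, side, atoms)

    for counts in itertools.product(*ranges):
        total = sum(counts)
        if total > settings.max_total_cleavages:
            continue
        channel_choices = [
            itertools.combinations(by_channel.get(ch, []), k)
            for ch, k in zip(CLEAVAGE_CHANNELS, counts)
        ]
        for picks in itertools.product(*channel_choices):
            chosen = [b for group in picks for b in group]
            removed = {b.bond_idx for b in chosen}
            cleaved = tuple((b.bond_type, b.bond_idx) for b in chosen)
            if not chosen:
                emit_with_losses(parent_mass, (), "parent", None,
                                 len(hydroxyl_atoms), len(amine_atoms))
                continue
            comps = _components(n_atoms, adjacency, removed, bond_atoms)
            for comp in comps:
                mass = sum(base[i] for i in comp)
                ends = 0
                for b in chosen:
                    acc_in = b.acceptor_atom in comp
                    don_in = b.donor_atom in comp
                    if acc_in and not don_in:
                        mass += H
                        ends += 1
                    elif don_in and not acc_in:
                        mass -= H
                        ends += 1
                if len(comps) == 1:
                    side = "ring_opened_full"
                elif ends >= 2:
                    if not allow_internal:
                        continue
                    side = "internal"
                else:
                    acc = any(b.acceptor_atom in comp and b.donor_atom not in comp for b in chosen)
                    side = "c_terminal_like" if acc else "n_terminal_like"
                n_oh = len(hydroxyl_atoms & comp)
                n_nh = len(amine_atoms & comp)
                emit_with_losses(mass, cleaved, side, comp, n_oh, n_nh)

    return sorted(out.values(), key=lambda f: f.neutral_mass)


def ionize(
    fragments: Iterable[FragmentIon],
    charges: Iterable[int] = (1,),
    min_mass_for_double: float = 400.0,
) -> list[FragmentIon]:
    """Protonated ions ([M+zH]^z+) for the neutral fragment species.

    Doubly charged entries are only produced for neutrals at or above
    ``min_mass_for_double``.
    """
    charges = set(charges)
    if not charges <= {1, 2}:
        raise ValueError("supported charges are 1 and 2")
    ions = []
    for frag in fragments:
        for z in sorted(charges):
            if z == 2 and frag.neutral_mass < min_mass_for_double:
                continue
            ions.append(
                replace(frag, mz=mz_from_neutral(frag.neutral_mass, z), charge=z)
            )
    return ions
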