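"""Combinatorial hypothetical-structure libraries from scaffolds and R-group axes.

A library spec holds scaffolds carrying atom-mapped R-sites ([*:n]),
R-group axes assigning substituents to those sites, and an optional
cyclization axis. Enumeration is the full cartesian product in
deterministic lexicographic order of provenance, with no deduplication:
the library size is exactly |scaffolds| x |cyclization| x product of axis
sizes. Axes may be linked (one choice assigns several sites at once, e.g.
"every methylmalonate swapped to malonate one at a time").

Recipe files are YAML; per-organism recipes modelled on published
combinatorialization settings ship with the package as synthetic
reconstructions of the original scaffolds.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml
from rdkit import Chem

from ._chem import mol_from_smiles, substitute_sites
from ._masses import H2O, monoisotopic_mass


class LibraryValidationError(ValueError):
    pass


@dataclass(frozen=True)
class AxisOption:
    name: str
    groups: tuple[str, ...]  # one substituent SMILES per axis site


@dataclass(frozen=True)
class RGroupAxis:
    """One axis of variability: options assigning substituents to site(s)."""

    label: str
    sites: tuple[int, ...]
    options: tuple[AxisOption, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.options:
            raise LibraryValidationError(f"axis {self.label!r}: no substituents")
        for opt in self.options:
            if len(opt.groups) != len(self.sites):
                raise LibraryValidationError(
                    f"axis {self.label!r} option {opt.name!r}: expected "
                    f"{len(self.sites)} groups, got {len(opt.groups)}"
                )
            for site, group in zip(self.sites, opt.groups):
                mol = Chem.MolFromSmiles(group, sanitize=False)
                if mol is None:
                    raise LibraryValidationError(
                        f"axis {self.label!r} option {opt.name!r}: bad SMILES {group!r}"
                    )
                dummies = [
                    a for a in mol.GetAtoms() if a.GetAtomicNum() == 0 and a.GetAtomMapNum() == site
                ]
                if len(dummies) != 1:
                    raise LibraryValidationError(
                        f"axis {self.label!r} option {opt.name!r}: substituent {group!r} "
                        f"needs exactly one attachment atom mapped {site}"
                    )


@dataclass(frozen=True)
class LibrarySpec:
    name: str
    scaffolds: tuple[tuple[str, str], ...]  # (scaffold_id, smiles)
    axes: tuple[RGroupAxis, ...]
    cyclization: tuple[str, ...] = ("linear",)

    def __post_init__(self) -> None:
        labels = [a.label for a in self.axes]
        if len(set(labels)) != len(labels):
            raise LibraryValidationError("axis labels must be distinct")
        for sid, smiles in self.scaffolds:
            mol = mol_from_smiles(smiles)
            maps = {a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0}
            for axis in self.axes:
                for site in axis.sites:
                    if site not in maps:
                        raise LibraryValidationError(
                            f"scaffold {sid!r} lacks site {site} of axis {axis.label!r}"
                        )


@dataclass(frozen=True)
class CandidateStructure:
    compound_id: str
    smiles: str
    neutral_monoisotopic_mass: float
    provenance: tuple = ()


def enumerate_library(spec: LibrarySpec) -> list[CandidateStructure]:
    """Enumerate the full cartesian product for one library spec.

    No canonical-structure deduplication is applied: the result length is
    exactly the product of the scaffold, cyclization and axis cardinalities.
    """
    out: list[CandidateStructure] = []
    option_lists = [axis.options for axis in spec.axes]
    counter = 0
    for s_idx, (sid, scaffold_smiles) in enumerate(spec.scaffolds):
        scaffold = mol_from_smiles(scaffold_smiles)
        for cyc in spec.cyclization:
            for choice in itertools.product(*option_lists):
                assignments: dict[int, str] = {}
                for axis, opt in zip(spec.axes, choice):
                    for site, group in zip(axis.sites, opt.groups):
                        assignments[site] = group
                mol = substitute_sites(scaffold, assignments) if assignments else scaffold
                smiles = Chem.MolToSmiles(mol)
                if cyc != "linear":
                    smiles = apply_cyclization(smiles, cyc)
                counter += 1
                compound_id = f"{spec.name}_{counter:05d}"
                has_open = any(
                    a.GetAtomicNum() == 0 for a in mol_from_smiles(smiles).GetAtoms()
                )
                mass = float("nan") if has_open else monoisotopic_mass(smiles)
                out.append(
                    CandidateStructure(
                        compound_id,
                        smiles,
                        mass,
                        provenance=(s_idx, cyc) + tuple(opt.name for opt in choice),
                    )
                )
    return out


_CARBOXYL = Chem.MolFromSmarts("[CX3](=O)[OX2H]")
_HYDROXYL = Chem.MolFromSmarts("[CX4][OX2H]")
_PRIMARY_AMINE = Chem.MolFromSmarts("[NX3;H2;!$(NC=O)]")


def apply_cyclization(smiles: str, choice: str) -> str:
    """Close a macrolactone or macrolactam on a finished structure.

    ``choice`` is ``linear`` (identity), ``lactone@oh:first|last`` (ester to
    the first/last free hydroxyl in canonical atom order) or
    ``lactam@amine:first|last`` (amide to a free primary amine). The bond is
    formed to the terminal carboxyl with loss of water.
    """
    if choice == "linear":
        return smiles
    try:
        kind, selector = choice.split("@", 1)
        site_kind, which = selector.split(":", 1)
    except ValueError:
        raise LibraryValidationError(f"bad cyclization choice {choice!r}") from None
    mol = mol_from_smiles(smiles)
    carboxyls = mol.GetSubstructMatches(_CARBOXYL)
    if not carboxyls:
        raise LibraryValidationError("no free carboxyl terminus to cyclize")
    carb_c, carb_o_dbl, carb_oh = carboxyls[-1]
    if kind == "lactone" and site_kind == "oh":
        sites = sorted({m[1] for m in mol.GetSubstructMatches(_HYDROXYL)} - {carb_oh})
    elif kind == "lactam" and site_kind == "amine":
        sites = sorted(m[0] for m in mol.GetSubstructMatches(_PRIMARY_AMINE))
    else:
        raise LibraryValidationError(f"bad cyclization choice {choice!r}")
    if not sites:
        raise LibraryValidationError(f"no {site_kind} site available for {kind}")
    target = sites[0] if which == "first" else sites[-1]
    rw = Chem.RWMol(mol)
    rw.AddBond(carb_c, target, Chem.BondType.SINGLE)
    rw.RemoveAtom(carb_oh)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def load_structure_library(path: str | Path) -> list[CandidateStructure]:
    """Load an id<TAB>smiles structure library (predictions or decoys).

    Unparseable lines are skipped with a warning collected into the raised
    error only when nothing parses at all.
    """
    candidates = []
    errors = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                errors.append(f"line {lineno}: expected id<TAB>smiles")
                continue
            cid, smiles = parts[0], parts[1]
            try:
                mass = monoisotopic_mass(smiles)
            except ValueError:
                errors.append(f"line {lineno}: unparseable SMILES for {cid!r}")
                continue
            candidates.append(CandidateStructure(cid, smiles, mass, provenance=("file", lineno)))
    if not candidates:
        raise LibraryValidationError(
            f"no usable structures in {path}" + (f" ({'; '.join(errors)})" if errors else "")
        )
    return candidates


def write_structure_library(candidates: Sequence[CandidateStructure], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.compound_id}\t{c.smiles}\n")


def load_recipe(path: str | Path) -> list[LibrarySpec]:
    """Load a YAML recipe file into one LibrarySpec per block."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = []
    for i, block in enumerate(doc["blocks"], start=1):
        axes = tuple(
            RGroupAxis(
                label=a["label"],
                sites=tuple(a["sites"]),
                options=tuple(
                    AxisOption(o["name"], tuple(o["groups"])) for o in a["options"]
                ),
                description=a.get("description", ""),
            )
            for a in block.get("axes", [])
        )
        specs.append(
            LibrarySpec(
                name=block.get("name", f"{doc['name']}_b{i}"),
                scaffolds=tuple((s["id"], s["smiles"]) for s in block["scaffolds"]),
                axes=axes,
                cyclization=tuple(block.get("cyclization", ["linear"])),
            )
        )
    return specs


def enumerate_recipe(path: str | Path) -> list[CandidateStructure]:
    """Enumerate all blocks of a recipe file; counts add across blocks."""
    out = []
    for spec in load_recipe(path):
        out.extend(enumerate_library(spec))
    return out


def packaged_recipe(name: str) -> Path:
    """Path to a packaged per-organism recipe fixture."""
    return Path(str(resources.files("gnp.data").joinpath("recipes").joinpath(f"{name}.yaml")))
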