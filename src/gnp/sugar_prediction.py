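"""Deoxysugar prediction from a sugar biosynthetic code, and glycosylation.

The number of deoxysugar slots in a cluster equals its glycosyltransferase
count minus the hexose-specific glycosyltransferases. Every multiset of
that size drawn from the sugar code is scored by two simultaneous counts:
gene families required by the combination but absent from the cluster
(missing) and sugar-gene families present in the cluster but unused by the
combination (extra). The optimum minimizes missing+extra, ties broken by
smaller missing and then by sugar-name order; all co-optimal multisets are
retained. Hexoses called from glycosyltransferase homology are appended
after the optimization.
"""

from __future__ import annotations

import csv
import itertools
import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from ._chem import attach_substituent, mol_from_smiles
from .domain_annotation import GlycosyltransferaseCall
from .scaffold_builder import Scaffold


@dataclass(frozen=True)
class SugarDefinition:
    name: str
    smiles: str  # [*:1]-marked anomeric attachment
    gene_families: frozenset[str]
    sugar_class: str  # deoxyhexose | pentose | hexose

    def __post_init__(self) -> None:
        if self.sugar_class in ("deoxyhexose", "pentose") and not self.gene_families:
            raise ValueError(f"{self.name}: deoxysugar/pentose entries need gene families")


@dataclass
class SugarAssignment:
    n_slots: int
    sugars: tuple[SugarDefinition, ...]
    missing_genes: int
    extra_genes: int
    co_optimal: list[tuple[str, ...]] = field(default_factory=list)
    hexoses: tuple[SugarDefinition, ...] = ()

    @property
    def sugar_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sugars)


def load_sugar_code(path: str | Path | None = None) -> list[SugarDefinition]:
    """Load a sugar biosynthetic code TSV (the packaged one by default).

    The packaged table is a synthetic reconstruction of a 67-deoxysugar
    biosynthetic code; users may supply their own with the same columns.
    """
    if path is None:
        path = resources.files("gnp.data").joinpath("sugar_code_synthetic.tsv")
    out = []
    with open(str(path), newline="") as fh:
        rows = [r for r in fh if not r.startswith("#")]
    for row in csv.DictReader(rows, delimiter="\t"):
        families = frozenset(f for f in (row.get("gene_families") or "").split(";") if f)
        if mol_from_smiles(row["smiles"]) is None:  # pragma: no cover - raises instead
            raise ValueError(f"{row['name']}: bad SMILES")
        out.append(SugarDefinition(row["name"], row["smiles"], families, row["class"]))
    return out


def count_sugar_slots(gt_calls: Sequence[GlycosyltransferaseCall]) -> int:
    """Deoxysugar slot count: total GTs minus hexose-substrate GTs."""
    total = len(gt_calls)
    hexose = sum(1 for c in gt_calls if c.substrate_class == "HEXOSE")
    n = total - hexose
    if n < 0:
        raise RuntimeError("hexose glycosyltransferase count exceeds total")
    return n


def score_combination(
    combo: Sequence[SugarDefinition], cluster_families: Iterable[str]
) -> tuple[int, int]:
    """(missing, extra) gene-family counts for one sugar multiset.

    Set semantics over family names: copy number is ignored because sugar
    enzymes are shared between pathways.
    """
    cluster = set(cluster_families)
    needed: set[str] = set()
    for sugar in combo:
        needed |= sugar.gene_families
    missing = len(needed - cluster)
    extra = len(cluster - needed)
    return missing, extra


#: Refuse exhaustive search above this multiset size.
MAX_SLOTS = 4


def predict_sugars(
    cluster_families: Iterable[str],
    gt_calls: Sequence[GlycosyltransferaseCall],
    code: Sequence[SugarDefinition] | None = None,
    max_slots: int = MAX_SLOTS,
) -> SugarAssignment:
    """Exhaustively optimize the sugar multiset for a cluster.

    Evaluates every multiset (combinations with repetition) of
    ``count_sugar_slots`` deoxysugar/pentose entries from the code.
    """
    code = list(code) if code is not None else load_sugar_code()
    if not code:
        raise ValueError("sugar code is empty")
    n = count_sugar_slots(gt_calls)
    if n > max_slots:
        raise ValueError(
            f"{n} sugar slots exceeds the combinatorial bound ({max_slots}); "
            "raise max_slots explicitly to search anyway"
        )
    hexoses = tuple(
        next(s for s in code if s.name == c.hexose_identity)
        for c in gt_calls
        if c.substrate_class == "HEXOSE" and any(s.name == c.hexose_identity for s in code)
    )
    if n == 0:
        return SugarAssignment(0, (), 0, 0, [], hexoses)

    candidates = sorted(
        (s for s in code if s.sugar_class in ("deoxyhexose", "pentose")), key=lambda s: s.name
    )
    cluster = set(cluster_families)
    best_key: Optional[tuple] = None
    best_combo: tuple[SugarDefinition, ...] = ()
    co_optimal: list[tuple[str, ...]] = []
    best_sum = None
    for combo in itertools.combinations_with_replacement(candidates, n):
        missing, extra = score_combination(combo, cluster)
        names = tuple(s.name for s in combo)
        key = (missing + extra, missing, names)
        if best_key is None or key < best_key:
            best_key = key
            best_combo = combo
        if best_sum is None or missing + extra < best_sum:
            best_sum = missing + extra
            co_optimal = [names]
        elif missing + extra == best_sum:
            co_optimal.append(names)
    missing, extra = score_combination(best_combo, cluster)
    return SugarAssignment(n, best_combo, missing, extra, sorted(co_optimal), hexoses)


#: Free hydroxyls eligible for glycosylation (alcohols, not carboxyls).
_FREE_OH = Chem.MolFromSmarts("[CX4][OX2H]")


def _free_hydroxyl_oxygens(mol: Chem.Mol) -> list[int]:
    return sorted({match[1] for match in mol.GetSubstructMatches(_FREE_OH)})


def glycosylate(
    scaffold: Scaffold | str,
    sugars: Sequence[SugarDefinition],
    seed: int = 0,
    enumerate_all: bool = False,
) -> list[str]:
    """O-glycosylate a scaffold at hydroxyl groups.

    By default each sugar is attached at a hydroxyl chosen by a seeded
    pseudo-random draw without replacement (one product, deterministic per
    seed). With ``enumerate_all`` every ordered placement of the sugar
    multiset over the free hydroxyls is emitted. Returns canonical SMILES.
    """
    smiles = scaffold.smiles if isinstance(scaffold, Scaffold) else scaffold
    mol = mol_from_smiles(smiles)
    sites = _free_hydroxyl_oxygens(mol)
    if len(sites) < len(sugars):
        raise ValueError(
            f"scaffold has {len(sites)} free hydroxyls; {len(sugars)} needed for glycosylation"
        )

    def build(site_choice: Sequence[int]) -> str:
        product = mol
        # attach in descending site order so indices stay valid
        for site, sugar in sorted(zip(site_choice, sugars), reverse=True):
            oxygen = product.GetAtomWithIdx(site)
            product = attach_substituent(product, site, sugar.smiles)
        return Chem.MolToSmiles(product)

    if enumerate_all:
        out = []
        seen = set()
        for placement in itertools.permutations(sites, len(sugars)):
            key = tuple(sorted(zip(placement, (s.name for s in sugars))))
            if key in seen:
                continue
            seen.add(key)
            out.append(build(placement))
        return out
    rng = random.Random(seed)
    placement = rng.sample(sites, len(sugars))
    return [build(placement)]
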