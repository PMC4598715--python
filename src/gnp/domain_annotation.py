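"""Typed, scored biosynthetic domain hits from homology-search result tables.

The homology searches themselves (HMMER against PFAM/SMART-derived domain
models, BLAST against a curated glycosyltransferase database) are pluggable:
this module consumes their result tables. Domain hits are filtered by
class-specific bitscore cutoffs, overlap-merged, and decorated with ranked
substrate calls, sugar-pathway gene families and glycosyltransferase
substrate classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence


class DomainFamily(str, Enum):
    ADENYLATION = "ADENYLATION"
    CONDENSATION = "CONDENSATION"
    THIOLATION = "THIOLATION"
    KETOSYNTHASE = "KETOSYNTHASE"
    ACYLTRANSFERASE = "ACYLTRANSFERASE"
    KETOREDUCTASE = "KETOREDUCTASE"
    DEHYDRATASE = "DEHYDRATASE"
    ENOYLREDUCTASE = "ENOYLREDUCTASE"
    THIOESTERASE = "THIOESTERASE"
    N_METHYLTRANSFERASE = "N_METHYLTRANSFERASE"
    GLYCOSYLTRANSFERASE = "GLYCOSYLTRANSFERASE"
    SUGAR_GENE = "SUGAR_GENE"
    OTHER_TAILORING = "OTHER_TAILORING"


#: Model-name to family mapping for the packaged fixture model vocabulary.
DEFAULT_FAMILY_MAP: dict[str, DomainFamily] = {
    "AMP-binding": DomainFamily.ADENYLATION,
    "Condensation": DomainFamily.CONDENSATION,
    "PP-binding": DomainFamily.THIOLATION,
    "PKS_KS": DomainFamily.KETOSYNTHASE,
    "PKS_AT": DomainFamily.ACYLTRANSFERASE,
    "PKS_KR": DomainFamily.KETOREDUCTASE,
    "PKS_DH": DomainFamily.DEHYDRATASE,
    "PKS_ER": DomainFamily.ENOYLREDUCTASE,
    "Thioesterase": DomainFamily.THIOESTERASE,
    "nMT": DomainFamily.N_METHYLTRANSFERASE,
    "Glycos_transf": DomainFamily.GLYCOSYLTRANSFERASE,
}

#: The 20 TDP-sugar biosynthesis gene families plus the UDP pathway pair
#: needed for pentose sugars (dehydrogenase then oxidative decarboxylase).
SUGAR_GENE_FAMILIES = (
    "glucose-1-phosphate-thymidylyltransferase",
    "4,6-dehydratase",
    "2,3-dehydratase",
    "3-ketoreductase",
    "4-ketoreductase",
    "3-aminotransferase",
    "4-aminotransferase",
    "3,4-isomerase",
    "N,N-dimethyltransferase",
    "N-methyltransferase",
    "C-methyltransferase",
    "O-methyltransferase",
    "3,5-epimerase",
    "5-epimerase",
    "4-O-acetyltransferase",
    "2,3-reductase",
    "3,4-dehydratase",
    "4-amino-4,6-dideoxytransferase",
    "UDP-glucose-dehydrogenase",
    "UDP-glucose-decarboxylase",
)

DEFAULT_SUGAR_FAMILY_MAP: dict[str, str] = {f"Sugar_{f}": f for f in SUGAR_GENE_FAMILIES}

#: Hexose identities assignable from glycosyltransferase homology.
HEXOSE_IDENTITIES = ("glucose", "mannose", "gulose", "N-acetylglucosamine")


class ParseError(ValueError):
    """Malformed result-table line."""


class ConfigurationError(ValueError):
    """A model name has no family/sugar-family mapping."""


@dataclass(frozen=True)
class CutoffProfile:
    """Bitscore significance cutoffs for the four adjustable domain classes."""

    adenylation_cutoff: float = 25.0
    acyltransferase_cutoff: float = 25.0
    thiolation_thioesterase_cutoff: float = 15.0
    other_cutoff: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "adenylation_cutoff",
            "acyltransferase_cutoff",
            "thiolation_thioesterase_cutoff",
            "other_cutoff",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def for_family(self, family: DomainFamily) -> float:
        if family is DomainFamily.ADENYLATION:
            return self.adenylation_cutoff
        if family is DomainFamily.ACYLTRANSFERASE:
            return self.acyltransferase_cutoff
        if family in (DomainFamily.THIOLATION, DomainFamily.THIOESTERASE):
            return self.thiolation_thioesterase_cutoff
        return self.other_cutoff


@dataclass(frozen=True)
class DomainHit:
    orf_id: str
    family: DomainFamily
    model_name: str
    bitscore: float
    ali_start: int  # 1-based residue coordinates
    ali_end: int
    substrate_calls: tuple[tuple[str, float], ...] = ()
    sugar_family: Optional[str] = None
    unknown_substrate: bool = False

    @property
    def top_substrate(self) -> Optional[str]:
        return self.substrate_calls[0][0] if self.substrate_calls else None


@dataclass(frozen=True)
class GlycosyltransferaseCall:
    orf_id: str
    substrate_class: str  # HEXOSE or DEOXYSUGAR
    hexose_identity: Optional[str]
    top_hit: str
    top_score: float


def parse_domtblout(path: str | Path) -> list[dict]:
    """Parse an HMMER3 ``--domtblout`` table into raw hit dicts.

    Column-exact per the HMMER3 format: whitespace-separated, 22 fixed
    columns with the free-text description last. The hmmsearch orientation
    is assumed (target = protein sequence, query = model).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(None, 22)
            if len(parts) < 22:
                raise ParseError(f"{path}: line {lineno}: expected >=22 columns, got {len(parts)}")
            try:
                rows.append(
                    {
                        "target": parts[0],
                        "query": parts[3],
                        "dom_score": float(parts[13]),
                        "ali_from": int(parts[17]),
                        "ali_to": int(parts[18]),
                    }
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return rows


def _overlap_fraction(a: DomainHit, b: DomainHit) -> float:
    ov = min(a.ali_end, b.ali_end) - max(a.ali_start, b.ali_start) + 1
    shorter = min(a.ali_end - a.ali_start, b.ali_end - b.ali_start) + 1
    return max(ov, 0) / max(shorter, 1)


#: Same-family hits overlapping more than this fraction are merged.
MERGE_OVERLAP = 0.30


def ingest_domain_hits(
    domtbl: str | Path,
    cutoffs: CutoffProfile | None = None,
    family_map: Mapping[str, DomainFamily] | None = None,
) -> list[DomainHit]:
    """Read a domtblout table into filtered, merged, sorted domain hits.

    Hits below their class cutoff are dropped; overlapping same-family hits
    on one protein are merged keeping the higher-bitscore hit. Model names
    absent from ``family_map`` are labelled OTHER_TAILORING.
    """
    cutoffs = cutoffs or CutoffProfile()
    family_map = dict(family_map) if family_map is not None else dict(DEFAULT_FAMILY_MAP)
    hits: list[DomainHit] = []
    for row in parse_domtblout(domtbl):
        family = family_map.get(row["query"], DomainFamily.OTHER_TAILORING)
        hit = DomainHit(
            orf_id=row["target"],
            family=family,
            model_name=row["query"],
            bitscore=row["dom_score"],
            ali_start=row["ali_from"],
            ali_end=row["ali_to"],
        )
        if hit.bitscore >= cutoffs.for_family(family):
            hits.append(hit)

    merged: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: (h.orf_id, h.ali_start, -h.bitscore)):
        for i, kept in enumerate(merged):
            if (
                kept.orf_id == hit.orf_id
                and kept.family == hit.family
                and _overlap_fraction(kept, hit) > MERGE_OVERLAP
            ):
                if hit.bitscore > kept.bitscore:
                    merged[i] = hit
                break
        else:
            merged.append(hit)
    merged.sort(key=lambda h: (h.orf_id, h.ali_start))
    return merged


def call_adenylation_substrates(
    hit: DomainHit, substrate_hits: Sequence[tuple[str, float]]
) -> DomainHit:
    """Attach ranked monomer substrate calls to an A or AT domain hit.

    Substrate model names encode the monomer after the first underscore
    (``A_ser``, ``AT_mmal``); ranking is bitscore-descending with an
    alphabetical tiebreak. An empty result list flags the hit as
    unknown-substrate (downstream: wildcard monomer).
    """
    if hit.family not in (DomainFamily.ADENYLATION, DomainFamily.ACYLTRANSFERASE):
        raise ValueError(f"substrate calling applies to A/AT domains, not {hit.family}")
    if not substrate_hits:
        return replace(hit, substrate_calls=(), unknown_substrate=True)
    calls = []
    for model_name, score in substrate_hits:
        monomer = model_name.split("_", 1)[1] if "_" in model_name else model_name
        calls.append((monomer, float(score)))
    calls.sort(key=lambda c: (-c[1], c[0]))
    return replace(hit, substrate_calls=tuple(calls), unknown_substrate=False)


def classify_sugar_genes(
    hits: Iterable[DomainHit],
    sugar_family_models: Mapping[str, str] | None = None,
) -> list[DomainHit]:
    """Label hits on sugar-pathway models with their gene family.

    Hits whose model name maps to one of the packaged sugar-gene families
    become SUGAR_GENE hits; all other hits pass through unchanged. A model
    explicitly marked as a sugar model but missing from the mapping is a
    configuration error.
    """
    mapping = (
        dict(sugar_family_models) if sugar_family_models is not None else dict(DEFAULT_SUGAR_FAMILY_MAP)
    )
    out = []
    for hit in hits:
        if hit.model_name in mapping:
            family = mapping[hit.model_name]
            if family not in SUGAR_GENE_FAMILIES:
                raise ConfigurationError(f"unknown sugar gene family {family!r}")
            out.append(replace(hit, family=DomainFamily.SUGAR_GENE, sugar_family=family))
        elif hit.model_name.startswith("Sugar_"):
            raise ConfigurationError(f"sugar model {hit.model_name!r} missing from family mapping")
        else:
            out.append(hit)
    return out


def assign_gt_substrate(
    orf_id: str,
    homology_results: Sequence[tuple[str, float, str]],
) -> GlycosyltransferaseCall:
    """Classify a glycosyltransferase's substrate from its top homology hit.

    ``homology_results`` rows are (reference_name, score, reference_substrate),
    score-descending. The single top hit decides hexose vs deoxysugar; ties
    go to the alphabetically earlier reference name. With no hits the GT is
    conservatively kept in the deoxysugar count.
    """
    if not homology_results:
        return GlycosyltransferaseCall(orf_id, "DEOXYSUGAR", None, "", 0.0)
    best = sorted(homology_results, key=lambda r: (-r[1], r[0]))[0]
    name, score, substrate = best
    if substrate in HEXOSE_IDENTITIES:
        return GlycosyltransferaseCall(orf_id, "HEXOSE", substrate, name, float(score))
    return GlycosyltransferaseCall(orf_id, "DEOXYSUGAR", None, name, float(score))
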