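"""Grouping annotated genes into biosynthetic clusters and assembly modules.

Clusters are formed by a greedy gap scan (new cluster whenever the distance
from the end of one annotated gene to the start of the next exceeds the
window, 10 kb by default), then filtered: a surviving cluster needs at
least one adenylation-or-acyltransferase domain and at least one
condensation-or-ketosynthase domain. Within a cluster, the concatenated
domain string is parsed into assembly-line modules under the co-linearity
assumption: every condensation-to-thiolation span containing an adenylation
domain is one NRPS module; every ketosynthase-to-thiolation span containing
an acyltransferase domain is one PKS module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .domain_annotation import DomainFamily, DomainHit
from .sequence_io import OrfRecord


@dataclass(frozen=True)
class ClusterSettings:
    max_gene_gap: int = 10_000  # bp

    def __post_init__(self) -> None:
        if self.max_gene_gap <= 0:
            raise ValueError("max_gene_gap must be > 0")


AnnotatedGene = tuple[OrfRecord, list[DomainHit]]


@dataclass
class GeneCluster:
    cluster_id: str
    contig_id: str
    genes: list[AnnotatedGene]

    @property
    def span(self) -> tuple[int, int]:
        return (min(o.start for o, _ in self.genes), max(o.end for o, _ in self.genes))

    def all_hits(self) -> list[DomainHit]:
        return [h for _, hits in self.genes for h in hits]


@dataclass
class AssemblyModule:
    index: int
    kind: str  # NRPS or PKS
    domains: list[DomainHit]
    substrate: str  # top-scoring monomer, "X" when unknown
    reductive_state: frozenset[str] = frozenset()  # subset of {KR, DH, ER}
    n_methylated: bool = False
    is_starter: bool = False
    trans_acting: bool = False


def group_into_clusters(
    genes: Sequence[AnnotatedGene], settings: ClusterSettings | None = None
) -> list[GeneCluster]:
    """Partition annotated genes into pre-filter clusters by the gap scan.

    The gap is measured end-of-previous to start-of-next gene. Genes are
    grouped per contig; input must be position-sorted within each contig.
    Protein-only input (no coordinates) should be passed as a single contig
    so all sequences fall into one cluster.
    """
    settings = settings or ClusterSettings()
    clusters: list[GeneCluster] = []
    current: list[AnnotatedGene] = []
    current_contig: Optional[str] = None

    def flush() -> None:
        if current:
            cid = f"cluster_{len(clusters) + 1}"
            clusters.append(GeneCluster(cid, current_contig or "", list(current)))
            current.clear()

    for orf, hits in genes:
        if current and (
            orf.contig_id != current_contig or orf.start - current[-1][0].end > settings.max_gene_gap
        ):
            flush()
        current_contig = orf.contig_id
        current.append((orf, hits))
    flush()
    return clusters


def filter_clusters(clusters: Sequence[GeneCluster]) -> list[GeneCluster]:
    """Keep clusters with >=1 A-or-AT domain and >=1 C-or-KS domain."""
    kept = []
    for cluster in clusters:
        families = {h.family for h in cluster.all_hits()}
        has_selection = families & {DomainFamily.ADENYLATION, DomainFamily.ACYLTRANSFERASE}
        has_extension = families & {DomainFamily.CONDENSATION, DomainFamily.KETOSYNTHASE}
        if has_selection and has_extension:
            kept.append(cluster)
    return kept


_REDUCTIVE = {
    DomainFamily.KETOREDUCTASE: "KR",
    DomainFamily.DEHYDRATASE: "DH",
    DomainFamily.ENOYLREDUCTASE: "ER",
}


def _gene_domain_families(hits: Sequence[DomainHit]) -> set[DomainFamily]:
    return {h.family for h in hits}


def _is_trans_at_didomain(hits: Sequence[DomainHit]) -> bool:
    """Standalone adenylation(-thiolation) gene with no flanking C or KS."""
    fams = _gene_domain_families(hits)
    return (
        DomainFamily.ADENYLATION in fams
        and not fams & {DomainFamily.CONDENSATION, DomainFamily.KETOSYNTHASE}
        and fams <= {DomainFamily.ADENYLATION, DomainFamily.THIOLATION}
    )


def define_modules(cluster: GeneCluster) -> list[AssemblyModule]:
    """Parse the cluster's concatenated domain string into ordered modules.

    Trans-acting A-T didomain genes are emitted separately (``trans_acting``)
    and never inserted into the chain; their placement is a user decision.
    Two consecutive condensation domains before the first adenylation domain
    mark the leading one as a starter (acylating) condensation, flagged on
    module 1.
    """
    modules: list[AssemblyModule] = []
    trans_modules: list[AssemblyModule] = []
    chain_hits: list[DomainHit] = []

    for orf, hits in cluster.genes:
        ordered = sorted(hits, key=lambda h: h.ali_start)
        if _is_trans_at_didomain(ordered):
            a_hit = next(h for h in ordered if h.family is DomainFamily.ADENYLATION)
            trans_modules.append(
                AssemblyModule(
                    index=-1,
                    kind="NRPS",
                    domains=ordered,
                    substrate=a_hit.top_substrate or "X",
                    trans_acting=True,
                )
            )
        else:
            chain_hits.extend(ordered)

    starter_seen = False
    span: list[DomainHit] = []
    open_kind: Optional[str] = None  # set by the C or KS that opened the span
    for hit in chain_hits:
        if hit.family in (DomainFamily.CONDENSATION, DomainFamily.KETOSYNTHASE):
            if open_kind is not None and not any(
                h.family in (DomainFamily.ADENYLATION, DomainFamily.ACYLTRANSFERASE) for h in span
            ):
                # consecutive C/KS with no selection domain in between: the
                # earlier one is a starter (acylating) condensation
                if not modules:
                    starter_seen = True
            open_kind = "NRPS" if hit.family is DomainFamily.CONDENSATION else "PKS"
            span = [hit]
            continue
        if open_kind is None:
            # domains before any C/KS (e.g. loading module leftovers) are skipped
            continue
        span.append(hit)
        if hit.family is DomainFamily.THIOLATION:
            selection = DomainFamily.ADENYLATION if open_kind == "NRPS" else DomainFamily.ACYLTRANSFERASE
            sel_hits = [h for h in span if h.family is selection]
            if sel_hits:
                sel = sel_hits[0]
                reductive = frozenset(
                    _REDUCTIVE[h.family] for h in span if h.family in _REDUCTIVE
                )
                modules.append(
                    AssemblyModule(
                        index=len(modules) + 1,
                        kind=open_kind,
                        domains=list(span),
                        substrate=sel.top_substrate or "X",
                        reductive_state=reductive if open_kind == "PKS" else frozenset(),
                        n_methylated=any(
                            h.family is DomainFamily.N_METHYLTRANSFERASE for h in span
                        ),
                    )
                )
            open_kind = None
            span = []

    if starter_seen and modules:
        modules[0].is_starter = True
    for i, tm in enumerate(trans_modules, start=1):
        tm.index = len(modules) + i
    return modules + trans_modules


def domain_string(cluster: GeneCluster) -> str:
    """Human-readable domain string, e.g. ``C-A(ser)-T | C-A(val)-nMT-T | TE``."""
    short = {
        DomainFamily.ADENYLATION: "A",
        DomainFamily.CONDENSATION: "C",
        DomainFamily.THIOLATION: "T",
        DomainFamily.KETOSYNTHASE: "KS",
        DomainFamily.ACYLTRANSFERASE: "AT",
        DomainFamily.KETOREDUCTASE: "KR",
        DomainFamily.DEHYDRATASE: "DH",
        DomainFamily.ENOYLREDUCTASE: "ER",
        DomainFamily.THIOESTERASE: "TE",
        DomainFamily.N_METHYLTRANSFERASE: "nMT",
        DomainFamily.GLYCOSYLTRANSFERASE: "GT",
        DomainFamily.SUGAR_GENE: "SUG",
        DomainFamily.OTHER_TAILORING: "TAIL",
    }
    parts = []
    for orf, hits in cluster.genes:
        tokens = []
        for h in sorted(hits, key=lambda h: h.ali_start):
            tok = short[h.family]
            if h.family in (DomainFamily.ADENYLATION, DomainFamily.ACYLTRANSFERASE) and h.top_substrate:
                tok += f"({h.top_substrate})"
            tokens.append(tok)
        parts.append("-".join(tokens))
    return " | ".join(parts)
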