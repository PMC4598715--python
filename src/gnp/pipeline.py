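"""End-to-end orchestration: annotation files in, clusters and scaffolds out.

Glue over the per-stage modules for callers holding a directory of standard
files (protein FASTA or ORF TSV, HMMER3 domtblout, homology TSV). Homology
TSV columns: query, ali_start, reference, score, substrate.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .cluster_assembly import (
    AssemblyModule,
    ClusterSettings,
    GeneCluster,
    define_modules,
    domain_string,
    filter_clusters,
    group_into_clusters,
)
from .domain_annotation import (
    CutoffProfile,
    DomainFamily,
    DomainHit,
    GlycosyltransferaseCall,
    assign_gt_substrate,
    call_adenylation_substrates,
    classify_sugar_genes,
    ingest_domain_hits,
)
from .sequence_io import OrfRecord, read_fasta, read_orf_table


def load_homology_table(path: str | Path) -> list[dict]:
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                {
                    "query": row["query"],
                    "ali_start": int(row["ali_start"]),
                    "reference": row["reference"],
                    "score": float(row["score"]),
                    "substrate": row["substrate"],
                }
            )
    return rows


@dataclass
class ClusterAnalysis:
    cluster: GeneCluster
    modules: list[AssemblyModule]
    gt_calls: list[GlycosyltransferaseCall]
    sugar_gene_families: list[str]

    @property
    def domain_string(self) -> str:
        return domain_string(self.cluster)


def annotate_and_cluster(
    orfs: Sequence[OrfRecord],
    domtbl: str | Path,
    homology: str | Path | None = None,
    cutoffs: CutoffProfile | None = None,
    settings: ClusterSettings | None = None,
) -> list[ClusterAnalysis]:
    """Full annotation pass: hits -> substrates -> clusters -> modules."""
    hits = ingest_domain_hits(domtbl, cutoffs)
    hits = classify_sugar_genes(hits)
    hom_rows = load_homology_table(homology) if homology else []
    substrate_rows = defaultdict(list)
    gt_rows = defaultdict(list)
    for row in hom_rows:
        key = (row["query"], row["ali_start"])
        if row["reference"].startswith(("A_", "AT_")):
            substrate_rows[key].append((row["reference"], row["score"]))
        elif row["reference"].startswith("GTref"):
            gt_rows[row["query"]].append((row["reference"], row["score"], row["substrate"]))

    enriched: list[DomainHit] = []
    for hit in hits:
        if hit.family in (DomainFamily.ADENYLATION, DomainFamily.ACYLTRANSFERASE):
            sub_hits = substrate_rows.get((hit.orf_id, hit.ali_start), [])
            enriched.append(call_adenylation_substrates(hit, sub_hits))
        else:
            enriched.append(hit)

    by_orf = defaultdict(list)
    for hit in enriched:
        by_orf[hit.orf_id].append(hit)
    annotated = [(orf, by_orf.get(orf.orf_id, [])) for orf in orfs if by_orf.get(orf.orf_id)]
    annotated.sort(key=lambda g: (g[0].contig_id, g[0].start))

    analyses = []
    for cluster in filter_clusters(group_into_clusters(annotated, settings)):
        gt_calls = [
            assign_gt_substrate(orf.orf_id, sorted(gt_rows[orf.orf_id], key=lambda r: -r[1]))
            for orf, hits_ in cluster.genes
            if any(h.family is DomainFamily.GLYCOSYLTRANSFERASE for h in hits_)
        ]
        sugar_families = [
            h.sugar_family for h in cluster.all_hits() if h.sugar_family is not None
        ]
        analyses.append(
            ClusterAnalysis(cluster, define_modules(cluster), gt_calls, sugar_families)
        )
    return analyses


def analyze_fixture_dir(
    dirpath: str | Path,
    cutoffs: CutoffProfile | None = None,
    settings: ClusterSettings | None = None,
) -> list[ClusterAnalysis]:
    """Run the annotation pass on a directory written by the fixtures module."""
    dirpath = Path(dirpath)
    orfs = read_orf_table(dirpath / "orfs.tsv")
    homology = dirpath / "homology.tsv"
    return annotate_and_cluster(
        orfs,
        dirpath / "hits.domtbl",
        homology if homology.exists() else None,
        cutoffs,
        settings,
    )
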