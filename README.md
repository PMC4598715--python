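# gnp — genome-guided natural product prediction and LC–MS/MS detection

`gnp` connects bacterial genome sequence to small-molecule discovery for
assembly-line natural products. Nonribosomal peptide synthetases (NRPS) and
type I polyketide synthases (PKS) build their products co-linearly: each
module selects one monomer (an adenylation domain picks an amino acid, an
acyltransferase picks malonate or methylmalonate) and condenses it onto a
growing chain, with optional tailoring (ketoreductase/dehydratase/
enoylreductase loops set the β-carbon oxidation state; N-methyltransferases
methylate the new amide). `gnp` reads annotated biosynthetic gene clusters,
predicts the encoded chemical scaffold as SMILES, expands it into a
combinatorial library of hypothetical structures, fragments every structure
in silico, and scores the library against LC–MS/MS runs of crude extracts
so that the real metabolite's retention time lights up on a
decoy-normalized discovery chart. It is written for natural-product
chemists and genome miners who want to go from a cluster to a targeted
isolation without manually annotating spectra.

## What it does

- **Sequence input** (`gnp.sequence_io`): FASTA in three modes — whole
  genomes (gene calls supplied externally), condensed DNA scanned for all
  six-frame ORFs, or translated proteins.
- **Domain annotation** (`gnp.domain_annotation`): ingests HMMER3
  `--domtblout` tables with class-specific bitscore cutoffs, merges
  overlapping hits, ranks adenylation/acyltransferase substrate calls, and
  classifies glycosyltransferases (hexose vs deoxysugar) and sugar-pathway
  gene families. The homology searches themselves are pluggable.
- **Cluster assembly** (`gnp.cluster_assembly`): greedy gap clustering
  (10 kb default window), the A/AT + C/KS keep-filter, and the module
  grammar — every condensation→thiolation span containing an adenylation
  domain is an NRPS module, every ketosynthase→thiolation span containing
  an acyltransferase is a PKS module. Starter (acylating) condensations are
  flagged; trans-acting A–T didomains are surfaced for user placement,
  never auto-inserted.
- **Scaffold building** (`gnp.scaffold_builder`): RDKit chemistry for
  peptide/ketide extension, reductive-loop simulation, N-methylation and
  fatty-acyl starters; emits canonical SMILES and MDL Molfiles with
  labelled R-sites for unresolved positions.
- **Sugar prediction** (`gnp.sugar_prediction`): deoxysugar slots = total
  glycosyltransferases − hexose-specific ones; every sugar multiset of that
  size from a biosynthetic-code table is scored by
  (pathway genes missing from the cluster) + (cluster sugar genes unused),
  minimized exhaustively with all co-optimal sets retained; scaffolds are
  O-glycosylated at seeded-random (or exhaustively enumerated) hydroxyls.
- **Combinatorial libraries** (`gnp.combinatorial`): cartesian-product
  enumeration over scaffolds × cyclization options × R-group axes, with no
  deduplication, from YAML recipe files.
- **Fragmentation** (`gnp.fragmentation`): amide, ester, inverse-ester,
  thioether and glycosidic cleavages (the last gated on an
  oxan-2-ol/pyranose ring around the anomeric carbon) under per-channel
  (min, max) budgets, plus combinatorial water/ammonia losses. Hydrogen
  transfer is bookkept so the two neutral fragments of any acyclic cleavage
  sum exactly to the parent mass; macrocycle bonds open first into a
  full-mass ring-opened species.
- **Spectral matching** (`gnp.spectral_matching`): precursor windowing with
  charge deconvolution, greedy nearest-m/z fragment matching, binomial-tail
  P1/P2 significance scores, per-scan ranking against a decoy ("dummy")
  library, and the prediction-guided discovery chart (decoy-normalized top
  P1 summed in 0.25-min buckets).
- **Synthetic fixtures** (`gnp.fixtures`): generates annotated clusters
  (FASTA/domtblout/homology TSV), decoy libraries and centroided mzXML/MGF
  runs from domain-string recipes, for tests and demos — no downloads.

## Worked example

Generate a synthetic condensation-initiated lipopeptide cluster with two
trans-acting A–T didomains, analyse it, and enumerate a packaged library:

```bash
gnp fixtures --recipe "C | C-A(thr)-T-C-A(ser)-T | A(asn)-T | TE" --seed 7 --out fix
gnp search-genome --orfs fix/orfs.tsv --domtbl fix/hits.domtbl \
    --homology fix/homology.tsv --out clusters.json
```

`clusters.json` reports one cluster whose module 1 (threonine) carries
`"is_starter": true` — the leading condensation domain acylates the
N-terminal amine, the lipopeptide signature — and one trans-acting
asparagine module surfaced separately. The predicted scaffold is

```
CC(O)C(NC(=O)[*:99])C(=O)NC(CO)C(=O)O
```

a Thr–Ser dipeptide whose N-terminus carries an open `R_acyl` site
(`[*:99]`), because no fatty-acyl substrate was resolved.

Enumerating the packaged thanamycin-style recipe:

```bash
gnp combinatorialize --spec src/gnp/data/recipes/thanamycin.yaml --out thana.tsv
# -> 120 structures -> thana.tsv
```

120 structures = 3 (Dab/Orn/Arg at position 2) × 2 (Asp/Asn) ×
2 (Ser/Thr-homoserine) × 10 (C12–C16 acyl, one or two hydroxyls).
Matching a library against a run:

```bash
gnp match --library pred.tsv --decoys decoys.tsv --spectra run.mzXML \
    --window 18 --p1 10 --p2 10 --amide 1:2 --water 0:1 --out report.json
```

For a synthetic run containing a planted hexapeptide at 12.1 min, the
report shows the planted compound as the only hit (`p1 = 200.0`, 20 matched
fragments) and a discovery chart whose 12.00-min bucket carries the run's
entire normalized signal.

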