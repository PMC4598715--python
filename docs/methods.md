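# Methods

## Scope and model

`gnp` implements the genomes-to-natural-products workflow for modular
(assembly-line) biosynthesis: NRPS, type I modular PKS, NRPS/PKS hybrids
and their glycosylated products. The structural model is strict
co-linearity — module order along the genome equals monomer order in the
product — with module-level chemistry limited to what the domain
architecture encodes: amide condensation, ketide extension with a
β-oxidation state set by the reductive loop, amide N-methylation, starter
acylation, and O-glycosylation. Iterative modules, module skipping,
docking-domain reordering and trans-AT PKSs are out of scope; trans-acting
adenylation–thiolation didomains are detected and surfaced but never
placed automatically, since their position genuinely is a user decision.

Stereochemistry is never predicted. MS/MS cannot resolve it, so every
stereocentre is emitted unspecified, and diastereomeric sugars
(mycaminose/ravidosamine) are represented by one constitution.

## Sequence input and ORF detection

Short DNA inputs (clusters, contigs) are scanned exhaustively on all six
frames: every ATG/GTG/TTG opens an ORF running to the next in-frame stop.
Defaults: minimum protein length 50 aa (bacterial gene-calling
convention), coordinates 0-based half-open on the forward strand so that
clustering-window arithmetic is unambiguous. Whole-genome gene calling is
delegated to external callers (protein FASTA or an ORF table is accepted);
interpolated-context-model prediction is deliberately not reimplemented.
Protein-only input carries no coordinates and is treated as one cluster.

## Domain annotation

Homology searching is pluggable: the module consumes HMMER3 `--domtblout`
tables (parsed column-exactly, with line-numbered errors) and tabular
homology hits, so packaged tests never need external HMM or BLAST
databases. Four adjustable significance cutoffs gate ingestion —
adenylation 25 bits, acyltransferase 25, thiolation/thioesterase 15, all
others 20. These defaults are this package's choices; only the existence
of the four adjustable classes is inherited from practice. Same-family
hits on one protein overlapping by more than 30% of the shorter hit are
merged keeping the higher bitscore, preventing double-counted modules.
Substrate calls (model names like `A_ser`, `AT_mmal`) are ranked by
bitscore with an alphabetical tiebreak; an empty result list flags the
domain unknown-substrate, which propagates to a wildcard residue with an
open attachment site in the scaffold. Glycosyltransferase substrate class
is decided by the single top homology hit; hexose identities are
restricted to glucose, mannose, gulose and N-acetylglucosamine, and a
glycosyltransferase with no hits is conservatively kept in the deoxysugar
count.

## Clustering and the module grammar

Annotated genes are grouped greedily: a new cluster starts when the gap
(end-of-previous to start-of-next) exceeds the window, default 10,000 bp.
Clusters survive only with at least one selection domain (A or AT) and at
least one extension domain (C or KS). Modules are parsed from the
concatenated domain string in genomic order: a C→T span containing an A
domain is an NRPS module; a KS→T span containing an AT is a PKS module;
KR/DH/ER inside a PKS span populate the reductive state and an
N-methyltransferase inside an NRPS span sets the methylation flag. Two
consecutive condensation domains before the first completed module mark
the leading one as a starter (acylating) condensation — the lipopeptide
signature — flagged on module 1. Genes carrying only A (±T) domains are
emitted as trans-acting modules outside the chain.

## Scaffold chemistry

Chains are assembled as concatenated SMILES fragments in N→C (acyl→acid)
order and finalized as the linear free acid; RDKit validates and
canonicalizes every emitted structure. Ketide extension rewrites the
previous carbonyl according to the new module's reductive state: none →
ketone, {KR} → hydroxyl, {KR,DH} → α,β-alkene, {KR,DH,ER} → methylene;
any other subset (e.g. DH without KR) is rejected as chemically
unreachable. Mass bookkeeping is additive: scaffold mass = Σ monomer
masses − (condensations × 18.010565 Da), with N-methyl +14.01565 Da and
the reductive deltas +2.01565 (KR vs ketone), −18.010565 (DH vs alcohol),
+2.01565 (ER vs alkene); the test suite asserts this identity. Release as
a macrolactone/macrolactam is exclusively a combinatorialization axis.
Tailoring enzymes outside the module string (β-hydroxylases, halogenases,
N-acyltransferases) are never auto-applied; the per-organism recipes show
them as explicit R-group axes instead.

The packaged monomer table (20 proteinogenic amino acids plus ornithine,
diaminobutyrate, homoserine, β-hydroxyaspartate, 4-chlorothreonine,
dehydrobutyrate, the two ketide units, and C8–C16 fatty acyls with mono-
and dihydroxy variants) is a reconstruction and is user-extensible: rows
are chainable SMILES fragments whose free form (fragment + OH) defines the
monoisotopic mass.

## Sugar prediction

The deoxysugar slot count is the number of glycosyltransferases minus
those with hexose substrates. All multisets of that size over the sugar
code (combinations with repetition, so duplicated sugars are
representable) are evaluated exhaustively; the objective is
missing + extra over gene-family *names* (presence/absence, not copy
number, because sugar enzymes are shared between pathways), with ties
broken by smaller missing and then lexicographic sugar names. All
co-optimal multisets are reported — deliberately, since subset
relationships between pathways and diastereomer pairs make unique optima
rare. The exhaustive search refuses more than 4 slots by default.
Hexoses called from glycosyltransferase homology are appended after
optimization. Glycosylation attaches each sugar at a free aliphatic
hydroxyl chosen by a seeded draw without replacement; an `enumerate_all`
flag emits every placement as library members instead.

The packaged sugar code (`sugar_code_synthetic.tsv`, 29 entries) is a
synthetic reconstruction of a 67-deoxysugar biosynthetic code built from
published glycogenomics logic (thymidylyltransferase + 4,6-dehydratase
entry into TDP-deoxyhexoses; UDP-glucose dehydrogenase/decarboxylase entry
into pentoses); it is a data file, user-replaceable, and its family
assignments are plausibility-level, not curated measurements.

## Combinatorial libraries

Libraries are exact cartesian products — scaffolds × cyclization options ×
R-group axis options — in deterministic provenance order with no
canonical-structure deduplication, so the library size obeys the product
law exactly. Substituents carry a single atom-mapped attachment dummy and
are merged by RDKit molzip; an axis may be *linked*, assigning several
sites per option (used to express "every methylmalonate swapped to
malonate one at a time"). Recipes are YAML files; the six packaged
per-organism recipes are synthetic reconstructions of published
combinatorialization settings whose axis factorizations yield 768, 576,
576, 32, 42 and 120 members:

- 768 = 4 scaffolds (Asn/Thr trans-didomain placements × linear/cyclic) ×
  3 acyl × 2⁶ binary residue interchanges;
- 576 = 2 forms × 2² Ser/Thr × 2 mal/mmal × 6² ornithine N-states
  ({free, N-OH, N-CHO, N-Ac, N-OH+CHO, N-OH+Ac});
- 32 = 2 forms × 2 Ser/Thr × 2 mal/mmal × 4 ornithine states;
- 42 = linear (6 backbone × 2 × 2 sugar sites) + macrolide (6 × 3 sugar
  options), with the six backbone variants being the all-methylmalonate
  chain plus each single malonate swap — the only reading of
  "methylmalonates interchangeable with malonate" consistent with the
  published total;
- 120 = 3 × 2 × 2 × (5 chain lengths × 2 hydroxylation states).

The exact variable-position assignments behind 576/42/32 are not printed
in the primary literature; the recipes encode the named axes on
reconstructed scaffolds and are labelled synthetic.

## Fragmentation

Cleavable bonds are found by substructure patterns: amide C(=O)–N, ester
C(=O)–O, inverse ester O–C(alkyl), thioether C–S, and glycosidic
(exocyclic C–O at an anomeric carbon inside a six-membered oxygen ring —
the oxan-2-ol gate). Amides and esters inside rings smaller than eight
atoms are not cleavable; macrocycle bonds are, and a single ring cleavage
yields a full-mass ring-opened species, so depsipeptide macrocycles
fragment only after opening. Note that side-chain primary amides (Asn,
Gln) are genuine amide bonds and are cleaved as such.

Hydrogen transfer: each broken bond moves one hydrogen from the
donor (acyl/alkyl) side to the acceptor (N/O/S) side. For a peptide amide
this makes the acceptor fragment the classical y neutral and the donor
fragment the b neutral (ketene-equivalent), and it conserves mass exactly
for any number of simultaneous cleavages — the suite checks agreement with
an independently computed b/y series and 1e−6 Da conservation. Neutral
losses (H₂O, NH₃) are applied combinatorially within budgets, gated on the
fragment's hydroxyl/amine counts. Internal fragments (two or more broken
ends) enter the match universe only when the summed channel maxima reach
three, containing combinatorial blow-up; the summed maxima are globally
bounded at six. Masses are monoisotopic throughout; ions are [M+zH]^z+
with the proton at 1.007276 Da, and z = 2 is only produced for neutrals of
at least 400 Da.

## Scoring and the discovery chart

P1 is −10·log₁₀ of the binomial upper tail P(X ≥ k) with X ~
Binomial(n, q), where n is the candidate's theoretical fragment count, k
its matched count under greedy nearest-m/z pairing (each peak and each
fragment used once), and q = min(1, n_peaks · 2·tol / m/z-range) the
per-fragment chance of hitting a random peak. P2 projects the matched
fraction of total ion current onto the top-half-intensity peak count
n_top = ⌈n_peaks/2⌉: k₂ = round(fraction · n_top), scored with the same
tail statistic. Both scores are clamped to [0, 200]; a zero-peak spectrum
scores (0, 0). These definitions are this package's scoring contract,
designed to live on the conventional cutoff scale (≈5–20 routine, higher
is better); they are not claimed to equal any earlier tool's formulas.

Defaults: fragment tolerance 0.5 Da (ion-trap CID; configurable for
high-resolution data), precursor window ±W Da around the candidate-implied
neutral mass at each allowed charge. Per scan, predictions and decoys are
ranked by (P1, P2, compound id); scans topped by a prediction passing both
cutoffs are reported, their top P1 divided by the scan's mean decoy P1
with the denominator floored at 1.0 (preventing blow-ups when decoys score
≈0), and the normalized values summed into half-open 0.25-minute buckets.

## Synthetic fixtures and what tests do (and do not) show

The fixtures module writes real on-disk formats — protein FASTA, ORF TSV,
HMMER3 domtblout, homology TSV, mzXML and MGF — so every format reader is
exercised. Cluster fixtures place pseudo-random proteins (120 residues per
domain) at controllable intergenic gaps with bitscores of 100, far above
every cutoff; spectrum fixtures contain a structure's theoretical
fragment m/z values at unit intensity plus a seeded fraction of uniform
noise peaks, with the precursor at [M+H]⁺. Decoy libraries are seeded
random linear peptides of length 4–10.

These fixtures emulate the logical structure of real data, not its
physics: no chromatographic peak shapes, isotope envelopes, intensity
structure, co-isolation or calibration error. Passing self-identification
tests therefore demonstrates the correctness of the enumeration, matching,
scoring and normalization machinery — not detection performance on real
extracts, which depends on abundance, ionization and fragmentation
coverage. The published discoveries themselves require the original raw
data and cultures and are explicitly not reproduced here.

## Problem sizes and determinism

Default test and acceptance runs use deliberately small problems — ORF
oracles on ≤10 kb sequences, sugar codes of ≤10 entries with ≤3 slots,
peptides of ≤7 residues, 50-decoy libraries, 120 matching trials — chosen
so the whole suite completes in seconds while still crossing every code
path at the published settings (cleavage budgets 1–2 amide / 0–1 ester /
0–1 water, 18 Da windows, P cutoffs 0–20). Every stochastic component
(fixture noise, decoy generation, glycosylation site choice) takes an
explicit seed, and equal seeds give byte-identical outputs.

## Known limitations

- Substrate prediction quality is entirely inherited from the user's HMM/
  homology tables; the package ships no trained models.
- The scaffold grammar assumes one chain per cluster and ignores
  inter-protein docking order beyond genomic coordinates; mixed-strand and
  multi-contig clusters follow coordinate order, which may not be the
  biosynthetic order.
- Fragment substructure SMILES carry explicit broken-end markers (`[*]`)
  for provenance and depiction; they are not hydrogen-adjusted molecules,
  and fragment masses are computed arithmetically, not from those strings.
- P1/P2 assume peak positions are uniform under the null; structured noise
  (isotope clusters, related ions) inflates scores for all candidates and
  is only partially absorbed by decoy normalization.
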