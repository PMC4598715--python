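"""Sequence input: FASTA reading, six-frame ORF detection and translation.

Three input modes are supported downstream: whole genomes (gene calls
supplied externally), condensed DNA sequences (clusters or contigs, scanned
here for all possible open reading frames) and translated protein FASTA.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq

DNA_CHARS = set("ACGTUNRYSWKMBDHV")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
#: Bacterial start codons accepted by the ORF scanner.
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
#: Default minimum protein length for a reported ORF (bacterial convention).
DEFAULT_MIN_AA = 50


class InputError(ValueError):
    """Unreadable or empty input file."""


class ValidationError(ValueError):
    """Input parsed but violates a record-level invariant."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    alphabet: Literal["dna", "protein"]
    residues: str
    source_file: str = ""


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame on the forward coordinate axis.

    ``start``/``end`` are 0-based half-open base-pair coordinates on the
    forward strand regardless of ``strand``; the span includes the stop
    codon when one terminates the ORF.
    """

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    frame: int
    protein: str


def _detect_alphabet(residues: str, record_id: str) -> str:
    up = residues.upper()
    chars = set(up)
    # Most amino-acid letters double as IUPAC DNA ambiguity codes, so
    # composition (not membership) decides: real DNA is nearly all ACGT(U/N).
    acgt_fraction = sum(up.count(c) for c in "ACGTUN") / len(up)
    if chars <= DNA_CHARS and acgt_fraction >= 0.95:
        return "dna"
    if chars <= PROTEIN_CHARS:
        return "protein"
    bad = "".join(sorted(chars - (DNA_CHARS | PROTEIN_CHARS)))
    raise ValidationError(f"record {record_id!r}: invalid characters {bad!r}")


def read_fasta(path: str | Path, alphabet_hint: str = "auto") -> list[SequenceRecord]:
    """Read a single- or multi-record FASTA file into sequence records.

    The alphabet is auto-detected from character composition unless a hint
    (``dna`` or ``protein``) forces it; records failing the hinted alphabet
    raise :class:`ValidationError` naming the record.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).strip("*")
        if not residues:
            raise ValidationError(f"record {rec.id!r}: empty sequence")
        if rec.id in seen:
            raise ValidationError(f"record {rec.id!r}: duplicate id in {path.name}")
        seen.add(rec.id)
        detected = _detect_alphabet(residues, rec.id)
        if alphabet_hint == "auto":
            alphabet = detected
        else:
            if alphabet_hint == "dna" and not set(residues.upper()) <= DNA_CHARS:
                raise ValidationError(f"record {rec.id!r}: not valid DNA")
            if alphabet_hint == "protein" and not set(residues.upper()) <= PROTEIN_CHARS:
                raise ValidationError(f"record {rec.id!r}: not valid protein")
            alphabet = alphabet_hint
        records.append(SequenceRecord(rec.id, alphabet, residues.upper(), str(path)))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def translate(dna: str, frame: int = 0) -> str:
    """Translate one reading frame with the standard genetic code.

    Start-codon exceptions are not applied (GTG/TTG translate to their
    encoded residue); codons containing ambiguity characters yield ``X``;
    stop codons yield ``*``.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    dna = dna.upper().replace("U", "T")
    if len(dna) < frame + 3:
        raise ValueError("sequence shorter than one codon in this frame")
    trimmed = dna[frame : frame + 3 * ((len(dna) - frame) // 3)]
    return str(Seq(trimmed).translate(table=1))


def find_orfs(dna: SequenceRecord, min_aa: int = DEFAULT_MIN_AA) -> list[OrfRecord]:
    """Detect all start-codon-to-stop spans on all six reading frames.

    Every accepted start codon (ATG/GTG/TTG) opens its own ORF running to
    the next in-frame stop (or the end of the sequence); ORFs whose protein
    is shorter than ``min_aa`` are dropped. Reverse-strand ORFs are
    reported on the forward axis. Output is ordered by start coordinate,
    with ``+`` before ``-`` on ties.
    """
    if dna.alphabet != "dna":
        raise TypeError(f"record {dna.id!r} is not DNA")
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = dna.residues.upper()
    n = len(seq)
    orfs: list[OrfRecord] = []

    def scan(strand_seq: str, strand: str) -> None:
        for frame in (0, 1, 2):
            pos = frame
            while pos + 3 <= len(strand_seq):
                codon = strand_seq[pos : pos + 3]
                if codon in START_CODONS:
                    end = None
                    q = pos
                    while q + 3 <= len(strand_seq):
                        if strand_seq[q : q + 3] in STOP_CODONS:
                            end = q + 3
                            break
                        q += 3
                    stop_found = end is not None
                    if end is None:
                        end = pos + 3 * ((len(strand_seq) - pos) // 3)
                    protein = translate(strand_seq[pos:end], 0)
                    if stop_found:
                        protein = protein[:-1]
                    if len(protein) >= min_aa and "*" not in protein:
                        if strand == "+":
                            fstart, fend = pos, end
                        else:
                            fstart, fend = n - end, n - pos
                        orfs.append(
                            OrfRecord(
                                orf_id="",
                                contig_id=dna.id,
                                start=fstart,
                                end=fend,
                                strand=strand,
                                frame=frame,
                                protein=protein,
                            )
                        )
                pos += 3

    scan(seq, "+")
    scan(str(Seq(seq).reverse_complement()), "-")
    orfs.sort(key=lambda o: (o.start, o.strand != "+", o.end))
    return [
        OrfRecord(f"{dna.id}_orf{i + 1}", o.contig_id, o.start, o.end, o.strand, o.frame, o.protein)
        for i, o in enumerate(orfs)
    ]


def orf_protein_record(orf: OrfRecord) -> SequenceRecord:
    """Protein record for one ORF (feeds the annotation stage)."""
    return SequenceRecord(orf.orf_id, "protein", orf.protein)


def write_orf_table(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    """Write ORFs as a GFF3-like TSV (contig, start, end, strand, frame, orf_id, protein)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["contig", "start", "end", "strand", "frame", "orf_id", "protein"])
        for o in orfs:
            w.writerow([o.contig_id, o.start, o.end, o.strand, o.frame, o.orf_id, o.protein])


def read_orf_table(path: str | Path) -> list[OrfRecord]:
    """Read back an ORF TSV written by :func:`write_orf_table`."""
    orfs = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            orfs.append(
                OrfRecord(
                    orf_id=row["orf_id"],
                    contig_id=row["contig"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    frame=int(row["frame"]),
                    protein=row["protein"],
                )
            )
    return orfs
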