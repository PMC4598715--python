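"""Synthetic fixtures: every pipeline input, generated to disk, no downloads.

Cluster fixtures are written as real on-disk formats (protein FASTA, ORF
TSV, HMMER3 domtblout, homology TSV) so the format readers are exercised;
spectrum fixtures are centroided MS2 scans (mzXML and MGF) whose peaks are
a known structure's theoretical fragment ions plus seeded uniform noise.
Fixed seeds give byte-identical outputs.
"""

from __future__ import annotations

import base64
import math
import random
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from ._masses import mz_from_neutral
from .combinatorial import CandidateStructure, write_structure_library
from .domain_annotation import DomainFamily
from .fragmentation import CleavageSettings, enumerate_fragments, ionize
from .scaffold_builder import MonomerTable, default_monomers
from .sequence_io import OrfRecord, write_orf_table


class RecipeError(ValueError):
    pass


#: domain token -> (family, model name written to the domtblout)
_TOKEN_MODELS = {
    "C": ("CONDENSATION", "Condensation"),
    "A": ("ADENYLATION", "AMP-binding"),
    "T": ("THIOLATION", "PP-binding"),
    "TE": ("THIOESTERASE", "Thioesterase"),
    "KS": ("KETOSYNTHASE", "PKS_KS"),
    "AT": ("ACYLTRANSFERASE", "PKS_AT"),
    "KR": ("KETOREDUCTASE", "PKS_KR"),
    "DH": ("DEHYDRATASE", "PKS_DH"),
    "ER": ("ENOYLREDUCTASE", "PKS_ER"),
    "nMT": ("N_METHYLTRANSFERASE", "nMT"),
    "GT": ("GLYCOSYLTRANSFERASE", "Glycos_transf"),
}

_AA = "ACDEFGHIKLMNPQRSTVWY"
_DOMAIN_SPAN = 120  # residues allotted per synthetic domain


@dataclass(frozen=True)
class DomainToken:
    token: str  # C, A, T, ... , SUG
    argument: str = ""  # substrate code, hexose identity, or sugar family


@dataclass
class FixtureSpec:
    seed: int = 0
    cluster_recipe: str = ""
    spectrum_noise_fraction: float = 0.0
    n_decoys: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.spectrum_noise_fraction < 1:
            raise ValueError("noise fraction must be in [0, 1)")


def _split_outside_parens(text: str, sep: str) -> list[str]:
    parts, depth, buf = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise RecipeError(f"unbalanced ')' in {text!r}")
        if ch == sep and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    if depth != 0:
        raise RecipeError(f"unbalanced '(' in {text!r}")
    parts.append("".join(buf))
    return [p.strip() for p in parts if p.strip()]


def parse_cluster_recipe(recipe: str) -> list[tuple[list[DomainToken], int]]:
    """Parse a domain-string recipe into genes.

    Genes are separated by ``|``, domains by ``-`` (outside parentheses).
    Tokens: C, A(code), T, TE, KS, AT(mal|mmal), KR, DH, ER, nMT,
    GT or GT(hexose-name), SUG(sugar-gene-family). A pseudo-gene
    ``GAP:<bp>`` sets the intergenic gap before the next gene.
    Returns (tokens, gap_before_bp) per gene.
    """
    genes: list[tuple[list[DomainToken], int]] = []
    pending_gap = 100
    for pos, gene_text in enumerate(_split_outside_parens(recipe, "|"), start=1):
        if gene_text.upper().startswith("GAP:"):
            try:
                pending_gap = int(gene_text.split(":", 1)[1])
            except ValueError:
                raise RecipeError(f"gene {pos}: bad gap {gene_text!r}") from None
            continue
        tokens = []
        for dom_text in _split_outside_parens(gene_text, "-"):
            arg = ""
            name = dom_text
            if "(" in dom_text:
                name, rest = dom_text.split("(", 1)
                if not rest.endswith(")"):
                    raise RecipeError(f"gene {pos}: malformed token {dom_text!r}")
                arg = rest[:-1]
            name = name.strip()
            if name not in _TOKEN_MODELS and name != "SUG":
                raise RecipeError(f"gene {pos}: unknown domain token {name!r}")
            if name == "SUG" and not arg:
                raise RecipeError(f"gene {pos}: SUG token needs a gene family")
            tokens.append(DomainToken(name, arg.strip()))
        if not tokens:
            raise RecipeError(f"gene {pos}: empty gene")
        genes.append((tokens, pending_gap))
        pending_gap = 100
    if not genes:
        raise RecipeError("recipe contains no genes")
    return genes


_SUBSTRATE_NAMES = {
    # code -> full monomer name used in homology substrate column
    m: m for m in ("mal", "mmal")
}


def make_cluster_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic annotated cluster: FASTA, ORF TSV, domtblout, homology TSV.

    The files, run through domain annotation and cluster assembly, reproduce
    the recipe's module list exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    table = default_monomers()
    genes = parse_cluster_recipe(spec.cluster_recipe)

    orfs: list[OrfRecord] = []
    domtbl_lines: list[str] = []
    homology_rows: list[tuple] = []
    fasta_lines: list[str] = []
    cursor = 0
    contig = "ctg1"
    for gi, (tokens, gap) in enumerate(genes, start=1):
        orf_id = f"orf_{gi:02d}"
        prot_len = _DOMAIN_SPAN * len(tokens)
        protein = "".join(rng.choice(_AA) for _ in range(prot_len))
        start = cursor + gap
        end = start + 3 * prot_len + 3
        cursor = end
        orfs.append(OrfRecord(orf_id, contig, start, end, "+", start % 3, protein))
        fasta_lines.append(f">{orf_id}\n{protein}")
        for di, tok in enumerate(tokens):
            ali_from = di * _DOMAIN_SPAN + 1
            ali_to = ali_from + _DOMAIN_SPAN - 21
            if tok.token == "SUG":
                model = f"Sugar_{tok.argument}"
            else:
                model = _TOKEN_MODELS[tok.token][1]
            score = 100.0
            domtbl_lines.append(
                f"{orf_id} - {prot_len} {model} - 300 1e-30 {score:.1f} 0.1 1 1 "
                f"1e-30 1e-30 {score:.1f} 0.1 1 280 {ali_from} {ali_to} "
                f"{ali_from} {ali_to} 0.95 -"
            )
            if tok.token in ("A", "AT") and tok.argument:
                code = tok.argument
                name = table[code].name if code in table else code
                prefix = "A" if tok.token == "A" else "AT"
                homology_rows.append(
                    (orf_id, ali_from, f"{prefix}_{code}", 60.0, name)
                )
                # a lower-scoring alternative so rankings are exercised
                alt = "gly" if code != "gly" else "ala"
                homology_rows.append(
                    (orf_id, ali_from, f"{prefix}_{alt}", 35.0, table[alt].name)
                )
            if tok.token == "GT":
                if tok.argument:  # hexose identity
                    homology_rows.append(
                        (orf_id, ali_from, f"GTref_{tok.argument}", 80.0, tok.argument)
                    )
                else:
                    homology_rows.append(
                        (orf_id, ali_from, "GTref_deoxy", 80.0, "deoxysugar")
                    )

    paths = {
        "proteins": outdir / "proteins.faa",
        "orfs": outdir / "orfs.tsv",
        "domtbl": outdir / "hits.domtbl",
        "homology": outdir / "homology.tsv",
    }
    paths["proteins"].write_text("\n".join(fasta_lines) + "\n")
    write_orf_table(orfs, paths["orfs"])
    header = "# synthetic domtblout (fixture)\n"
    paths["domtbl"].write_text(header + "\n".join(domtbl_lines) + "\n")
    hom_header = "query\tali_start\treference\tscore\tsubstrate\n"
    paths["homology"].write_text(
        hom_header + "\n".join("\t".join(map(str, r)) for r in homology_rows) + "\n"
    )
    return paths


def _encode_peaks(peaks: Sequence[tuple[float, float]]) -> str:
    packed = b"".join(struct.pack(">ff", mz, inten) for mz, inten in peaks)
    return base64.b64encode(packed).decode("ascii")


def write_mzxml(scans: Sequence[dict], path: str | Path) -> None:
    """Write centroided MS2 scans as a minimal, pyteomics-readable mzXML.

    Each scan dict: scan_id, rt_min, precursor_mz, precursor_z, peaks.
    """
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f' <msRun scanCount="{len(scans)}">',
    ]
    for scan in scans:
        peaks = scan["peaks"]
        rt_s = scan["rt_min"] * 60.0
        lines += [
            f'  <scan num="{scan["scan_id"]}" msLevel="2" peaksCount="{len(peaks)}"'
            f' retentionTime="PT{rt_s:.3f}S">',
            f'   <precursorMz precursorCharge="{scan["precursor_z"]}">'
            f'{scan["precursor_mz"]:.5f}</precursorMz>',
            '   <peaks precision="32" byteOrder="network" contentType="m/z-int">'
            + _encode_peaks(peaks)
            + "</peaks>",
            "  </scan>",
        ]
    lines += [" </msRun>", "</mzXML>"]
    Path(path).write_text("\n".join(lines) + "\n")


def write_mgf(scans: Sequence[dict], path: str | Path) -> None:
    lines = []
    for scan in scans:
        lines += [
            "BEGIN IONS",
            f"TITLE={scan['scan_id']}",
            f"PEPMASS={scan['precursor_mz']:.5f}",
            f"CHARGE={scan['precursor_z']}+",
            f"RTINSECONDS={scan['rt_min'] * 60.0:.3f}",
        ]
        lines += [f"{mz:.5f} {inten:.1f}" for mz, inten in scan["peaks"]]
        lines.append("END IONS")
    Path(path).write_text("\n".join(lines) + "\n")


def make_spectrum_scan(
    structure: CandidateStructure,
    settings: CleavageSettings,
    noise_fraction: float = 0.0,
    seed: int = 0,
    rt_min: float = 10.0,
    scan_id: str = "1",
) -> dict:
    """One synthetic MS2 scan: theoretical fragment ions plus seeded noise."""
    ions = ionize(enumerate_fragments(structure, settings), charges=(1,))
    if not ions:
        raise ValueError(f"{structure.compound_id} yields no fragments under these settings")
    rng = random.Random(seed)
    mzs = sorted({round(i.mz, 5) for i in ions})
    lo, hi = min(mzs), max(mzs)
    if hi - lo < 1:
        lo, hi = lo - 50, hi + 50
    n_noise = math.ceil(noise_fraction * len(mzs))
    noise = [round(rng.uniform(lo, hi), 5) for _ in range(n_noise)]
    peaks = sorted((mz, 1.0) for mz in mzs + noise)
    return {
        "scan_id": scan_id,
        "rt_min": rt_min,
        "precursor_mz": mz_from_neutral(structure.neutral_monoisotopic_mass, 1),
        "precursor_z": 1,
        "peaks": peaks,
    }


def make_spectrum_fixture(
    structure: CandidateStructure,
    settings: CleavageSettings,
    noise_fraction: float,
    seed: int,
    outdir: str | Path,
    rt_min: float = 10.0,
) -> dict[str, Path]:
    """Write one synthetic scan as both mzXML and MGF."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scan = make_spectrum_scan(structure, settings, noise_fraction, seed, rt_min)
    paths = {"mzxml": outdir / "run.mzXML", "mgf": outdir / "run.mgf"}
    write_mzxml([scan], paths["mzxml"])
    write_mgf([scan], paths["mgf"])
    return paths


def make_decoy_library(
    n: int,
    monomer_table: Optional[MonomerTable] = None,
    seed: int = 0,
    length_range: tuple[int, int] = (4, 10),
) -> list[CandidateStructure]:
    """n seeded random linear peptides drawn from the monomer table."""
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    from ._masses import monoisotopic_mass

    table = monomer_table or default_monomers()
    amino = [m for m in table.monomers if m.monomer_class == "amino_acid"]
    rng = random.Random(seed)
    out = []
    for i in range(1, n + 1):
        length = rng.randint(*length_range)
        picks = [rng.choice(amino) for _ in range(length)]
        smiles = "".join(m.fragment for m in picks) + "O"
        out.append(
            CandidateStructure(
                f"decoy_{i:03d}",
                smiles,
                monoisotopic_mass(smiles),
                provenance=("decoy", tuple(m.code for m in picks)),
            )
        )
    return out
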