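"""Library-vs-LC-MS/MS matching, P1/P2 scoring and the discovery chart.

Candidate structures are precursor-filtered against MS2 scans, their
theoretical fragment ions greedily matched to observed peaks, and each
candidate-scan pair scored with two significance scores. P1 is
-10*log10 of the binomial upper-tail probability of observing at least the
matched number of theoretical fragments under a null in which each
theoretical fragment independently hits a random peak (per-fragment success
probability q = n_peaks * 2 * tolerance / observed m/z range). P2 applies
the same tail statistic to the intensity side: the matched fraction of the
total ion current, projected onto the top-half-intensity peak count. Scans
where a prediction-library compound outranks every decoy contribute their
decoy-normalized P1 (top P1 divided by the mean decoy P1, denominator
floored at 1) to 0.25-minute retention-time buckets of the
prediction-guided discovery chart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import binom

from ._masses import neutral_from_mz
from .combinatorial import CandidateStructure
from .fragmentation import CleavageSettings, FragmentIon, enumerate_fragments, ionize


class EmptyRunError(ValueError):
    pass


@dataclass(frozen=True)
class Spectrum:
    scan_id: str
    rt_min: float
    precursor_mz: float
    precursor_z: Optional[int]
    peaks: tuple[tuple[float, float], ...]  # (mz, intensity), mz-sorted
    ms_level: int = 2

    def __post_init__(self) -> None:
        if self.rt_min < 0:
            raise ValueError("retention time must be >= 0")


@dataclass(frozen=True)
class MatchSettings:
    precursor_window: float = 18.0  # Da, +/- around the candidate mass
    fragment_tolerance: float = 0.5  # Da (ion-trap CID default)
    p1_cutoff: float = 10.0
    p2_cutoff: float = 10.0
    charges: frozenset[int] = frozenset({1, 2})

    def __post_init__(self) -> None:
        if self.precursor_window <= 0 or self.fragment_tolerance <= 0:
            raise ValueError("window and tolerance must be > 0")
        if self.p1_cutoff < 0 or self.p2_cutoff < 0:
            raise ValueError("P score cutoffs must be >= 0")


@dataclass
class ScanMatch:
    scan_id: str
    compound_id: str
    matched_fragments: list[tuple[FragmentIon, tuple[float, float]]]
    p1: float
    p2: float
    rank: int = 0
    is_decoy: bool = False
    rt_min: float = 0.0


@dataclass(frozen=True)
class ChartPoint:
    bucket_start: float  # minutes, multiple of 0.25
    summed_normalized_p1: float
    contributing_scans: tuple[str, ...]


def read_spectra(path: str | Path, format: Optional[str] = None) -> list[Spectrum]:
    """Read MS2 scans from mzXML or MGF, ordered by retention time."""
    path = Path(path)
    fmt = format or ("mgf" if path.suffix.lower() == ".mgf" else "mzxml")
    spectra: list[Spectrum] = []
    if fmt.lower() == "mzxml":
        from pyteomics import mzxml

        with mzxml.read(str(path)) as reader:
            for scan in reader:
                if int(scan.get("msLevel", 1)) != 2:
                    continue
                rt = scan.get("retentionTime", 0.0)
                rt_min = float(rt)  # pyteomics returns minutes
                prec = scan["precursorMz"][0]
                peaks = tuple(
                    sorted(zip(map(float, scan["m/z array"]), map(float, scan["intensity array"])))
                )
                spectra.append(
                    Spectrum(
                        scan_id=str(scan["num"]),
                        rt_min=rt_min,
                        precursor_mz=float(prec["precursorMz"]),
                        precursor_z=int(prec["precursorCharge"]) if "precursorCharge" in prec else None,
                        peaks=peaks,
                    )
                )
    elif fmt.lower() == "mgf":
        from pyteomics import mgf

        with mgf.read(str(path)) as reader:
            for i, scan in enumerate(reader, start=1):
                params = scan["params"]
                rt = params.get("rtinseconds", 0.0)
                charge = params.get("charge")
                peaks = tuple(
                    sorted(zip(map(float, scan["m/z array"]), map(float, scan["intensity array"])))
                )
                spectra.append(
                    Spectrum(
                        scan_id=str(params.get("title", f"scan_{i}")),
                        rt_min=float(rt) / 60.0,
                        precursor_mz=float(params["pepmass"][0]),
                        precursor_z=int(charge[0]) if charge else None,
                        peaks=peaks,
                    )
                )
    else:
        raise ValueError(f"unsupported spectrum format {format!r}")
    if not spectra:
        raise EmptyRunError(f"no MS2 scans in {path}")
    spectra.sort(key=lambda s: s.rt_min)
    return spectra


def precursor_filter(
    spectra: Sequence[Spectrum], candidate: CandidateStructure, settings: MatchSettings
) -> list[Spectrum]:
    """Scans whose precursor-implied neutral mass falls within the window.

    The observed neutral mass is computed from the precursor m/z at the
    scan's declared charge, or at every allowed charge when undeclared.
    """
    kept = []
    for s in spectra:
        charges = [s.precursor_z] if s.precursor_z else sorted(settings.charges)
        for z in charges:
            neutral = neutral_from_mz(s.precursor_mz, z)
            if abs(neutral - candidate.neutral_monoisotopic_mass) <= settings.precursor_window:
                kept.append(s)
                break
    return kept


def match_fragments(
    spectrum: Spectrum,
    fragments: Sequence[FragmentIon],
    settings: MatchSettings,
) -> list[tuple[FragmentIon, tuple[float, float]]]:
    """Greedy nearest-m/z pairing of theoretical ions to observed peaks.

    Candidate pairs within tolerance are taken smallest-|delta| first;
    each observed peak and each theoretical fragment is used at most once.
    """
    pairs = []
    for fi, frag in enumerate(fragments):
        for peak in spectrum.peaks:
            delta = abs(frag.mz - peak[0])
            if delta <= settings.fragment_tolerance:
                pairs.append((delta, fi, peak))
    pairs.sort(key=lambda p: (p[0], p[1], p[2][0]))
    used_frags: set[int] = set()
    used_peaks: set[float] = set()
    matched = []
    for _delta, fi, peak in pairs:
        if fi in used_frags or peak[0] in used_peaks:
            continue
        used_frags.add(fi)
        used_peaks.add(peak[0])
        matched.append((fragments[fi], peak))
    return matched


_P_CLAMP = 200.0


def _tail_score(k: int, n: int, q: float) -> float:
    if k <= 0 or n <= 0:
        return 0.0
    q = min(max(q, 1e-12), 1.0)
    tail = float(binom.sf(k - 1, n, q))
    if tail <= 0:
        return _P_CLAMP
    return min(max(-10.0 * math.log10(tail), 0.0), _P_CLAMP)


def score_match(
    matched: Sequence[tuple[FragmentIon, tuple[float, float]]],
    n_theoretical: int,
    spectrum: Spectrum,
    settings: MatchSettings,
) -> tuple[float, float]:
    """(P1, P2) significance scores for one candidate against one scan."""
    if n_theoretical < 1:
        raise ValueError("need at least one theoretical fragment")
    n_peaks = len(spectrum.peaks)
    if n_peaks == 0:
        return 0.0, 0.0
    mzs = [p[0] for p in spectrum.peaks]
    mz_range = max(mzs) - min(mzs)
    if mz_range <= 0:
        mz_range = 2 * settings.fragment_tolerance
    q = min(1.0, n_peaks * 2 * settings.fragment_tolerance / mz_range)
    p1 = _tail_score(len(matched), n_theoretical, q)

    total_current = sum(p[1] for p in spectrum.peaks)
    matched_current = sum(peak[1] for _, peak in matched)
    frac = matched_current / total_current if total_current > 0 else 0.0
    n_top = max(1, math.ceil(n_peaks / 2))
    k2 = round(frac * n_top)
    p2 = _tail_score(k2, n_top, q)
    return p1, p2


@dataclass
class LibraryIndex:
    """Fragmented, ionized candidate library ready for matching."""

    candidates: list[CandidateStructure]
    fragments: dict[str, list[FragmentIon]]

    @classmethod
    def build(
        cls,
        candidates: Sequence[CandidateStructure],
        cleavage: CleavageSettings,
        charges: Iterable[int] = (1,),
    ) -> "LibraryIndex":
        frags = {}
        for cand in candidates:
            frags[cand.compound_id] = ionize(enumerate_fragments(cand, cleavage), charges)
        return cls(list(candidates), frags)


def score_scan(
    spectrum: Spectrum,
    library: LibraryIndex,
    settings: MatchSettings,
    is_decoy: bool = False,
) -> list[ScanMatch]:
    """Score every precursor-compatible library candidate against one scan."""
    matches = []
    for cand in library.candidates:
        if not precursor_filter([spectrum], cand, settings):
            continue
        frags = library.fragments[cand.compound_id]
        if not frags:
            continue
        matched = match_fragments(spectrum, frags, settings)
        p1, p2 = score_match(matched, len(frags), spectrum, settings)
        matches.append(
            ScanMatch(spectrum.scan_id, cand.compound_id, matched, p1, p2,
                      is_decoy=is_decoy, rt_min=spectrum.rt_min)
        )
    return matches


def rank_and_report(
    spectra: Sequence[Spectrum],
    prediction_library: LibraryIndex,
    decoy_library: Optional[LibraryIndex],
    settings: MatchSettings,
) -> tuple[list[ScanMatch], dict[str, list[ScanMatch]]]:
    """Rank predictions and decoys per scan; report prediction-topped scans.

    Returns (report rows, per-scan full rankings). Report rows are the
    rank-1 prediction matches passing both P cutoffs on scans where the
    top-ranked hit across the union of libraries is a prediction compound.
    """
    report: list[ScanMatch] = []
    rankings: dict[str, list[ScanMatch]] = {}
    for spectrum in spectra:
        matches = score_scan(spectrum, prediction_library, settings)
        if decoy_library is not None:
            matches += score_scan(spectrum, decoy_library, settings, is_decoy=True)
        if not matches:
            continue
        matches.sort(key=lambda m: (-m.p1, -m.p2, m.compound_id))
        for rank, m in enumerate(matches, start=1):
            m.rank = rank
        rankings[spectrum.scan_id] = matches
        top = matches[0]
        if not top.is_decoy and top.p1 >= settings.p1_cutoff and top.p2 >= settings.p2_cutoff:
            report.append(top)
    return report, rankings


BUCKET_MIN = 0.25


def build_discovery_chart(
    report: Sequence[ScanMatch],
    rankings: dict[str, list[ScanMatch]],
) -> list[ChartPoint]:
    """Sum decoy-normalized top P1 values into 0.25-minute buckets.

    For each reported scan the top prediction P1 is divided by the mean
    decoy P1 on that scan (denominator floored at 1.0); buckets are
    half-open [k*0.25, (k+1)*0.25).
    """
    buckets: dict[int, list[tuple[str, float]]] = {}
    for row in report:
        decoy_p1s = [m.p1 for m in rankings.get(row.scan_id, []) if m.is_decoy]
        denom = max(1.0, float(np.mean(decoy_p1s))) if decoy_p1s else 1.0
        normalized = row.p1 / denom
        k = int(math.floor(row.rt_min / BUCKET_MIN))
        buckets.setdefault(k, []).append((row.scan_id, normalized))
    return [
        ChartPoint(k * BUCKET_MIN, sum(v for _, v in rows), tuple(s for s, _ in rows))
        for k, rows in sorted(buckets.items())
    ]


def chart_to_rows(chart: Sequence[ChartPoint]) -> list[tuple[float, float]]:
    """(bucket_start, value) rows for CSV export."""
    return [(p.bucket_start, p.summed_normalized_p1) for p in chart]
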