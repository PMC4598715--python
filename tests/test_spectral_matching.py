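"""Spectrum reading, precursor filtering, P scores, ranking and the chart."""

import math

import pytest
from scipy.stats import binom

from gnp._masses import mz_from_neutral
from gnp.combinatorial import CandidateStructure
from gnp.fragmentation import CleavageSettings, FragmentIon
from gnp.spectral_matching import (
    ChartPoint,
    EmptyRunError,
    LibraryIndex,
    MatchSettings,
    ScanMatch,
    Spectrum,
    build_discovery_chart,
    match_fragments,
    precursor_filter,
    read_spectra,
    score_match,
)
from gnp.fixtures import write_mgf, write_mzxml


def spectrum(peaks, precursor_mz=500.0, z=1, rt=10.0, scan_id="1"):
    return Spectrum(scan_id, rt, precursor_mz, z, tuple(sorted(peaks)))


def ion(mz):
    return FragmentIon(mz - 1.007276466, (), (), "parent", "C", mz=mz, charge=1)


def candidate(mass, cid="c"):
    return CandidateStructure(cid, "C", mass)


SETTINGS = MatchSettings(precursor_window=18.0, fragment_tolerance=0.5, p1_cutoff=0, p2_cutoff=0)


class TestReadSpectra:
    def scans(self):
        return [
            {"scan_id": str(i), "rt_min": 5.0 + i, "precursor_mz": 400.0 + i,
             "precursor_z": 1, "peaks": [(100.0 + i, 1.0), (200.0, 2.0)]}
            for i in range(3)
        ]

    def test_mzxml_round_trip(self, tmp_path):
        p = tmp_path / "run.mzXML"
        write_mzxml(self.scans(), p)
        spectra = read_spectra(p)
        assert len(spectra) == 3
        assert spectra[0].rt_min == pytest.approx(5.0, abs=1e-6)
        assert spectra[1].precursor_mz == pytest.approx(401.0, abs=1e-5)
        assert spectra[2].peaks[0][0] == pytest.approx(102.0, abs=1e-4)

    def test_mgf_round_trip(self, tmp_path):
        p = tmp_path / "run.mgf"
        write_mgf(self.scans()[:1], p)
        (s,) = read_spectra(p)
        assert s.precursor_mz == pytest.approx(400.0, abs=1e-5)
        assert s.rt_min == pytest.approx(5.0, abs=1e-6)

    def test_empty_run_raises(self, tmp_path):
        p = tmp_path / "empty.mzXML"
        write_mzxml([], p)
        with pytest.raises(EmptyRunError):
            read_spectra(p)


class TestPrecursorFilter:
    def test_within_window_kept(self):
        s = spectrum([(100.0, 1.0)], precursor_mz=1008.0, z=1)
        assert precursor_filter([s], candidate(1000.0), SETTINGS)

    def test_narrow_window_drops(self):
        s = spectrum([(100.0, 1.0)], precursor_mz=1008.0, z=1)
        narrow = MatchSettings(precursor_window=1.0, fragment_tolerance=0.5)
        assert precursor_filter([s], candidate(1000.0), narrow) == []

    def test_charge_two_deconvolution(self):
        s = spectrum([(100.0, 1.0)], precursor_mz=504.511, z=2)
        assert precursor_filter([s], candidate(1000.0), SETTINGS)

    def test_wider_window_retains_superset(self):
        scans = [spectrum([(100.0, 1.0)], precursor_mz=mz, z=1, scan_id=str(i))
                 for i, mz in enumerate([1001.0, 1010.0, 1030.0, 1050.0])]
        cand = candidate(1000.0)
        prev: set = set()
        for w in (1.0, 10.0, 30.0, 60.0):
            got = {s.scan_id for s in precursor_filter(
                scans, cand, MatchSettings(precursor_window=w, fragment_tolerance=0.5))}
            assert prev <= got
            prev = got


class TestMatchFragments:
    def test_simple_match(self):
        s = spectrum([(133.06, 1.0)])
        matched = match_fragments(s, [ion(133.061)], SETTINGS)
        assert len(matched) == 1

    def test_nearest_wins_each_peak_used_once(self):
        s = spectrum([(133.06, 1.0)])
        far, near = ion(133.10), ion(133.059)
        matched = match_fragments(s, [far, near], SETTINGS)
        assert len(matched) == 1 and matched[0][0] is near

    def test_empty_spectrum(self):
        assert match_fragments(spectrum([]), [ion(100.0)], SETTINGS) == []


class TestScoreMatch:
    def test_zero_matches_zero_score(self):
        s = spectrum([(100.0, 1.0), (300.0, 1.0)])
        assert score_match([], 10, s, SETTINGS) == (0.0, 0.0)

    def test_binomial_tail_example(self):
        """n=10 theoreticals, q=0.01, k=3 gives P1 about 39.4."""
        # choose peaks so q = n_peaks*2*tol/range = 2*2*0.5/200 = 0.01
        s = spectrum([(100.0, 1.0), (300.0, 1.0)])
        matched = [(ion(100.0), (100.0, 1.0))] * 3
        p1, _ = score_match(matched, 10, s, SETTINGS)
        expected = -10 * math.log10(float(binom.sf(2, 10, 0.01)))
        assert p1 == pytest.approx(expected, abs=1e-6)
        assert p1 == pytest.approx(39.4, abs=0.1)

    def test_more_matches_never_lower_p1(self):
        s = spectrum([(100.0 + i, 1.0) for i in range(20)])
        prev = -1.0
        for k in range(0, 8):
            matched = [(ion(100.0 + i), (100.0 + i, 1.0)) for i in range(k)]
            p1, _ = score_match(matched, 10, s, SETTINGS)
            assert p1 >= prev
            prev = p1

    def test_zero_peak_spectrum(self):
        assert score_match([], 5, spectrum([]), SETTINGS) == (0.0, 0.0)


class TestChart:
    def row(self, scan_id, rt, p1):
        return ScanMatch(scan_id, "pred", [], p1, p1, rank=1, is_decoy=False, rt_min=rt)

    def decoys(self, scan_id, p1s):
        return [ScanMatch(scan_id, f"d{i}", [], p, p, is_decoy=True) for i, p in enumerate(p1s)]

    def test_bucket_sum(self):
        report = [self.row("a", 12.10, 30.0), self.row("b", 12.20, 20.0)]
        rankings = {"a": self.decoys("a", [10.0]), "b": self.decoys("b", [10.0])}
        (pt,) = build_discovery_chart(report, rankings)
        assert pt.bucket_start == 12.0
        assert pt.summed_normalized_p1 == pytest.approx(5.0)

    def test_half_open_boundary(self):
        report = [self.row("a", 12.25, 30.0)]
        (pt,) = build_discovery_chart(report, {"a": self.decoys("a", [10.0])})
        assert pt.bucket_start == 12.25

    def test_normalization_ratio(self):
        report = [self.row("a", 1.0, 40.0)]
        (pt,) = build_discovery_chart(report, {"a": self.decoys("a", [10.0, 10.0])})
        assert pt.summed_normalized_p1 == pytest.approx(4.0)

    def test_denominator_floor(self):
        report = [self.row("a", 1.0, 40.0)]
        (pt,) = build_discovery_chart(report, {"a": self.decoys("a", [0.0, 0.0])})
        assert pt.summed_normalized_p1 == pytest.approx(40.0)

    def test_chart_total_equals_sum_of_normalized(self):
        report = [self.row(str(i), 0.1 * i, 10.0 + i) for i in range(20)]
        rankings = {str(i): self.decoys(str(i), [5.0]) for i in range(20)}
        chart = build_discovery_chart(report, rankings)
        total = sum(p.summed_normalized_p1 for p in chart)
        expected = sum((10.0 + i) / 5.0 for i in range(20))
        assert total == pytest.approx(expected)
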