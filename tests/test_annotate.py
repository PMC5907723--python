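"""TIR detection, flank-architecture classification and family
summaries."""

import pytest

from satarscan.align import revcomp
from satarscan.annotate import (FlankParams, TIRParams, classify_flanks,
                                detect_tir, summarize_family)
from satarscan.families import ElementOccurrence, Family
from satarscan.ssr import find_ssrs

from conftest import random_seq


_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def element_with_tir(rng, size, tir_len, mismatch_positions=()):
    """Element whose first tir_len bp pair with the last tir_len bp as
    an inverted repeat, with the four columns just past the TIR forced
    to mismatch so the call boundary is unambiguous."""
    core = random_seq(rng, size - tir_len, gc=0.45)
    head = core[:tir_len]
    tail = list(revcomp(head))
    for p in mismatch_positions:
        tail[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tail[p]]
    element = list(head + core[tir_len:] + "".join(tail))
    # column i of the terminal comparison pairs element[i] with
    # element[size-1-i]; break pairing for the columns after the TIR
    for i in range(tir_len, min(tir_len + 4, size // 2, 300)):
        j = size - 1 - i
        if element[i] == _COMP[element[j]]:
            element[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[element[i]]
    return "".join(element)


class TestDetectTIR:
    def test_perfect_forty_bp_tir(self, rng):
        element = element_with_tir(rng, 400, 40)
        report = detect_tir(element)
        assert report.present
        assert report.length == 40
        assert report.identity == 1.0
        assert report.left_offset == 0 and report.right_offset == 0

    def test_random_sequence_has_no_tir(self, rng):
        for _ in range(5):
            report = detect_tir(random_seq(rng, 400, gc=0.45))
            assert not report.present

    def test_two_mismatches_in_forty(self, rng):
        element = element_with_tir(rng, 400, 40, mismatch_positions=(10, 20))
        report = detect_tir(element)
        assert report.present
        assert report.identity == pytest.approx(38 / 40)

    def test_strand_invariant(self, rng):
        element = element_with_tir(rng, 400, 50)
        fwd = detect_tir(element)
        rev = detect_tir(revcomp(element))
        assert (fwd.present, fwd.length, fwd.identity) == \
            (rev.present, rev.length, rev.identity)

    def test_too_short_element_flagged(self):
        report = detect_tir("ACGTACGT")
        assert not report.present and report.too_short

    def test_long_tir_like_autonomous_partner(self, rng):
        element = element_with_tir(rng, 900, 300)
        report = detect_tir(element)
        assert report.present and report.length == 300


def occ(scaffold, start, end, family="fam01"):
    return ElementOccurrence(family, scaffold, start, end, "+", 0.95, 1.0)


class TestClassifyFlanks:
    def _scaffold(self, rng, left, middle, right, pad=200):
        a = random_seq(rng, pad, gc=0.5)
        b = random_seq(rng, pad, gc=0.5)
        seq = a + left + middle + right + b
        start = len(a) + len(left)
        return seq, start, start + len(middle)

    def test_satellites_both_sides(self, rng):
        seq, s, e = self._scaffold(rng, "TA" * 7, random_seq(rng, 400, 0.45),
                                   "TA" * 7)
        call = classify_flanks(occ("c", s, e), seq, find_ssrs(seq))
        assert call.category == "microsatellite"
        assert call.left_satellite is not None

    def test_exact_ten_bp_duplication(self, rng):
        tsd = "GCTTACGGAC"
        seq, s, e = self._scaffold(rng, tsd, random_seq(rng, 400, 0.45), tsd)
        call = classify_flanks(occ("c", s, e), seq, find_ssrs(seq))
        assert call.category == "tsd"
        assert call.tsd_len == 10 and call.tsd_seq == tsd

    def test_complex_unrelated_flanks(self, rng):
        while True:
            seq, s, e = self._scaffold(rng, "", random_seq(rng, 400, 0.45), "")
            call = classify_flanks(occ("c", s, e), seq, find_ssrs(seq))
            if call.category != "tsd":  # guard against chance repeats
                break
        assert call.category == "neither"

    def test_satellite_never_masquerades_as_tsd(self, rng):
        # a (TA)n tract on one side would produce a perfect "duplication"
        # of itself; the satellite guard must veto the TSD call
        seq, s, e = self._scaffold(rng, "TA" * 10,
                                   random_seq(rng, 400, 0.45), "TA" * 10)
        # shift the element bounds so only one side abuts the satellite
        call = classify_flanks(occ("c", s, e + 20), seq, find_ssrs(seq))
        assert call.category != "tsd"

    def test_scaffold_end_is_unresolved(self, rng):
        seq = random_seq(rng, 430, gc=0.45)
        call = classify_flanks(occ("c", 10, 410), seq, find_ssrs(seq))
        assert call.category == "unresolved"


class TestSummarizeFamily:
    def _occurrences(self, categories):
        from satarscan.annotate import FlankClassification
        out = []
        for i, cat in enumerate(categories):
            o = occ("c", 1000 * i, 1000 * i + 400)
            o.flank = FlankClassification(cat)
            out.append(o)
        return out

    def test_percentages(self):
        fam = Family("fam01", "A" * 400, 10)
        occs = self._occurrences(["microsatellite"] * 7 + ["tsd"] * 2 +
                                 ["neither"])
        s = summarize_family(fam, occs)
        assert (s.pct_microsatellite, s.pct_tsd, s.pct_neither) == \
            (70.0, 20.0, 10.0)
        assert s.n_total == 10

    def test_linked_share_counts_multi_element_arrays(self):
        from satarscan.arrays import ElementArray
        fam = Family("fam01", "A" * 400, 10)
        occs = self._occurrences(["microsatellite"] * 10)
        arrays = [ElementArray("c", occs[:3]),
                  *[ElementArray("c", [o]) for o in occs[3:]]]
        s = summarize_family(fam, occs, arrays)
        assert s.pct_linked_or_fused == pytest.approx(30.0)

    def test_unresolved_counts_in_total_only(self):
        fam = Family("fam01", "A" * 400, 4)
        occs = self._occurrences(["microsatellite", "unresolved",
                                  "unresolved", "tsd"])
        s = summarize_family(fam, occs)
        assert s.pct_unresolved == 50.0
        total = (s.pct_microsatellite + s.pct_tsd + s.pct_neither +
                 s.pct_unresolved)
        assert total == pytest.approx(100.0)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_family(Family("fam01", "A" * 400, 0), [])
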