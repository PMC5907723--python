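"""Candidate element extraction.

Segments lying between consecutive targeting satellites are candidate
satellite-targeted elements when they pass the discovery filters
(250-800 bp, >= 20% GC by default). A flank-probe mode additionally
emits fixed windows beside every targeting satellite, the fallback used
for genomes where the inter-satellite scan returns nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ssr import SSRDomain, SSRThresholds, targeting_domains


class UndefinedContentError(ValueError):
    """GC content is undefined (no unambiguous bases)."""


def gc_fraction(sequence: str) -> float:
    """(G+C) / (A+C+G+T); N and other ambiguity codes are ignored in
    both numerator and denominator."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise UndefinedContentError("no unambiguous bases in sequence")
    return (counts["G"] + counts["C"]) / denom


@dataclass(frozen=True)
class CandidateParams:
    min_len: int = 250
    max_len: int = 800
    min_gc: float = 0.20
    max_offset: int = 0  # candidates are exactly inter-satellite intervals


@dataclass(frozen=True)
class CandidateSegment:
    """A putative element: an inter-satellite interval (or a flank
    probe) that passed the size and GC filters."""

    scaffold_id: str
    start: int
    end: int
    sequence: str
    gc: float
    left_ssr: SSRDomain | None = None
    right_ssr: SSRDomain | None = None
    flank_probe: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_candidates(sequence: str, ssrs: list[SSRDomain],
                       params: CandidateParams | None = None,
                       thresholds: SSRThresholds | None = None,
                       scaffold_id: str = "") -> list[CandidateSegment]:
    """Candidates between consecutive targeting satellites.

    For every pair of consecutive non-overlapping targeting satellites
    the intervening segment is emitted iff its length lies within
    [min_len, max_len] and its GC fraction is >= min_gc. Output is in
    coordinate order.
    """
    params = params or CandidateParams()
    seq = sequence.upper()
    targets = targeting_domains(ssrs, thresholds)
    out: list[CandidateSegment] = []
    for left, right in zip(targets, targets[1:]):
        start, end = left.end, right.start
        if not params.min_len <= end - start <= params.max_len:
            continue
        segment = seq[start:end]
        try:
            gc = gc_fraction(segment)
        except UndefinedContentError:
            continue
        if gc < params.min_gc:
            continue
        out.append(CandidateSegment(scaffold_id, start, end, segment, gc,
                                    left_ssr=left, right_ssr=right))
    return out


def probe_satellite_flanks(sequence: str, ssrs: list[SSRDomain],
                           window: int = 400,
                           thresholds: SSRThresholds | None = None,
                           scaffold_id: str = "") -> list[CandidateSegment]:
    """Windows immediately flanking every targeting satellite.

    Probes are clipped at scaffold ends and at neighbouring targeting
    satellites, so the shared interval between two nearby satellites is
    emitted once. No size/GC filter is applied: probes feed clustering
    directly.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    seq = sequence.upper()
    targets = targeting_domains(ssrs, thresholds)
    intervals: set[tuple[int, int]] = set()
    for i, sat in enumerate(targets):
        left_bound = targets[i - 1].end if i > 0 else 0
        right_bound = targets[i + 1].start if i + 1 < len(targets) else len(seq)
        left = (max(left_bound, sat.start - window), sat.start)
        right = (sat.end, min(right_bound, sat.end + window))
        for start, end in (left, right):
            if end > start:
                intervals.add((start, end))
    out = []
    for start, end in sorted(intervals):
        segment = seq[start:end]
        try:
            gc = gc_fraction(segment)
        except UndefinedContentError:
            continue
        out.append(CandidateSegment(scaffold_id, start, end, segment, gc,
                                    flank_probe=True))
    return out
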