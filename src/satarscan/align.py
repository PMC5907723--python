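"""Alignment helpers shared by the discovery and annotation stages.

Genome-scale searches (probing an assembly with a family consensus,
re-locating flank anchors in a second assembly) run through edlib's
bit-parallel infix aligner; fine-grained work near element termini
(TIR detection, truncation measurement, split-host checks) uses
Biopython's PairwiseAligner with an affine-gap DNA scheme
(match +1, mismatch -2, gap open -4, gap extend -1).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
from Bio import Align

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: Default affine-gap scoring used throughout the package.
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -4, -1


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware; case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def make_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


@dataclass(frozen=True)
class LocalHit:
    """One pairwise local alignment, in 0-based half-open coordinates."""

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _hit_from_alignment(alignment) -> LocalHit:
    counts = alignment.counts()
    matches = counts.identities
    columns = counts.identities + counts.mismatches + counts.gaps
    (a_start, a_end) = (alignment.aligned[0][0][0], alignment.aligned[0][-1][1])
    (b_start, b_end) = (alignment.aligned[1][0][0], alignment.aligned[1][-1][1])
    return LocalHit(alignment.score, int(a_start), int(a_end),
                    int(b_start), int(b_end), int(matches), int(columns))


def best_local(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> LocalHit | None:
    """Best local alignment of ``a`` against ``b``; None when score <= 0."""
    if not a or not b:
        return None
    aligner = aligner or make_local_aligner()
    try:
        alignment = aligner.align(a, b)[0]
    except (IndexError, ValueError):
        return None
    if alignment.score <= 0 or len(alignment.aligned[0]) == 0:
        return None
    return _hit_from_alignment(alignment)


@dataclass(frozen=True)
class InfixHit:
    """An edlib infix ('HW') hit of a whole query inside a target."""

    start: int
    end: int  # exclusive
    distance: int
    query_length: int

    @property
    def identity(self) -> float:
        # Edit-distance identity over the longer of query / matched span;
        # a lower bound on matches-per-column for near-full-length hits.
        span = max(self.query_length, self.end - self.start)
        return 1.0 - self.distance / span if span else 0.0


def _merge_locations(locations: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Collapse equivalent optimal locations of a single occurrence."""
    merged: list[list[int]] = []
    for start, end in sorted(locations):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def find_infix_hits(query: str, target: str, max_dist: int,
                    max_rounds: int = 2000) -> list[InfixHit]:
    """All non-overlapping infix occurrences of ``query`` in ``target``.

    edlib reports only the optimal locations per call, so hits are
    harvested iteratively: record the optimal hits, mask them out, and
    realign until the best remaining distance exceeds ``max_dist``.
    """
    if not query or not target or max_dist < 0:
        return []
    hits: list[InfixHit] = []
    masked = bytearray(target.encode())
    qlen = len(query)
    for _ in range(max_rounds):
        res = edlib.align(query, bytes(masked).decode("latin-1"),
                          mode="HW", task="locations", k=max_dist)
        if res["editDistance"] < 0:
            break
        dist = res["editDistance"]
        for start, end in _merge_locations([(s, e + 1) for s, e in res["locations"]]):
            # A merged span can cover several shift-equivalent optima of
            # one occurrence; keep a window of query length at its centre.
            if end - start > qlen + dist:
                mid = (start + end) // 2
                start = max(0, mid - (qlen + dist) // 2)
                end = min(len(target), start + qlen + dist)
            hits.append(InfixHit(start, end, dist, qlen))
            masked[start:end] = b"#" * (end - start)
    hits.sort(key=lambda h: h.start)
    return hits
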