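"""Microsatellite (SSR) scanning.

Detects maximal perfect runs of 1-6 bp motifs across a scaffold, merges
nearby runs into compound domains, and flags "targeting" satellites —
the (TA)n-type domains that delimit satellite-targeted transposable
elements (>= 12 bp of an AT-motif run by default).

Coordinates are 0-based half-open throughout; motifs are reported in a
strand- and phase-independent canonical form, so a (TA)n tract and its
reverse complement are both reported under motif "AT".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_ACGT = frozenset("ACGT")

DEFAULT_MIN_UNITS = {1: 10, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}


class InvalidMotifError(ValueError):
    """Motif contains characters outside A/C/G/T or has bad length."""


def canonical_motif(motif: str) -> str:
    """Canonical form of a repeat unit: the lexicographically smallest
    string among all rotations of the motif and of its reverse
    complement. Idempotent; (TA)n == (AT)n on either strand.
    """
    motif = motif.upper()
    if not 1 <= len(motif) <= 6:
        raise InvalidMotifError(f"motif length must be 1-6, got {motif!r}")
    if not set(motif) <= _ACGT:
        raise InvalidMotifError(f"non-ACGT character in motif {motif!r}")
    from .align import revcomp

    candidates = []
    for unit in (motif, revcomp(motif)):
        doubled = unit + unit
        candidates.extend(doubled[i:i + len(unit)] for i in range(len(unit)))
    return min(candidates)


def _minimal_period(unit: str) -> int:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return p
    return len(unit)


@dataclass(frozen=True)
class SSRDomain:
    """A maximal simple-sequence-repeat interval.

    ``motif`` is the canonical unit of the (dominant) repeat; compound
    domains produced by :func:`merge_adjacent` additionally carry the
    full set of component motifs in ``motifs``.
    """

    scaffold_id: str
    start: int
    end: int
    motif: str
    unit_count: int
    purity: float = 1.0
    compound: bool = False
    motifs: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.motifs:
            object.__setattr__(self, "motifs", (self.motif,))

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SSRThresholds:
    """Scan configuration.

    min_units_by_motif_length
        Minimum number of complete units per motif length; the
        dinucleotide default of 6 units makes a 12 bp (TA)6 tract the
        smallest reportable targeting satellite.
    max_interrupt
        Maximum gap (bp) bridged when merging adjacent domains into a
        compound domain.
    targeting_motifs / targeting_min_len
        Which canonical motifs, at which minimum tract length, count as
        element-delimiting "targeting" satellites.
    """

    min_units_by_motif_length: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_UNITS))
    max_interrupt: int = 3
    targeting_motifs: frozenset[str] = frozenset({"AT"})
    targeting_min_len: int = 12


def find_ssrs(sequence: str, thresholds: SSRThresholds | None = None,
              scaffold_id: str = "") -> list[SSRDomain]:
    """All maximal perfect SSR runs meeting the unit thresholds.

    Runs are broken by N (or any non-ACGT character). A run whose unit
    is itself periodic (e.g. poly-A seen as "AA") is reported only
    under its shortest motif. Output is sorted by start coordinate.
    """
    thresholds = thresholds or SSRThresholds()
    seq = sequence.upper()
    n = len(seq)
    if n == 0:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = ((arr == ord("A")) | (arr == ord("C")) |
             (arr == ord("G")) | (arr == ord("T")))
    domains: list[SSRDomain] = []
    for m, min_units in thresholds.min_units_by_motif_length.items():
        min_len = m * min_units
        if n < min_len:
            continue
        eq = (arr[m:] == arr[:-m]) & valid[m:] & valid[:-m]
        # Maximal True runs in eq: eq[k] means seq[k+m] == seq[k].
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for a, b in zip(starts, ends):
            total = (b - a) + m
            units = total // m
            if units < min_units:
                continue
            unit = seq[a:a + m]
            if _minimal_period(unit) < m:
                continue  # reportable under a shorter motif
            if not valid[a:a + m].all():
                continue
            domains.append(SSRDomain(scaffold_id, int(a), int(a + units * m),
                                     canonical_motif(unit), int(units)))
    domains.sort(key=lambda d: (d.start, d.end, d.motif))
    return domains


def merge_adjacent(ssrs: list[SSRDomain], sequence: str,
                   max_interrupt: int = 3) -> list[SSRDomain]:
    """Merge domains separated by <= max_interrupt bp into compound
    domains (same- or mixed-motif), recomputing purity as the fraction
    of the merged span covered by the component perfect runs.

    Input must be sorted and non-overlapping; a single left-to-right
    pass reaches the fixed point, so the result is order-independent.
    """
    if not ssrs:
        return []
    merged: list[SSRDomain] = []
    # (domain, matched_bp) accumulator
    cur = ssrs[0]
    cur_matched = round(cur.purity * cur.length)
    for nxt in ssrs[1:]:
        gap = nxt.start - cur.end
        if 0 <= gap <= max_interrupt:
            nxt_matched = round(nxt.purity * nxt.length)
            motifs = tuple(dict.fromkeys(cur.motifs + nxt.motifs))
            span = nxt.end - cur.start
            cur_matched += nxt_matched
            # dominant motif = motif of the longer component chain
            motif = cur.motif if cur.length >= nxt.length else nxt.motif
            cur = SSRDomain(cur.scaffold_id, cur.start, nxt.end, motif,
                            cur.unit_count + nxt.unit_count,
                            purity=cur_matched / span, compound=True,
                            motifs=motifs)
        else:
            merged.append(cur)
            cur = nxt
            cur_matched = round(nxt.purity * nxt.length)
    merged.append(cur)
    return merged


def is_targeting(ssr: SSRDomain, thresholds: SSRThresholds | None = None) -> bool:
    """True iff the domain can delimit a satellite-targeted element:
    any component motif is a targeting motif and the tract is long
    enough (>= 12 bp for the AT default)."""
    thresholds = thresholds or SSRThresholds()
    return (ssr.length >= thresholds.targeting_min_len and
            any(m in thresholds.targeting_motifs for m in ssr.motifs))


def targeting_domains(ssrs: list[SSRDomain],
                      thresholds: SSRThresholds | None = None) -> list[SSRDomain]:
    """Consecutive, non-overlapping targeting satellites in coordinate
    order (overlap resolved by keeping the earlier domain)."""
    thresholds = thresholds or SSRThresholds()
    out: list[SSRDomain] = []
    for d in ssrs:
        if not is_targeting(d, thresholds):
            continue
        if out and d.start < out[-1].end:
            continue
        out.append(d)
    return out
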