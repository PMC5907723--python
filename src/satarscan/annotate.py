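"""Element annotation: TIRs, flank architecture, family summaries.

Satellite-targeted elements are class II (DNA) transposons: they carry
imperfect terminal inverted repeats, and copies inserted into complex
sequence by cut-and-paste transposition are flanked by 8-11 bp target
site duplications, whereas microsatellite-targeted copies sit directly
between satellite tracts with no TSD. This module calls both features
and aggregates them into per-family summaries mirroring the standard
"flanked microsatellite / flanked TSD / linked-fused" table layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import revcomp
from .families import ElementOccurrence, Family
from .ssr import SSRDomain, SSRThresholds, is_targeting


@dataclass(frozen=True)
class TIRParams:
    min_tir_len: int = 15
    min_tir_identity: float = 0.75
    max_terminus_offset: int = 3
    max_window: int = 300


@dataclass(frozen=True)
class TIRReport:
    present: bool
    length: int = 0
    identity: float = 0.0
    left_offset: int = 0
    right_offset: int = 0
    too_short: bool = False


@dataclass(frozen=True)
class FlankParams:
    satellite_max_gap: int = 2
    tsd_min: int = 8
    tsd_max: int = 11
    tsd_max_mismatch: int = 0
    flank_window: int = 50
    #: element edges from consensus probing are uncertain by a base or
    #: two; the TSD search slides outward by up to this much per side
    edge_slack: int = 2


@dataclass(frozen=True)
class FlankClassification:
    category: str  # microsatellite | tsd | neither | unresolved
    tsd_len: int | None = None
    tsd_seq: str | None = None
    left_satellite: SSRDomain | None = None
    right_satellite: SSRDomain | None = None


@dataclass(frozen=True)
class FamilySummary:
    family_id: str
    n_total: int
    size_bp: int
    tir_len: int
    pct_microsatellite: float
    pct_tsd: float
    pct_neither: float
    pct_unresolved: float
    pct_linked_or_fused: float
    pct_at_scaffold_ends: float


_NEG = -1e9
_TIR_MATCH, _TIR_MISMATCH, _TIR_GAP = 1.0, -1.0, -2.0


def _anchored_prefix_dp(a: str, b: str, max_offset: int):
    """DP for alignments starting within max_offset of the start of
    both sequences and ending anywhere (linear gaps). Returns the score
    matrix."""
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    h = np.full((n + 1, m + 1), _NEG)
    h[0, :max_offset + 1] = 0.0
    h[:max_offset + 1, 0] = 0.0
    jj = np.arange(m + 1) * (-_TIR_GAP)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], _TIR_MATCH, _TIR_MISMATCH)
        row = np.maximum(h[i - 1, :-1] + sub, h[i - 1, 1:] + _TIR_GAP)
        row = np.concatenate(([h[i, 0]], row))
        # propagate gaps along the row: h[j] = max(row[j], h[j-1]+gap)
        h[i] = np.maximum.accumulate(row + jj) - jj
    return h


def detect_tir(element: str, params: TIRParams | None = None) -> TIRReport:
    """Terminal-inverted-repeat call for one element sequence.

    The first W bp are aligned against the reverse complement of the
    last W bp (W = min(max_window, len/2)) with a dynamic program
    anchored within max_terminus_offset of both termini and free to end
    anywhere inside the windows (match +1, mismatch -1, gap -2). A TIR
    is reported when the best such alignment spans >= min_tir_len at
    >= min_tir_identity. Ties are broken toward the longer alignment,
    then the smaller left offset. The call is strand-invariant.
    """
    params = params or TIRParams()
    element = element.upper()
    if len(element) < 2 * params.min_tir_len:
        return TIRReport(False, too_short=True)
    w = min(params.max_window, len(element) // 2)
    head = element[:w]
    tail_rc = revcomp(element[-w:])
    h = _anchored_prefix_dp(head, tail_rc, params.max_terminus_offset)
    best = h.max()
    if best <= 0:
        return TIRReport(False)
    # equal-scoring end cells can trade length against identity; take
    # the longest qualifying alignment (then the smaller left offset)
    cells = sorted(np.argwhere(h == best),
                   key=lambda c: (-(c[0] + c[1]), c[0]))
    for end_i, end_j in ((int(i), int(j)) for i, j in cells):
        i, j = end_i, end_j
        matches = columns = 0
        while i > 0 and j > 0:
            s = (_TIR_MATCH if head[i - 1] == tail_rc[j - 1]
                 else _TIR_MISMATCH)
            if h[i, j] == h[i - 1, j - 1] + s:
                matches += head[i - 1] == tail_rc[j - 1]
                columns += 1
                i, j = i - 1, j - 1
            elif h[i, j] == h[i - 1, j] + _TIR_GAP:
                columns += 1
                i -= 1
            elif h[i, j] == h[i, j - 1] + _TIR_GAP:
                columns += 1
                j -= 1
            else:  # free anchored start cell
                break
        left_offset, right_offset = i, j
        identity = matches / columns if columns else 0.0
        length = max(end_i - left_offset, end_j - right_offset)
        if (length >= params.min_tir_len and
                identity >= params.min_tir_identity and
                left_offset <= params.max_terminus_offset and
                right_offset <= params.max_terminus_offset):
            return TIRReport(True, length, identity, left_offset,
                             right_offset)
    return TIRReport(False)


def _adjacent_satellite(ssrs: list[SSRDomain], pos: int, side: str,
                        max_gap: int, thresholds: SSRThresholds) -> SSRDomain | None:
    """Targeting satellite abutting ``pos`` on the given side, allowing
    a gap or overlap of up to max_gap bp."""
    for d in ssrs:
        if not is_targeting(d, thresholds):
            continue
        if side == "left" and d.start < pos and abs(pos - d.end) <= max_gap:
            return d
        if side == "right" and d.end > pos and abs(d.start - pos) <= max_gap:
            return d
    return None


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def classify_flanks(occurrence: ElementOccurrence, sequence: str,
                    ssrs: list[SSRDomain],
                    params: FlankParams | None = None,
                    thresholds: SSRThresholds | None = None) -> FlankClassification:
    """Flank architecture of one element copy.

    Precedence: a flank truncated by a scaffold end (or N-gap) makes
    the call unresolved; targeting satellites abutting both termini
    make it microsatellite; otherwise an exact 8-11 bp direct repeat of
    the immediate flanks (longest first) makes it tsd — but never when
    a satellite abuts either terminus, which would let a (TA)n tract
    masquerade as its own duplication; anything else is neither.
    """
    params = params or FlankParams()
    thresholds = thresholds or SSRThresholds()
    seq = sequence.upper()
    start, end = occurrence.start, occurrence.end
    left_window = seq[max(0, start - params.flank_window):start]
    right_window = seq[end:end + params.flank_window]
    if (start < params.flank_window or len(seq) - end < params.flank_window
            or "N" in left_window or "N" in right_window):
        return FlankClassification("unresolved")
    left_sat = _adjacent_satellite(ssrs, start, "left",
                                   params.satellite_max_gap, thresholds)
    right_sat = _adjacent_satellite(ssrs, end, "right",
                                    params.satellite_max_gap, thresholds)
    if left_sat is not None and right_sat is not None:
        return FlankClassification("microsatellite", left_satellite=left_sat,
                                   right_satellite=right_sat)
    if left_sat is None and right_sat is None:
        for tsd_len in range(params.tsd_max, params.tsd_min - 1, -1):
            for dl in range(params.edge_slack + 1):
                for dr in range(params.edge_slack + 1):
                    left = seq[start - dl - tsd_len:start - dl]
                    right = seq[end + dr:end + dr + tsd_len]
                    if len(left) == tsd_len and len(right) == tsd_len and \
                            _mismatches(left, right) <= params.tsd_max_mismatch:
                        return FlankClassification("tsd", tsd_len=tsd_len,
                                                   tsd_seq=left)
    return FlankClassification("neither",
                               left_satellite=left_sat,
                               right_satellite=right_sat)


def summarize_family(family: Family, occurrences: list[ElementOccurrence],
                     arrays: list | None = None) -> FamilySummary:
    """Per-family summary percentages.

    Percentages are over all full occurrences of the family; unresolved
    copies count in the total but in no architecture category, so
    microsatellite + tsd + neither + unresolved = 100 up to rounding.
    linked_or_fused is the share of copies sitting in a multi-element
    array or carrying a fusion truncation.
    """
    mine = [o for o in occurrences if o.family_id == family.family_id]
    if not mine:
        raise ValueError(f"no occurrences for family {family.family_id}")
    n = len(mine)
    cats = {"microsatellite": 0, "tsd": 0, "neither": 0, "unresolved": 0}
    for occ in mine:
        category = occ.flank.category if occ.flank is not None else "unresolved"
        cats[category] += 1
    linked = 0
    if arrays:
        in_multi = set()
        fused_ids = set()
        for arr in arrays:
            members = getattr(arr, "members", [])
            if len(members) >= 2:
                in_multi.update(id(m) for m in members)
            for fusion in getattr(arr, "fusions", []):
                fused_ids.add(id(fusion.left_occurrence))
                fused_ids.add(id(fusion.right_occurrence))
        linked = sum(1 for o in mine if id(o) in in_multi or id(o) in fused_ids)
    at_ends = sum(1 for o in mine if o.at_scaffold_end)
    pct = lambda x: 100.0 * x / n
    return FamilySummary(family.family_id, n, family.size_bp,
                         family.tir.length if family.tir and family.tir.present else 0,
                         pct(cats["microsatellite"]), pct(cats["tsd"]),
                         pct(cats["neither"]), pct(cats["unresolved"]),
                         pct(linked), pct(at_ends))
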