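"""Cross-assembly insertion-site classification.

For each element occurrence in assembly A, unique flanking anchors are
lifted over to a related assembly B by alignment; the inter-anchor
region in B is then classified as still carrying the element
(occupied), carrying only a satellite tract — the hallmark of an
insertion-site polymorphism at a microsatellite target (empty_satellite)
— carrying neither (absent), or unresolvable because an anchor is
unplaced, ambiguous or discordant. Calls are symmetric site states: no
attempt is made to decide whether a difference is an insertion in A or
an excision/deletion in B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib

from .align import revcomp
from .families import ElementOccurrence, Family
from .ssr import SSRDomain, SSRThresholds, find_ssrs, is_targeting, merge_adjacent


class UnresolvedAnchorError(ValueError):
    """No usable flank exists on one side of the occurrence."""


@dataclass(frozen=True)
class AnchorParams:
    anchor_len: int = 500
    satellite_max_gap: int = 2


@dataclass(frozen=True)
class SiteParams:
    anchor_min_identity: float = 0.90
    max_inter_anchor: int = 20000
    ambiguity_frac: float = 0.05  # 2nd placement within 5% of best => ambiguous
    min_satellite_cover: float = 0.80
    probe_min_identity: float = 0.80


@dataclass(frozen=True)
class FlankAnchors:
    occurrence: ElementOccurrence
    left_anchor: str
    right_anchor: str
    left_start: int  # coordinates in assembly A
    left_end: int
    right_start: int
    right_end: int
    left_clipped: bool = False
    right_clipped: bool = False


@dataclass(frozen=True)
class SiteCall:
    occurrence: ElementOccurrence
    status: str  # occupied | empty_satellite | absent | unresolved
    scaffold_B: str | None = None
    start_B: int | None = None
    end_B: int | None = None
    inter_anchor_content: str | None = None  # element|satellite_only|other|gap
    satellite_len_B: int | None = None


def anchor_flanks(occurrence: ElementOccurrence, sequence: str,
                  ssrs: list[SSRDomain],
                  params: AnchorParams | None = None,
                  thresholds: SSRThresholds | None = None,
                  occurrences: list[ElementOccurrence] | None = None) -> FlankAnchors:
    """Anchors immediately outside the occurrence's flanking satellite
    domains (or outside its TSD copies for TSD-flanked insertions).

    Chains of satellites separated by small gaps are skipped entirely;
    when the other element occurrences on the scaffold are supplied,
    the walk also crosses abutting array neighbours, so an array
    member's anchors land in unique flanking sequence rather than in
    repeat copies that would be multiply-placed in the other assembly.
    Anchors shorter than anchor_len because of a scaffold end are
    flagged clipped. A zero-length flank raises UnresolvedAnchorError.
    """
    params = params or AnchorParams()
    thresholds = thresholds or SSRThresholds()
    seq = sequence.upper()
    left_edge, right_edge = occurrence.start, occurrence.end
    flank = occurrence.flank
    if flank is not None and flank.category == "tsd" and flank.tsd_len:
        left_edge -= flank.tsd_len
        right_edge += flank.tsd_len
    skippable = [(d.start, d.end) for d in ssrs
                 if is_targeting(d, thresholds)]
    if occurrences is not None:
        skippable += [(o.start, o.end) for o in occurrences
                      if o.scaffold_id == occurrence.scaffold_id]
    moved = True
    while moved:
        moved = False
        for start, end in skippable:
            if start < left_edge and \
                    left_edge - end <= params.satellite_max_gap:
                left_edge = start
                moved = True
            if end > right_edge and \
                    start - right_edge <= params.satellite_max_gap:
                right_edge = end
                moved = True
    left_start = max(0, left_edge - params.anchor_len)
    right_end = min(len(seq), right_edge + params.anchor_len)
    left_anchor = seq[left_start:left_edge]
    right_anchor = seq[right_edge:right_end]
    if not left_anchor or not right_anchor:
        raise UnresolvedAnchorError(
            f"occurrence at {occurrence.scaffold_id}:{occurrence.start} has "
            "no flanking sequence on one side")
    return FlankAnchors(occurrence, left_anchor, right_anchor,
                        left_start, left_edge, right_edge, right_end,
                        left_clipped=len(left_anchor) < params.anchor_len,
                        right_clipped=len(right_anchor) < params.anchor_len)


def _place_anchor(anchor: str, assembly: dict[str, str],
                  params: SiteParams) -> tuple[str, int, int, str] | None:
    """Unique best placement of an anchor in an assembly, or None when
    unplaced or ambiguous (second placement within ambiguity_frac of
    the best)."""
    k = int(math.floor((1 - params.anchor_min_identity) * len(anchor)))
    best = None  # (dist, scaffold, start, end, strand)
    second_dist = None
    for scaffold_id in sorted(assembly):
        seq = assembly[scaffold_id].upper()
        for strand in "+-":
            query = anchor if strand == "+" else revcomp(anchor)
            res = edlib.align(query, seq, mode="HW", task="locations", k=k)
            if res["editDistance"] < 0:
                continue
            dist = res["editDistance"]
            locs = sorted({(s, e + 1) for s, e in res["locations"]})
            # collapse shift-equivalent optima of one placement
            placements = []
            for s, e in locs:
                if placements and s <= placements[-1][1]:
                    placements[-1] = (placements[-1][0], max(placements[-1][1], e))
                else:
                    placements.append((s, e))
            for s, e in placements:
                if best is None or dist < best[0]:
                    if best is not None and (best[1], best[4]) != (scaffold_id, strand):
                        second_dist = best[0]
                    elif best is not None and abs(best[2] - s) > len(anchor):
                        second_dist = best[0]
                    best = (dist, scaffold_id, s, e, strand)
                elif abs(s - best[2]) > len(anchor) or \
                        (scaffold_id, strand) != (best[1], best[4]):
                    second_dist = dist if second_dist is None else min(second_dist, dist)
    if best is None:
        return None
    if second_dist is not None and \
            second_dist - best[0] <= params.ambiguity_frac * len(anchor):
        return None
    return (best[1], best[2], best[3], best[4])


def classify_site(anchors: FlankAnchors, assembly_B: dict[str, str],
                  family: Family,
                  params: SiteParams | None = None,
                  thresholds: SSRThresholds | None = None) -> SiteCall:
    """Classify one insertion site of assembly A in assembly B.

    Both anchors are placed in B by alignment; when they land
    collinearly on one scaffold within max_inter_anchor, the
    inter-anchor region decides the call: a consensus match at probe
    thresholds means occupied; a satellite-dominated region with no
    consensus match means empty_satellite; otherwise absent.
    """
    params = params or SiteParams()
    thresholds = thresholds or SSRThresholds()
    left = _place_anchor(anchors.left_anchor, assembly_B, params)
    right = _place_anchor(anchors.right_anchor, assembly_B, params)
    occ = anchors.occurrence
    if left is None or right is None:
        return SiteCall(occ, "unresolved")
    (l_scaf, l_start, l_end, l_strand) = left
    (r_scaf, r_start, r_end, r_strand) = right
    if l_scaf != r_scaf or l_strand != r_strand:
        return SiteCall(occ, "unresolved")
    if l_strand == "+":
        inner_start, inner_end = l_end, r_start
    else:
        inner_start, inner_end = r_end, l_start
    if inner_end < inner_start or inner_end - inner_start > params.max_inter_anchor:
        return SiteCall(occ, "unresolved")
    region = assembly_B[l_scaf].upper()[inner_start:inner_end]
    if region and region.count("N") / len(region) > 0.5:
        return SiteCall(occ, "unresolved", l_scaf, inner_start, inner_end,
                        inter_anchor_content="gap")
    # element present?
    cons = family.consensus
    k = int(math.floor((1 - params.probe_min_identity) * len(cons)))
    present = False
    if len(region) >= 0.5 * len(cons):
        for query in (cons, revcomp(cons)):
            res = edlib.align(query, region, mode="HW", task="distance", k=k)
            if res["editDistance"] >= 0:
                present = True
                break
    if present:
        return SiteCall(occ, "occupied", l_scaf, inner_start, inner_end,
                        inter_anchor_content="element")
    # satellite-only empty site?
    ssrs = merge_adjacent(find_ssrs(region, thresholds), region,
                          thresholds.max_interrupt)
    sat_bp = sum(d.length for d in ssrs)
    if region and sat_bp >= params.min_satellite_cover * len(region):
        return SiteCall(occ, "empty_satellite", l_scaf, inner_start, inner_end,
                        inter_anchor_content="satellite_only",
                        satellite_len_B=sat_bp)
    return SiteCall(occ, "absent", l_scaf, inner_start, inner_end,
                    inter_anchor_content="other")
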