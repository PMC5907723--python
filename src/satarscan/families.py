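"""Repeat family construction and genome probing.

Candidates are clustered greedily around length-sorted centroids, a
majority-vote consensus is built per cluster, and each consensus is
then used to probe the whole assembly on both strands — recovering all
copies of the family, including those inserted into complex sequence
with target-site duplications rather than between satellites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib

from .align import (InfixHit, best_local, find_infix_hits, make_local_aligner,
                    revcomp)
from .discovery import CandidateSegment


@dataclass(frozen=True)
class ClusterParams:
    min_identity: float = 0.80
    min_coverage: float = 0.80
    min_copies: int = 3


@dataclass(frozen=True)
class ProbeParams:
    min_identity: float = 0.80
    min_coverage: float = 0.90
    keep_partial: bool = False
    #: length of consensus chunks used to recover fragmentary copies
    partial_chunk: int = 100


@dataclass
class Family:
    family_id: str
    consensus: str
    n_members_discovery: int
    members: list[CandidateSegment] = field(default_factory=list)
    tir: "object | None" = None  # TIRReport, filled by the annotator

    @property
    def size_bp(self) -> int:
        return len(self.consensus)


@dataclass
class ElementOccurrence:
    """One genomic copy of a family.

    ``cons_start``/``cons_end`` give the consensus interval covered by
    the refined alignment; their distance from the consensus ends is
    the truncation used by fusion detection downstream.
    """

    family_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float
    cons_start: int = 0
    cons_end: int = 0
    flank: "object | None" = None  # FlankClassification
    at_scaffold_end: bool = False
    partial: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def truncation_left(self, consensus_len: int) -> int:
        """Consensus bp missing at the genomic-left end of the copy."""
        return self.cons_start if self.strand == "+" else consensus_len - self.cons_end

    def truncation_right(self, consensus_len: int) -> int:
        return consensus_len - self.cons_end if self.strand == "+" else self.cons_start


def _canonical_orientation(seq: str) -> str:
    """Orientation-normalised form: the lexicographically smaller of a
    sequence and its reverse complement (element orientation is
    arbitrary for TIR-symmetric elements)."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def _matches(a: str, b: str, min_identity: float,
             min_coverage: float = 0.80) -> bool:
    """Cluster membership test: the shorter of a/b must match an infix
    of the longer at the identity threshold on either strand, and the
    two lengths must be within the coverage ratio of each other.

    The mutual-coverage requirement keeps chimeric segments (e.g. a
    fused element pair picked up as one inter-satellite candidate) from
    becoming centroids that absorb their component families.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if len(short) < min_coverage * len(long_):
        return False
    k = int(math.floor((1 - min_identity) * len(short)))
    for query in (short, revcomp(short)):
        res = edlib.align(query, long_, mode="HW", task="distance", k=k)
        if res["editDistance"] >= 0:
            return True
    return False


def cluster_candidates(candidates: list[CandidateSegment],
                       params: ClusterParams | None = None) -> list[Family]:
    """Greedy centroid clustering.

    Candidates are visited in order of decreasing length (ties broken
    by coordinates, so the outcome is deterministic); each joins the
    first centroid it matches at >= min_identity over the shorter
    sequence on either strand, else founds a new centroid. Clusters
    with fewer than min_copies members are discarded.
    """
    params = params or ClusterParams()
    ordered = sorted(candidates,
                     key=lambda c: (-c.length, c.scaffold_id, c.start))
    centroids: list[CandidateSegment] = []
    clusters: list[list[CandidateSegment]] = []
    for cand in ordered:
        for i, centroid in enumerate(centroids):
            if _matches(cand.sequence, centroid.sequence, params.min_identity,
                        params.min_coverage):
                clusters[i].append(cand)
                break
        else:
            centroids.append(cand)
            clusters.append([cand])
    families = []
    kept = [(c, m) for c, m in zip(centroids, clusters)
            if len(m) >= params.min_copies]
    kept.sort(key=lambda cm: (-len(cm[1]), -cm[0].length, cm[0].scaffold_id,
                              cm[0].start))
    for idx, (centroid, members) in enumerate(kept, start=1):
        consensus = build_consensus([m.sequence for m in members],
                                    centroid.sequence)
        consensus = _canonical_orientation(consensus)
        families.append(Family(f"fam{idx:02d}", consensus, len(members),
                               members=members))
    return families


def build_consensus(member_sequences: list[str], centroid: str) -> str:
    """Star-alignment consensus.

    Every member is aligned to the centroid; votes are tallied per
    centroid column (a deletion in a member votes "gap"). Columns
    gapped in more than half the members are dropped; ties go to the
    centroid base. Member insertions relative to the centroid are not
    added to the consensus.
    """
    if not member_sequences:
        raise ValueError("need at least one member")
    aligner = make_local_aligner()
    n_cols = len(centroid)
    votes: list[dict[str, int]] = [dict() for _ in range(n_cols)]
    for member in member_sequences:
        oriented = member
        hit = best_local(centroid, oriented, aligner)
        hit_rc = best_local(centroid, revcomp(member), aligner)
        if hit_rc is not None and (hit is None or hit_rc.score > hit.score):
            hit, oriented = hit_rc, revcomp(member)
        if hit is None:
            continue
        alignment = aligner.align(centroid, oriented)[0]
        covered = set()
        for (a_blk, b_blk) in zip(alignment.aligned[0], alignment.aligned[1]):
            for offset in range(a_blk[1] - a_blk[0]):
                col = a_blk[0] + offset
                base = oriented[b_blk[0] + offset]
                votes[col][base] = votes[col].get(base, 0) + 1
                covered.add(col)
        lo = alignment.aligned[0][0][0]
        hi = alignment.aligned[0][-1][1]
        for col in range(lo, hi):
            if col not in covered:  # centroid column deleted in member
                votes[col]["-"] = votes[col].get("-", 0) + 1
    out = []
    n_members = len(member_sequences)
    for col, tally in enumerate(votes):
        if not tally:
            out.append(centroid[col])
            continue
        if tally.get("-", 0) * 2 > n_members:
            continue
        best = max(tally.values())
        winners = {b for b, v in tally.items() if v == best and b != "-"}
        if not winners:
            continue
        out.append(centroid[col] if centroid[col] in winners
                   else sorted(winners)[0])
    return "".join(out)


_CIGAR_RE = None


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    global _CIGAR_RE
    if _CIGAR_RE is None:
        import re
        _CIGAR_RE = re.compile(r"(\d+)([=XID])")
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _refine_hit(consensus: str, scaffold_id: str, seq: str, hit: InfixHit,
                strand: str, aligner=None) -> ElementOccurrence | None:
    """Exact bounds / identity / consensus coverage for one raw hit.

    A global (NW) alignment of the oriented consensus against the hit
    slice keeps terminal mismatches inside the occurrence — a local
    realignment would trim them and shift the element edge off its
    flanking satellite or TSD. Leading/trailing target gaps tighten
    the genomic bounds; leading/trailing query gaps are truncation.
    """
    query = consensus if strand == "+" else revcomp(consensus)
    target = seq[hit.start:hit.end]
    res = edlib.align(query, target, mode="NW", task="path")
    if res["editDistance"] < 0 or not res["cigar"]:
        return None
    ops = _parse_cigar(res["cigar"])
    g_start, g_end = hit.start, hit.end
    q_lo, q_hi = 0, len(query)
    while ops:
        n, op = ops[0]
        if op == "D":
            g_start += n
        elif op == "I":
            q_lo += n
        else:
            break
        ops.pop(0)
    while ops:
        n, op = ops[-1]
        if op == "D":
            g_end -= n
        elif op == "I":
            q_hi -= n
        else:
            break
        ops.pop()
    if not ops:
        return None
    matches = sum(n for n, op in ops if op == "=")
    columns = sum(n for n, op in ops)
    cons_lo, cons_hi = q_lo, q_hi
    if strand == "-":
        cons_lo, cons_hi = len(consensus) - q_hi, len(consensus) - q_lo
    coverage = (q_hi - q_lo) / len(consensus)
    return ElementOccurrence("", scaffold_id, g_start, g_end, strand,
                             matches / columns if columns else 0.0,
                             coverage, cons_lo, cons_hi)


def _chain_partials(chunk_hits, consensus_len, chunk, scaffold_id, strand,
                    family_id) -> list[ElementOccurrence]:
    """Chain collinear chunk hits into partial occurrences carrying an
    approximate consensus interval."""
    chunk_hits.sort(key=lambda t: t[1].start)  # (chunk_index, hit)
    partials: list[ElementOccurrence] = []
    open_chain: list[tuple[int, InfixHit]] = []

    def flush():
        if not open_chain:
            return
        g_start = open_chain[0][1].start
        g_end = open_chain[-1][1].end
        idxs = [i for i, _ in open_chain]
        c_lo = min(idxs) * chunk
        c_hi = min(consensus_len, (max(idxs) + 1) * chunk)
        if strand == "-":
            c_lo, c_hi = consensus_len - c_hi, consensus_len - c_lo
        cov = (c_hi - c_lo) / consensus_len
        partials.append(ElementOccurrence(family_id, scaffold_id, g_start,
                                          g_end, strand, 1.0, cov,
                                          c_lo, c_hi, partial=True))
        open_chain.clear()

    for idx, hit in chunk_hits:
        if open_chain:
            prev_idx, prev_hit = open_chain[-1]
            gap_g = hit.start - prev_hit.end
            step = (idx - prev_idx) if strand == "+" else (prev_idx - idx)
            expected = (step - 1) * chunk
            if step >= 1 and abs(gap_g - expected) <= 30 and gap_g > -15:
                open_chain.append((idx, hit))
                continue
            flush()
        open_chain.append((idx, hit))
    flush()
    return partials


def probe_genome(family: Family, assembly: dict[str, str],
                 params: ProbeParams | None = None) -> list[ElementOccurrence]:
    """Locate every copy of a family consensus in an assembly.

    Both strands of every scaffold are searched with the full consensus
    (edlib infix alignment, iteratively masked); hits are refined with
    a local affine-gap alignment to obtain exact bounds, identity and
    coverage. Overlapping same-family hits keep the highest identity.
    With ``keep_partial`` the consensus is additionally probed in
    chunks and collinear chunk hits are chained into partial
    occurrences (fragments, fusion stubs, split nesting hosts).
    """
    params = params or ProbeParams()
    consensus = family.consensus
    k_full = int(math.floor((1 - params.min_identity) * len(consensus) * 1.2))
    aligner = make_local_aligner()
    occurrences: list[ElementOccurrence] = []
    partials: list[ElementOccurrence] = []
    for scaffold_id in sorted(assembly):
        seq = assembly[scaffold_id].upper()
        raw: list[ElementOccurrence] = []
        for strand in "+-":
            query = consensus if strand == "+" else revcomp(consensus)
            for hit in find_infix_hits(query, seq, k_full):
                occ = _refine_hit(consensus, scaffold_id, seq, hit, strand,
                                  aligner)
                if occ is not None:
                    raw.append(occ)
        # overlap resolution: greedy by identity; a modest overlap is
        # tolerated so both halves of a same-family fusion survive
        raw.sort(key=lambda o: (-o.identity, o.start))
        chosen: list[ElementOccurrence] = []
        for occ in raw:
            conflict = any(
                min(occ.end, c.end) - max(occ.start, c.start) >
                0.5 * min(occ.length, c.length) for c in chosen)
            if conflict:
                continue
            chosen.append(occ)
        for occ in sorted(chosen, key=lambda o: o.start):
            occ.family_id = family.family_id
            occ.at_scaffold_end = occ.start == 0 or occ.end == len(seq)
            if occ.coverage >= params.min_coverage and \
                    occ.identity >= params.min_identity:
                occurrences.append(occ)
            elif params.keep_partial:
                occ.partial = True
                partials.append(occ)
        if params.keep_partial:
            partials.extend(_probe_partials(family, scaffold_id, seq,
                                            occurrences, params))
    occurrences.sort(key=lambda o: (o.scaffold_id, o.start))
    if params.keep_partial:
        return occurrences, partials
    return occurrences


def _probe_partials(family: Family, scaffold_id: str, seq: str,
                    full_occurrences: list[ElementOccurrence],
                    params: ProbeParams) -> list[ElementOccurrence]:
    consensus = family.consensus
    chunk = params.partial_chunk
    if len(consensus) < 2 * chunk:
        return []
    full_spans = [(o.start, o.end) for o in full_occurrences
                  if o.scaffold_id == scaffold_id]
    out: list[ElementOccurrence] = []
    for strand in "+-":
        query_full = consensus if strand == "+" else revcomp(consensus)
        chunk_hits = []
        n_chunks = len(consensus) // chunk
        for j in range(n_chunks):
            piece = query_full[j * chunk:(j + 1) * chunk]
            idx = j if strand == "+" else n_chunks - 1 - j
            k = int(math.floor((1 - params.min_identity) * chunk))
            for hit in find_infix_hits(piece, seq, k):
                if any(hit.start >= s - 5 and hit.end <= e + 5
                       for s, e in full_spans):
                    continue  # inside an already-called full copy
                chunk_hits.append((idx, hit))
        out.extend(_chain_partials(chunk_hits, len(consensus), chunk,
                                   scaffold_id, strand, family.family_id))
    return out
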