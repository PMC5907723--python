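"""Linked-array construction, modularity testing and fusion calling.

Microsatellite-targeted elements accumulate as tandem, mixed-family
arrays in which intact elements are joined end-to-end by satellite
linkers. Two departures from the plain linked architecture are called
here: fusions, where the linker plus the facing element termini have
been deleted so two truncated elements abut directly, and nesting,
where one element has inserted inside another (never observed for
satellite-targeted elements, hence the "modular" verdict this module
tests). A small helper also computes the random-placement spacing
expectation used to show how non-random the observed clustering is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import best_local, make_local_aligner, revcomp
from .families import ElementOccurrence, Family
from .ssr import SSRDomain


@dataclass(frozen=True)
class ArrayParams:
    max_link_gap: int = 100
    min_linker_satellite_frac: float = 0.5
    max_junction_gap: int = 12
    min_truncation: int = 5
    nesting_abut_tol: int = 20
    min_split_part: int = 30


@dataclass
class FusionEvent:
    left_occurrence: ElementOccurrence
    right_occurrence: ElementOccurrence
    junction: int
    left_truncation: int
    right_truncation: int

    @property
    def left_family(self) -> str:
        return self.left_occurrence.family_id

    @property
    def right_family(self) -> str:
        return self.right_occurrence.family_id


@dataclass
class ElementArray:
    scaffold_id: str
    members: list[ElementOccurrence]
    linkers: list[list[SSRDomain]] = field(default_factory=list)
    modular: bool | None = None
    fusions: list[FusionEvent] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span(self) -> int:
        return self.members[-1].end - self.members[0].start


@dataclass
class NestingEvent:
    host_family: str
    inserted: ElementOccurrence
    left_cons_range: tuple[int, int]
    right_cons_range: tuple[int, int]
    strand: str


@dataclass
class ModularityReport:
    modular: bool
    nesting_events: list[NestingEvent] = field(default_factory=list)


@dataclass(frozen=True)
class SpacingExpectation:
    genome_length: int
    n_elements: int
    k: int

    @property
    def mean_spacing(self) -> float:
        return self.genome_length / self.n_elements

    @property
    def expected_span_k(self) -> float:
        return self.k * self.mean_spacing


def _satellite_cover(ssrs: list[SSRDomain], start: int, end: int) -> int:
    """bp of [start, end) covered by satellite domains (any motif)."""
    covered = 0
    for d in ssrs:
        covered += max(0, min(d.end, end) - max(d.start, start))
    return min(covered, end - start)


def link_elements(occurrences: list[ElementOccurrence],
                  ssrs_by_scaffold: dict[str, list[SSRDomain]],
                  params: ArrayParams | None = None) -> list[ElementArray]:
    """Chain occurrences (all families pooled) into arrays.

    Consecutive occurrences on a scaffold are linked when the gap
    between them is at most max_link_gap and at least
    min_linker_satellite_frac covered by satellite domains, or when the
    gap is small enough (<= max_junction_gap) to be a fusion junction.
    Linking is transitive; isolated occurrences become singletons.
    Every occurrence ends up in exactly one array.
    """
    params = params or ArrayParams()
    arrays: list[ElementArray] = []
    by_scaffold: dict[str, list[ElementOccurrence]] = {}
    for occ in occurrences:
        by_scaffold.setdefault(occ.scaffold_id, []).append(occ)
    for scaffold_id in sorted(by_scaffold):
        occs = sorted(by_scaffold[scaffold_id], key=lambda o: (o.start, o.end))
        ssrs = ssrs_by_scaffold.get(scaffold_id, [])
        current = [occs[0]]
        linkers: list[list[SSRDomain]] = []
        for prev, nxt in zip(occs, occs[1:]):
            gap = nxt.start - prev.end
            gap_sats = [d for d in ssrs
                        if d.start < nxt.start and d.end > prev.end]
            sat_cover = _satellite_cover(gap_sats, prev.end, nxt.start)
            linked = False
            if gap <= params.max_junction_gap:
                linked = True  # direct abutment / fusion junction
            elif gap <= params.max_link_gap and \
                    sat_cover >= params.min_linker_satellite_frac * gap:
                linked = True
            if linked:
                current.append(nxt)
                linkers.append(gap_sats)
            else:
                arrays.append(ElementArray(scaffold_id, current, linkers))
                current, linkers = [nxt], []
        arrays.append(ElementArray(scaffold_id, current, linkers))
    return arrays


def _junction_truncation(occ: ElementOccurrence, family: Family, seq: str,
                         side: str, aligner) -> int:
    """Consensus bp missing on the junction-facing end of a member.

    Probing bounds can bleed across a fusion junction (the missing
    consensus tail aligns into the neighbour more cheaply than as a
    gap), so the truncation is re-measured by a local alignment of the
    member's locus against its consensus, which trims the low-identity
    bleed and exposes the uncovered consensus end.
    """
    cons = family.consensus
    margin = 10
    lo = max(0, occ.start - margin)
    hi = min(len(seq), occ.end + margin)
    query = cons if occ.strand == "+" else revcomp(cons)
    hit = best_local(query, seq[lo:hi], aligner)
    if hit is None:
        return 0
    # query is genomically oriented, so a_start/a_end are genomic sides
    missing_head, missing_tail = hit.a_start, len(cons) - hit.a_end
    return missing_tail if side == "right" else missing_head


def detect_fusions(array: ElementArray, families: dict[str, Family],
                   sequence: str | None = None,
                   params: ArrayParams | None = None) -> list[FusionEvent]:
    """Fusion junctions inside one array.

    Adjacent members abutting within max_junction_gap with no
    satellite in the junction, both truncated by >= min_truncation bp
    of consensus on their junction-facing ends, constitute a fusion
    (deletion of the linker plus the facing element termini). When the
    scaffold sequence is given, truncations are re-measured by local
    realignment; otherwise the stored consensus ranges are used.
    """
    params = params or ArrayParams()
    aligner = make_local_aligner() if sequence is not None else None
    events: list[FusionEvent] = []
    for i, (left, right) in enumerate(zip(array.members, array.members[1:])):
        gap = right.start - left.end
        if gap > params.max_junction_gap:
            continue
        linker = array.linkers[i] if i < len(array.linkers) else []
        if _satellite_cover(linker, left.end, right.start) > 0:
            continue
        lf = families.get(left.family_id)
        rf = families.get(right.family_id)
        if lf is None or rf is None:
            continue
        if sequence is not None:
            lt = _junction_truncation(left, lf, sequence, "right", aligner)
            rt = _junction_truncation(right, rf, sequence, "left", aligner)
        else:
            lt = left.truncation_right(len(lf.consensus))
            rt = right.truncation_left(len(rf.consensus))
        if lt >= params.min_truncation and rt >= params.min_truncation:
            events.append(FusionEvent(left, right, left.end, lt, rt))
    array.fusions = events
    return events


def _split_host_check(occ: ElementOccurrence, seq: str, family: Family,
                      params: ArrayParams, aligner) -> NestingEvent | None:
    """Does ``occ`` sit inside a split copy of ``family``'s consensus?

    Looks for a prefix of the consensus ending at occ.start and a
    suffix starting at occ.end whose consensus coordinates abut (within
    nesting_abut_tol, which also absorbs a duplicated target site).
    """
    cons = family.consensus
    w = len(cons) + 50
    left_region = seq[max(0, occ.start - w):occ.start]
    right_region = seq[occ.end:occ.end + w]
    if len(left_region) < params.min_split_part or \
            len(right_region) < params.min_split_part:
        return None
    for strand in "+-":
        query = cons if strand == "+" else revcomp(cons)
        lh = best_local(query, left_region, aligner)
        rh = best_local(query, right_region, aligner)
        if lh is None or rh is None:
            continue
        # left part must abut the insertion on its genomic-right edge,
        # right part on its genomic-left edge
        if len(left_region) - lh.b_end > params.nesting_abut_tol:
            continue
        if rh.b_start > params.nesting_abut_tol:
            continue
        if lh.a_end - lh.a_start < params.min_split_part or \
                rh.a_end - rh.a_start < params.min_split_part:
            continue
        if lh.identity < 0.75 or rh.identity < 0.75:
            continue
        # split-host signature: the two parts tile the oriented
        # consensus (query coordinates are genomic for both sides, so
        # no strand flip is needed; the abut tolerance also absorbs a
        # duplicated target site at the junction)
        if abs(lh.a_end - rh.a_start) > params.nesting_abut_tol:
            continue
        combined = (lh.a_end - lh.a_start) + (rh.a_end - rh.a_start)
        if combined > len(cons) + params.nesting_abut_tol or \
                combined < 0.6 * len(cons):
            continue
        return NestingEvent(family.family_id, occ,
                            (lh.a_start, lh.a_end), (rh.a_start, rh.a_end),
                            strand)
    return None


def check_modularity(array: ElementArray, assembly: dict[str, str],
                     families: dict[str, Family],
                     partial_hits: list[ElementOccurrence] | None = None,
                     params: ArrayParams | None = None) -> ModularityReport:
    """Test an array for nesting (one element interrupting another).

    For every member, every family consensus is tested for the split-
    host signature: collinear partial matches flanking the member whose
    consensus coordinates abut. Partial hits from probing, when given,
    restrict which member/family pairs are examined (a member with no
    partial hit of a family beside it cannot split that family's
    copy). Arrays with no such signature are modular.
    """
    params = params or ArrayParams()
    aligner = make_local_aligner()
    seq = assembly[array.scaffold_id].upper()
    candidates: list[tuple[ElementOccurrence, Family]] = []
    for occ in array.members:
        for family in families.values():
            if partial_hits is not None:
                near = [p for p in partial_hits
                        if p.scaffold_id == occ.scaffold_id
                        and p.family_id == family.family_id
                        and p.start < occ.start + len(family.consensus) + 50
                        and p.end > occ.end - len(family.consensus) - 50]
                if not near:
                    continue
            candidates.append((occ, family))
    events: list[NestingEvent] = []
    for occ, family in candidates:
        event = _split_host_check(occ, seq, family, params, aligner)
        if event is not None:
            events.append(event)
    report = ModularityReport(modular=not events, nesting_events=events)
    array.modular = report.modular
    return report


def random_expectation(genome_length: int, n_elements: int,
                       k: int = 1) -> SpacingExpectation:
    """Random-placement spacing: mean distance between elements under a
    uniform distribution, and the span k consecutive elements would be
    expected to occupy (k * genome_length / n_elements)."""
    if n_elements <= 0:
        raise ValueError("n_elements must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    return SpacingExpectation(genome_length, n_elements, k)
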