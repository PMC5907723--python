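"""Synthetic assemblies with planted satellite-targeted elements.

The generator emulates a fragmented plant assembly: i.i.d. background
sequence at a configurable GC, TA (or other-motif) microsatellite
tracts, and planted element families carrying imperfect terminal
inverted repeats. Copies are inserted either between freshly generated
targeting satellites (the microsatellite-targeted mode) or into
complex sequence with an 8-11 bp target-site duplication (the
cut-and-paste mode). Multi-family linked arrays, linker-deleting
fusions and (optionally) nested insertions are planted with full
ground-truth records, and a derived second assembly can excise a
fraction of satellite-mode copies back to a satellite-only empty site.

Everything is reproducible from the spec seed; scaffolds are built as
typed piece lists, so truth coordinates always slice to the planted
sequences by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FamilySpec:
    """One planted family.

    Defaults across the module emulate compact non-autonomous elements:
    a few hundred bp, 40-120 bp imperfect TIRs, ~2% divergence between
    copies, and ~70% of copies targeted to satellites (the remainder
    TSD-inserted into complex sequence).
    """

    size_bp: int
    tir_len: int
    n_copies: int = 30
    tir_identity: float = 0.95
    gc: float = 0.45
    copy_mutation_rate: float = 0.02
    indel_rate: float = 0.0
    frac_tsd_inserted: float = 0.30
    tsd_len: int = 10


def default_families() -> list[FamilySpec]:
    """Three families shaped like well-characterised compact elements:
    400 bp / 40 bp TIR, 400 bp / 50 bp TIR, 440 bp / 120 bp TIR."""
    return [FamilySpec(400, 40), FamilySpec(400, 50), FamilySpec(440, 120)]


@dataclass(frozen=True)
class SimulationSpec:
    n_scaffolds: int = 10
    scaffold_length: int = 500_000
    background_gc: float = 0.35
    families: tuple[FamilySpec, ...] = field(
        default_factory=lambda: tuple(default_families()))
    satellite_motif: str = "TA"
    satellite_min_units: int = 6
    satellite_geom_p: float = 0.15  # unit count ~ min + Geometric(p)
    n_arrays: int = 6
    array_sizes: tuple[int, ...] = (2, 3, 4)
    n_fusions: int = 2
    n_nested: int = 0
    excision_fraction: float = 0.20
    make_b: bool = False
    seed: int = 0


@dataclass
class TruthRecord:
    element_id: str
    family_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    insertion_mode: str  # satellite | tsd
    array_id: str | None = None
    fused: bool = False
    nested_in: str | None = None
    split_host: bool = False
    excised_in_B: bool = False
    start_B: int | None = None
    end_B: int | None = None


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _satellite(rng: np.random.Generator, spec: SimulationSpec) -> str:
    units = spec.satellite_min_units + rng.geometric(spec.satellite_geom_p)
    return spec.satellite_motif * int(units)


def _has_targeting_run(seq: str, motif: str = "TA", min_len: int = 12) -> bool:
    from .ssr import SSRThresholds, find_ssrs, is_targeting
    thr = SSRThresholds()
    return any(is_targeting(d, thr) for d in find_ssrs(seq, thr))


def make_family_consensus(rng: np.random.Generator, fam: FamilySpec) -> str:
    """Random family consensus carrying a TIR of the requested length
    and identity, free of internal targeting-satellite runs (which
    would fragment the element at discovery time)."""
    for _ in range(200):
        core = _random_seq(rng, fam.size_bp - fam.tir_len, fam.gc)
        head = core[:fam.tir_len]
        tail = revcomp(head)
        n_mut = int(round((1 - fam.tir_identity) * fam.tir_len))
        if n_mut:
            pos = rng.choice(fam.tir_len, size=n_mut, replace=False)
            tail_list = list(tail)
            for p in pos:
                tail_list[p] = str(rng.choice([b for b in "ACGT"
                                               if b != tail_list[p]]))
            tail = "".join(tail_list)
        seq = head + core[fam.tir_len:] + tail
        # keep element edges distinguishable from the satellite linker
        if not _has_targeting_run(seq) and not seq.startswith("TA") \
                and not seq.endswith("TA") and not seq.startswith("AT") \
                and not seq.endswith("AT"):
            return seq
    raise RuntimeError("could not draw a satellite-free consensus")


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float,
            indel_rate: float = 0.0) -> str:
    out = []
    for ch in seq:
        r = rng.random()
        if indel_rate and r < indel_rate / 2:
            continue  # deletion
        if indel_rate and r < indel_rate:
            out.append(str(rng.choice(list("ACGT"))))  # insertion
        if rng.random() < sub_rate:
            out.append(str(rng.choice([b for b in "ACGT" if b != ch])))
        else:
            out.append(ch)
    return "".join(out)


@dataclass
class _Piece:
    kind: str  # background | satellite | element | tsd
    seq: str
    element_id: str | None = None
    in_b: bool = True


class _ScaffoldBuilder:
    def __init__(self, scaffold_id: str):
        self.scaffold_id = scaffold_id
        self.pieces: list[_Piece] = []

    def add(self, kind: str, seq: str, element_id: str | None = None):
        self.pieces.append(_Piece(kind, seq, element_id))

    def render(self, assembly_b: bool = False):
        """Concatenate pieces; returns (sequence, {element_id: (start, end)})."""
        parts = []
        coords = {}
        pos = 0
        for piece in self.pieces:
            if assembly_b and not piece.in_b:
                continue
            if piece.kind == "element" and piece.element_id:
                coords[piece.element_id] = (pos, pos + len(piece.seq))
            parts.append(piece.seq)
            pos += len(piece.seq)
        return "".join(parts), coords


@dataclass
class SimulationResult:
    assembly_a: dict[str, str]
    assembly_b: dict[str, str] | None
    truth: list[TruthRecord]
    consensi: dict[str, str]


def simulate(spec: SimulationSpec) -> SimulationResult:
    """Build assembly A (and optionally B) plus ground truth.

    Raises ValueError when the planted material cannot be packed into
    the scaffold budget. Byte-identical output for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    consensi = {f"true{fid + 1:02d}": make_family_consensus(rng, fam)
                for fid, fam in enumerate(spec.families)}
    fam_specs = {f"true{fid + 1:02d}": fam
                 for fid, fam in enumerate(spec.families)}

    # --- plan copies -------------------------------------------------
    # per family: n_copies split into tsd-mode and satellite-mode by
    # largest-remainder rounding; array members and nested hosts are
    # drawn from the satellite-mode pool.
    units: list[dict] = []  # planned insertion units
    copy_counter = 0
    sat_pool: list[tuple[str, str]] = []  # (family_id, element_id) satellite singles
    for fam_id, fam in fam_specs.items():
        n_tsd = int(round(fam.frac_tsd_inserted * fam.n_copies))
        n_sat = fam.n_copies - n_tsd
        for _ in range(n_tsd):
            copy_counter += 1
            units.append({"type": "tsd", "family": fam_id,
                          "id": f"e{copy_counter:04d}"})
        for _ in range(n_sat):
            copy_counter += 1
            sat_pool.append((fam_id, f"e{copy_counter:04d}"))

    rng.shuffle(sat_pool)
    array_units = []
    array_counter = 0
    sizes = list(spec.array_sizes)
    for i in range(spec.n_arrays):
        size = sizes[i % len(sizes)]
        if len(sat_pool) < size + 2:
            raise ValueError("not enough satellite-mode copies for arrays")
        members = [sat_pool.pop() for _ in range(size)]
        array_counter += 1
        array_units.append({"type": "array", "members": members,
                            "array_id": f"arr{array_counter:02d}",
                            "fused_junction": None})
    for i in range(spec.n_fusions):
        if i >= len(array_units):
            break
        unit = array_units[i]
        junction = int(rng.integers(0, len(unit["members"]) - 1))
        unit["fused_junction"] = junction
    units.extend(array_units)

    for i in range(spec.n_nested):
        if len(sat_pool) < 2:
            raise ValueError("not enough copies for nested insertions")
        host = sat_pool.pop()
        inner = sat_pool.pop()
        units.append({"type": "nested", "host": host, "inner": inner})
    for fam_id, element_id in sat_pool:
        units.append({"type": "satellite_single", "family": fam_id,
                      "id": element_id})

    rng.shuffle(units)

    # --- place units on scaffolds -----------------------------------
    slot_width = 4000
    slots_per_scaffold = max(1, (spec.scaffold_length - 2000) // slot_width)
    total_slots = spec.n_scaffolds * slots_per_scaffold
    if len(units) > total_slots:
        raise ValueError(
            f"cannot pack {len(units)} insertion units into "
            f"{total_slots} scaffold slots")
    slot_ids = rng.choice(total_slots, size=len(units), replace=False)
    by_scaffold: dict[int, list[tuple[int, dict]]] = {}
    for slot, unit in zip(slot_ids, units):
        by_scaffold.setdefault(int(slot) // slots_per_scaffold, []).append(
            (int(slot) % slots_per_scaffold, unit))

    truth: list[TruthRecord] = []
    builders: list[_ScaffoldBuilder] = []
    for s in range(spec.n_scaffolds):
        scaffold_id = f"scaffold{s + 1:03d}"
        builder = _ScaffoldBuilder(scaffold_id)
        placed = sorted(by_scaffold.get(s, []))
        cursor = 0
        for slot, unit in placed:
            offset = 1000 + slot * slot_width + int(rng.integers(0, 500))
            gap = offset - cursor
            background = _random_seq(rng, gap, spec.background_gc)
            _emit_unit(rng, spec, builder, unit, background, fam_specs,
                       consensi, truth)
            cursor = offset
        tail = spec.scaffold_length - cursor
        builder.add("background", _random_seq(rng, max(tail, 0),
                                              spec.background_gc))
        builders.append(builder)

    # --- mark excisions ---------------------------------------------
    if spec.make_b:
        singles = [t for t in truth
                   if t.insertion_mode == "satellite" and t.array_id is None
                   and t.nested_in is None and not t.split_host]
        n_excise = int(round(spec.excision_fraction * len(singles)))
        order = sorted(singles, key=lambda t: t.element_id)
        excised = {order[i].element_id
                   for i in rng.choice(len(order), size=n_excise, replace=False)}
        for builder in builders:
            for piece in builder.pieces:
                if piece.kind == "element" and piece.element_id in excised:
                    piece.in_b = False
        for t in truth:
            if t.element_id in excised:
                t.excised_in_B = True

    assembly_a: dict[str, str] = {}
    assembly_b: dict[str, str] | None = {} if spec.make_b else None
    for builder in builders:
        seq_a, coords_a = builder.render(False)
        assembly_a[builder.scaffold_id] = seq_a
        for t in truth:
            if t.scaffold_id != builder.scaffold_id:
                continue
            if t.element_id in coords_a:
                t.start, t.end = coords_a[t.element_id]
            elif t.split_host and t.element_id + "_L" in coords_a:
                t.start = coords_a[t.element_id + "_L"][0]
                t.end = coords_a[t.element_id + "_R"][1]
        if spec.make_b:
            seq_b, coords_b = builder.render(True)
            assembly_b[builder.scaffold_id] = seq_b
            for t in truth:
                if t.scaffold_id == builder.scaffold_id and \
                        t.element_id in coords_b:
                    t.start_B, t.end_B = coords_b[t.element_id]
    truth.sort(key=lambda t: (t.scaffold_id, t.start))
    return SimulationResult(assembly_a, assembly_b, truth, consensi)


def _make_copy(rng, fam_specs, consensi, fam_id, truncate=(0, 0)):
    fam = fam_specs[fam_id]
    seq = _mutate(rng, consensi[fam_id], fam.copy_mutation_rate,
                  fam.indel_rate)
    lo, hi = truncate
    seq = seq[lo:len(seq) - hi if hi else len(seq)]
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        seq = revcomp(seq)
    return seq, strand


def _emit_unit(rng, spec, builder, unit, background, fam_specs, consensi,
               truth):
    scaffold_id = builder.scaffold_id
    kind = unit["type"]
    if kind == "satellite_single":
        builder.add("background", background)
        builder.add("satellite", _satellite(rng, spec))
        seq, strand = _make_copy(rng, fam_specs, consensi, unit["family"])
        builder.add("element", seq, unit["id"])
        builder.add("satellite", _satellite(rng, spec))
        truth.append(TruthRecord(unit["id"], unit["family"], scaffold_id,
                                 0, 0, strand, "satellite"))
    elif kind == "tsd":
        fam = fam_specs[unit["family"]]
        # duplicate the tsd_len bp of host sequence at the cut point;
        # redraw if the duplicated word is itself satellite-like
        for _ in range(50):
            tsd = background[-fam.tsd_len:]
            if not _has_targeting_run(tsd + tsd):
                break
            background = background[:-1] + str(rng.choice(list("GC")))
        builder.add("background", background)
        seq, strand = _make_copy(rng, fam_specs, consensi, unit["family"])
        builder.add("element", seq, unit["id"])
        builder.add("tsd", tsd)
        truth.append(TruthRecord(unit["id"], unit["family"], scaffold_id,
                                 0, 0, strand, "tsd"))
    elif kind == "array":
        builder.add("background", background)
        builder.add("satellite", _satellite(rng, spec))
        members = unit["members"]
        fused_j = unit["fused_junction"]
        for j, (fam_id, element_id) in enumerate(members):
            fused_left = fused_j is not None and j == fused_j + 1
            fused_right = fused_j is not None and j == fused_j
            trunc = (int(rng.integers(5, 31)) if fused_left else 0,
                     int(rng.integers(5, 31)) if fused_right else 0)
            if fused_left or fused_right:
                # keep fused members on the plus strand so the planted
                # truncation sides are genomic sides
                fam = fam_specs[fam_id]
                seq = _mutate(rng, consensi[fam_id], fam.copy_mutation_rate,
                              fam.indel_rate)
                seq = seq[trunc[0]:len(seq) - trunc[1] if trunc[1] else len(seq)]
                strand = "+"
            else:
                seq, strand = _make_copy(rng, fam_specs, consensi, fam_id)
            builder.add("element", seq, element_id)
            truth.append(TruthRecord(element_id, fam_id, scaffold_id, 0, 0,
                                     strand, "satellite",
                                     array_id=unit["array_id"],
                                     fused=fused_left or fused_right))
            if j < len(members) - 1 and not (fused_j is not None and j == fused_j):
                builder.add("satellite", _satellite(rng, spec))
        builder.add("satellite", _satellite(rng, spec))
    elif kind == "nested":
        host_fam, host_id = unit["host"]
        inner_fam, inner_id = unit["inner"]
        builder.add("background", background)
        builder.add("satellite", _satellite(rng, spec))
        host_seq, host_strand = _make_copy(rng, fam_specs, consensi, host_fam)
        split = int(rng.integers(int(0.3 * len(host_seq)),
                                 int(0.7 * len(host_seq))))
        tsd = host_seq[split:split + 10]
        inner_seq, inner_strand = _make_copy(rng, fam_specs, consensi,
                                             inner_fam)
        builder.add("element", host_seq[:split + 10], host_id + "_L")
        builder.add("element", inner_seq, inner_id)
        builder.add("element", host_seq[split:], host_id + "_R")
        builder.add("satellite", _satellite(rng, spec))
        truth.append(TruthRecord(host_id, host_fam, scaffold_id, 0, 0,
                                 host_strand, "satellite", split_host=True))
        truth.append(TruthRecord(inner_id, inner_fam, scaffold_id, 0, 0,
                                 inner_strand, "tsd", nested_in=host_id))
    else:  # pragma: no cover
        raise ValueError(f"unknown unit type {kind!r}")
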