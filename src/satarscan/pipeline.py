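"""End-to-end orchestration: scan -> discover -> cluster -> probe ->
annotate -> arrays -> summarize (-> compare when a second assembly is
given). Each stage consumes only upstream artifacts, so the pipeline
is re-entrant per stage and deterministic for a fixed config."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .annotate import (FamilySummary, classify_flanks, detect_tir,
                       summarize_family)
from .arrays import (ElementArray, ModularityReport, check_modularity,
                     detect_fusions, link_elements)
from .comparative import SiteCall, UnresolvedAnchorError, anchor_flanks, classify_site
from .discovery import CandidateSegment, extract_candidates, probe_satellite_flanks
from .families import ElementOccurrence, Family, cluster_candidates, probe_genome
from .io import RunConfig, read_fasta, write_fasta, write_gff3, write_manifest, write_tsv
from .ssr import SSRDomain, find_ssrs, merge_adjacent

logger = logging.getLogger("satarscan")


@dataclass
class PipelineResult:
    ssrs: dict[str, list[SSRDomain]]
    candidates: list[CandidateSegment]
    families: list[Family]
    occurrences: list[ElementOccurrence]
    partial_hits: list[ElementOccurrence]
    arrays: list[ElementArray]
    modularity: list[ModularityReport]
    summaries: list[FamilySummary]
    site_calls: list[SiteCall] = field(default_factory=list)


def scan_assembly(assembly: dict[str, str],
                  config: RunConfig) -> dict[str, list[SSRDomain]]:
    ssrs = {}
    for scaffold_id in sorted(assembly):
        raw = find_ssrs(assembly[scaffold_id], config.ssr, scaffold_id)
        ssrs[scaffold_id] = merge_adjacent(raw, assembly[scaffold_id],
                                          config.ssr.max_interrupt)
    return ssrs


def run_pipeline(config: RunConfig,
                 assembly_a: dict[str, str] | None = None,
                 assembly_b: dict[str, str] | None = None,
                 flank_probe: bool = False,
                 write_outputs: bool = True) -> PipelineResult:
    """Execute the full discovery pipeline.

    Assemblies may be passed in-memory (tests, simulations) or read
    from the paths in ``config``.
    """
    if assembly_a is None:
        assembly_a = read_fasta(config.assembly_a)
    if assembly_b is None and config.assembly_b:
        assembly_b = read_fasta(config.assembly_b)

    logger.info("scanning %d scaffolds for microsatellites", len(assembly_a))
    ssrs = scan_assembly(assembly_a, config)

    candidates: list[CandidateSegment] = []
    for scaffold_id in sorted(assembly_a):
        candidates.extend(extract_candidates(
            assembly_a[scaffold_id], ssrs[scaffold_id], config.discovery,
            config.ssr, scaffold_id))
    if not candidates and flank_probe:
        logger.info("no inter-satellite candidates; falling back to "
                    "flank probing")
        for scaffold_id in sorted(assembly_a):
            candidates.extend(probe_satellite_flanks(
                assembly_a[scaffold_id], ssrs[scaffold_id],
                config.flank_probe_window, config.ssr, scaffold_id))
    logger.info("%d candidate segments", len(candidates))

    families = cluster_candidates(candidates, config.clustering)
    logger.info("%d families", len(families))

    occurrences: list[ElementOccurrence] = []
    partial_hits: list[ElementOccurrence] = []
    probe_params = config.probing
    for family in families:
        family.tir = detect_tir(family.consensus, config.tir)
        if probe_params.keep_partial:
            occs, partials = probe_genome(family, assembly_a, probe_params)
            partial_hits.extend(partials)
        else:
            occs = probe_genome(family, assembly_a, probe_params)
        occurrences.extend(occs)
    occurrences.sort(key=lambda o: (o.scaffold_id, o.start))
    logger.info("%d occurrences", len(occurrences))

    for occ in occurrences:
        occ.flank = classify_flanks(occ, assembly_a[occ.scaffold_id],
                                    ssrs[occ.scaffold_id], config.flanks,
                                    config.ssr)

    arrays = link_elements(occurrences, ssrs, config.arrays)
    fam_by_id = {f.family_id: f for f in families}
    modularity = []
    for array in arrays:
        detect_fusions(array, fam_by_id,
                       assembly_a[array.scaffold_id], config.arrays)
        modularity.append(check_modularity(
            array, assembly_a, fam_by_id,
            partial_hits if probe_params.keep_partial else None,
            config.arrays))

    summaries = [summarize_family(f, occurrences, arrays) for f in families
                 if any(o.family_id == f.family_id for o in occurrences)]

    site_calls: list[SiteCall] = []
    if assembly_b is not None:
        site_calls = compare_assemblies(assembly_a, assembly_b, occurrences,
                                        ssrs, fam_by_id, config)

    result = PipelineResult(ssrs, candidates, families, occurrences,
                            partial_hits, arrays, modularity, summaries,
                            site_calls)
    if write_outputs and config.out_dir:
        write_results(result, config)
    return result


def compare_assemblies(assembly_a, assembly_b, occurrences, ssrs, fam_by_id,
                       config: RunConfig) -> list[SiteCall]:
    calls = []
    for occ in occurrences:
        family = fam_by_id[occ.family_id]
        try:
            anchors = anchor_flanks(occ, assembly_a[occ.scaffold_id],
                                    ssrs[occ.scaffold_id], config.anchors,
                                    config.ssr, occurrences=occurrences)
        except UnresolvedAnchorError:
            calls.append(SiteCall(occ, "unresolved"))
            continue
        calls.append(classify_site(anchors, assembly_b, family,
                                   config.sites, config.ssr))
    return calls


def write_results(result: PipelineResult, config: RunConfig):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ssr_rows, ssr_tsv = [], []
    for scaffold_id, domains in sorted(result.ssrs.items()):
        for d in domains:
            ssr_rows.append({"scaffold": scaffold_id, "type": "satellite_DNA",
                             "start": d.start, "end": d.end,
                             "attrs": {"motif": "/".join(d.motifs),
                                       "units": d.unit_count,
                                       "purity": f"{d.purity:.3f}",
                                       "compound": int(d.compound)}})
            ssr_tsv.append([scaffold_id, d.start, d.end, "/".join(d.motifs),
                            d.unit_count, f"{d.purity:.3f}", int(d.compound)])
    write_gff3(out / "ssrs.gff3", ssr_rows)
    write_tsv(out / "ssrs.tsv",
              ["scaffold", "start", "end", "motif", "units", "purity",
               "compound"], ssr_tsv)

    write_fasta(out / "candidates.fasta",
                {f"{c.scaffold_id}:{c.start}-{c.end}": c.sequence
                 for c in result.candidates})
    write_tsv(out / "candidates.tsv",
              ["scaffold", "start", "end", "length", "gc", "flank_probe"],
              [[c.scaffold_id, c.start, c.end, c.length, f"{c.gc:.3f}",
                int(c.flank_probe)] for c in result.candidates])

    write_fasta(out / "families.fasta",
                {f.family_id: f.consensus for f in result.families})

    occ_rows, occ_bed = [], []
    for o in result.occurrences:
        flank = o.flank
        occ_rows.append({"scaffold": o.scaffold_id, "type": "repeat_region",
                         "start": o.start, "end": o.end, "strand": o.strand,
                         "score": f"{o.identity:.3f}",
                         "attrs": {"family": o.family_id,
                                   "identity": f"{o.identity:.3f}",
                                   "coverage": f"{o.coverage:.3f}",
                                   "flank_class": flank.category if flank else None,
                                   "tsd_len": flank.tsd_len if flank else None}})
        occ_bed.append([o.scaffold_id, o.start, o.end, o.family_id,
                        int(1000 * o.identity), o.strand])
    write_gff3(out / "occurrences.gff3", occ_rows)
    write_tsv(out / "occurrences.bed",
              ["#scaffold", "start", "end", "family", "score", "strand"],
              occ_bed)

    write_tsv(out / "families.tsv",
              ["family", "n_elements", "size_bp", "tir_len",
               "pct_microsatellite", "pct_tsd", "pct_neither",
               "pct_unresolved", "pct_linked_or_fused",
               "pct_at_scaffold_ends"],
              [[s.family_id, s.n_total, s.size_bp, s.tir_len,
                f"{s.pct_microsatellite:.1f}", f"{s.pct_tsd:.1f}",
                f"{s.pct_neither:.1f}", f"{s.pct_unresolved:.1f}",
                f"{s.pct_linked_or_fused:.1f}",
                f"{s.pct_at_scaffold_ends:.1f}"] for s in result.summaries])

    array_rows = []
    bed12 = []
    for i, (arr, rep) in enumerate(zip(result.arrays, result.modularity), 1):
        array_rows.append([f"arr{i:04d}", arr.scaffold_id, arr.size, arr.span,
                           int(rep.modular), len(arr.fusions),
                           ",".join(m.family_id for m in arr.members)])
        start = arr.members[0].start
        end = arr.members[-1].end
        sizes = ",".join(str(m.length) for m in arr.members)
        starts = ",".join(str(m.start - start) for m in arr.members)
        bed12.append([arr.scaffold_id, start, end, f"arr{i:04d}", arr.size,
                      ".", start, end, "0,0,0", arr.size, sizes, starts])
    write_tsv(out / "arrays.tsv",
              ["array", "scaffold", "size", "span", "modular", "fusions",
               "members"], array_rows)
    write_tsv(out / "arrays.bed12",
              ["#scaffold", "start", "end", "name", "score", "strand",
               "thickStart", "thickEnd", "rgb", "blockCount", "blockSizes",
               "blockStarts"], bed12)

    if result.site_calls:
        write_tsv(out / "sites.tsv",
                  ["scaffold_A", "start_A", "end_A", "family", "status",
                   "scaffold_B", "start_B", "end_B", "content_B",
                   "satellite_len_B"],
                  [[c.occurrence.scaffold_id, c.occurrence.start,
                    c.occurrence.end, c.occurrence.family_id, c.status,
                    c.scaffold_B or ".", c.start_B if c.start_B is not None else ".",
                    c.end_B if c.end_B is not None else ".",
                    c.inter_anchor_content or ".",
                    c.satellite_len_B if c.satellite_len_B is not None else "."]
                   for c in result.site_calls])

    write_manifest(out / "manifest.json", config, {
        "n_candidates": len(result.candidates),
        "n_families": len(result.families),
        "n_occurrences": len(result.occurrences),
        "n_arrays": len(result.arrays),
        "n_site_calls": len(result.site_calls),
    })
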