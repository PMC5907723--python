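# satarscan

De novo discovery of **satellite-targeted transposable elements**
(*SaTar* elements) in genome assemblies.

## The problem

Most class II (DNA) transposons insert into more-or-less arbitrary
genomic sequence by a transposase-driven cut-and-paste mechanism that
leaves a short **target-site duplication** (TSD, 8–11 bp for
*Mu*-superfamily elements). Several plant genomes, however, carry
families of compact non-autonomous Mu-like elements (MULEs/MITEs) that
are preferentially inserted **into microsatellite tracts**, most often
(TA)<sub>n</sub>. These satellite-targeted elements pile up as tandem,
mixed-family arrays in which intact elements are joined end-to-end by
satellite linkers — and, strikingly, never interrupt one another
("modular" arrays, in contrast to the nested stacking typical of
MITEs). Their hallmark architecture is:

```
...host———(TA)n———[TIR·······TIR]———(TA)n———[TIR·····TIR]———(TA)n———host...
              element 1 (family A)       element 2 (family B)
```

`satarscan` re-implements the discovery pipeline for such elements and
the analyses around it:

1. **SSR scan** — maximal perfect microsatellite runs (1–6 bp motifs,
   MISA-style unit thresholds), merged across ≤ 3 bp interruptions
   into compound domains; (TA)<sub>n</sub> tracts ≥ 12 bp are flagged
   as *targeting* satellites.
2. **Candidate discovery** — segments lying between consecutive
   targeting satellites that are 250–800 bp long with ≥ 20 % GC
   (both configurable; a satellite-flank probing mode is the fallback
   for genomes where this scan returns nothing).
3. **Family building** — greedy centroid clustering (≥ 80 % identity,
   ≥ 3 copies), star-alignment consensus, then probing of the whole
   assembly with each consensus on both strands, which also recovers
   copies inserted in complex sequence with TSDs.
4. **Annotation** — imperfect terminal inverted repeats (TIRs), and
   per-copy flank architecture: `microsatellite` (satellite tract on
   both sides), `tsd` (exact 8–11 bp direct repeat, never called when
   a satellite abuts a terminus), `neither`, or `unresolved` at
   scaffold ends.
5. **Arrays** — satellite-linked element chains, detection of
   *fusions* (linker deleted together with the facing element
   termini), a split-alignment test for *nesting* (one element
   interrupting another), and the random-placement spacing expectation
   genome_length / n_elements used to quantify clustering.
6. **Comparative sites** — for two related assemblies, each insertion
   site is re-anchored by its unique flanks and classified as
   `occupied`, `empty_satellite` (only the satellite tract remains —
   an insertion polymorphism at a microsatellite target), `absent`, or
   `unresolved`.
7. **Synthetic genomes** — a generator that plants element families
   with known TIRs, insertion modes, arrays, fusions, nestings and
   excisions, with full ground truth, used to validate every stage.

## Worked example

Simulate a 1.2 Mb assembly with three planted families (400/400/440 bp,
TIRs of 40/50/120 bp, 30 copies each, 70 % satellite-targeted), then
run the pipeline on it:

```sh
$ satarscan simulate --out-dir sim --seed 7 --n-scaffolds 4 --scaffold-length 300000
90 planted copies -> sim
$ satarscan run sim/assembly_A.fasta --out-dir out
3 families, 90 occurrences, 78 arrays -> out
$ head -4 out/families.tsv
family  n_elements  size_bp  tir_len  pct_microsatellite  pct_tsd  pct_neither  pct_unresolved  pct_linked_or_fused  pct_at_scaffold_ends
fam01   30          441      135      70.0                30.0     0.0          0.0             16.7                 0.0
fam02   30          400      77       66.7                30.0     3.3          0.0             16.7                 0.0
fam03   30          401      51       60.0                30.0     10.0         0.0             26.7                 0.0
```

All 90 planted copies are recovered. Each family row reads like the
standard element-architecture table: consensus size, TIR length, the
share of copies flanked by microsatellites vs. TSDs, and the share
sitting in multi-element arrays or fusions. Per-copy calls are in
`out/occurrences.gff3` (`repeat_region` features with family,
identity and flank class), satellites in `out/ssrs.gff3`
(`satellite_DNA`), arrays in `out/arrays.tsv`/`arrays.bed12`.

With a second assembly, sites are compared directly; here 9 of the 45
single satellite-mode copies were excised in the derived assembly B,
and all are recovered as satellite-only empty sites:

```sh
$ satarscan simulate --out-dir simb --seed 8 --n-scaffolds 4 --scaffold-length 300000 --make-b
$ satarscan compare simb/assembly_A.fasta simb/assembly_B.fasta --out-dir outc
empty_satellite=9 occupied=81
```

The library mirrors the CLI one-to-one (`satarscan.find_ssrs`,
`extract_candidates`, `cluster_candidates`, `probe_genome`,
`detect_tir`, `classify_flanks`, `link_elements`, `check_modularity`,
`classify_site`, `simulate`, …); see the docstrings and
`docs/methods.md`.

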