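# Methods

This note documents the models, algorithms and numerical choices
behind `satarscan`, and what the synthetic-genome validation does and
does not establish.

## Microsatellite scan

A microsatellite (SSR) is a maximal perfect tandem run of a 1–6 bp
motif. The scanner reports, for every motif length *m*, each maximal
interval where `s[p] == s[p-m]`, trimmed to whole units; runs are
broken by `N`, soft-masking is ignored (input is uppercased), and a run
whose unit is itself periodic (poly-A seen as "AA") is reported only
under its shortest motif. Motifs are canonicalised to the
lexicographically smallest string over all rotations of the unit and of
its reverse complement, so a (TA)<sub>n</sub> tract is motif `AT` on
either strand and scan output is mirror-symmetric under reverse
complementation.

Unit thresholds follow MISA-style defaults — mono ≥ 10, di ≥ 6,
tri ≥ 4, tetra/penta/hexa ≥ 3 units. Only the dinucleotide value is
load-bearing for discovery: with it, the smallest *targeting*
satellite, the (TA)<sub>n</sub>-type tract eligible to delimit an
element, is 12 bp. The targeting motif set defaults to `{AT}` but is
configurable, because element-flanking satellites in real genomes are
often non-TA. Domains of the same or different motifs separated by
≤ `max_interrupt` = 3 bp merge into a *compound* domain whose purity is
the fraction of the merged span covered by the component perfect runs;
compound domains act as single flanks/linkers downstream. Imperfect-SSR
detection by alignment scoring is deliberately out of scope — only
perfect runs plus bounded-interrupt merging.

One consequence of whole-unit trimming worth knowing: when the base
adjacent to a planted (TA)<sub>n</sub> tract happens to extend the run
in the other phase, the reported domain can start or stop one or two bp
away from the biological tract boundary. All downstream consumers
(flank classification, anchoring) therefore tolerate a
`satellite_max_gap` = 2 bp slack rather than requiring exact abutment.

## Candidate discovery

Candidates are the segments between *consecutive, non-overlapping*
targeting satellites that pass the discovery filters: length within
[250, 800] bp and GC ≥ 0.20 (N ignored in numerator and denominator;
an all-N segment is skipped). `max_len` is configurable up to 2000 bp
for the larger families (1–1.9 kb) known from real genomes; the default
stays 800. Segments are exactly the inter-satellite intervals
(`max_offset` = 0); edge slack is handled by flank classification, not
here.

The *flank-probe* mode emits fixed windows (default 400 bp) on both
sides of every targeting satellite, clipped at scaffold ends and at
neighbouring targeting satellites (so the shared interval between two
close satellites is emitted once). It feeds the same clustering and is
the fallback for genomes where the inter-satellite scan returns
nothing; no claim is made that it is equivalent to the primary scan.

## Family building

Clustering is greedy centroid assignment: candidates are visited in
decreasing length order (ties broken by coordinates, making the result
deterministic); each joins the first centroid the shorter sequence
matches as an edlib infix of the longer at ≥ 80 % identity on either
strand, else founds a centroid; clusters with < 3 members are dropped
(`min_copies` = 3 avoids calling plain two-copy duplications
families). Membership additionally requires the two lengths to be
within the coverage ratio (0.8) of each other. This mutual-coverage
rule is a deliberate tightening of coverage-of-the-shorter-only: a
fused element pair picked up as a single ~760 bp inter-satellite
candidate is otherwise the longest candidate, becomes the first
centroid, and absorbs both component families into one chimeric
cluster. With the rule, chimeras stay singletons and are discarded,
while the genuine families cluster around full-length centroids; their
fused copies are still recovered later by probing.

The consensus is a star alignment: every member is locally aligned to
the centroid (better strand kept) and votes per centroid column;
columns gapped in more than half the members are dropped, ties go to
the centroid base. Member insertions relative to the centroid are not
added — adequate for the substitution-dominated divergence the
generator emulates and for real young element families. Because
element orientation is intrinsically ambiguous for TIR-symmetric
elements, the consensus is normalised to the lexicographically smaller
of itself and its reverse complement.

Probing searches both strands of every scaffold with the full
consensus using edlib's bit-parallel infix aligner, harvesting
non-optimal hits by iterative masking down to an edit-distance budget
of 1.2 × (1 − min_identity) × consensus length. Each raw hit is then
refined by a *global* (NW) alignment of the oriented consensus against
the hit slice: identity is matches over alignment columns from the
cigar, leading/trailing target gaps tighten the genomic bounds, and
leading/trailing query gaps are recorded as consensus truncation. The
global refinement is essential: a local realignment trims terminal
mismatches, systematically shifting element edges off their flanking
satellites or TSDs. Hits at ≥ 80 % identity and ≥ 90 % consensus
coverage become full occurrences; overlapping same-family hits are
resolved greedily by identity, tolerating up to 50 % mutual overlap so
both halves of a same-family fusion survive. With `keep_partial`,
100 bp consensus chunks are probed as well and collinear chunk hits are
chained into partial occurrences (fragments, fusion stubs, split
nesting hosts).

Alignment scoring throughout the fine-grained steps is affine
match +1 / mismatch −2 / gap open −4 / extend −1; no scoring scheme is
prescribed by the biology, these are ordinary DNA-alignment values.

## TIR and flank annotation

TIR detection aligns the first *W* bp of the element against the
reverse complement of its last *W* bp (*W* = min(300, len/2)) with a
banded-start dynamic program: alignments must start within
`max_terminus_offset` = 3 of both termini and may end anywhere
(match +1, mismatch −1, gap −2, linear gaps — edit-style scoring is
appropriate here because the two windows are short and the search is
for a contiguous terminal repeat, not a general homology). Among
equal-scoring end cells the longest qualifying alignment is preferred,
then the smaller left offset; equal-scoring extensions of a true TIR
through chance matches would otherwise dilute identity below
threshold. A TIR is present at length ≥ 15 and identity ≥ 0.75 —
15 bp is set well below the shortest TIR the generator plants (40 bp)
to avoid false negatives, and the call is strand-invariant. Elements
shorter than twice the minimum length get a `too_short` report.

Flank classification has a strict precedence. (1) A flank cut by a
scaffold end or N-gap (less than `flank_window` = 50 bp of clean
sequence) → `unresolved`, regardless of anything else. (2) Targeting
satellites abutting (within 2 bp of) *both* termini →
`microsatellite`. (3) Otherwise, if *neither* terminus abuts a
satellite and the L bp immediately left equal the L bp immediately
right for some L from 11 down to 8 (longest first, exact match by
default; `tsd_max_mismatch` is configurable to 1 for degraded sites) →
`tsd`. The satellite guard in (3) is an invariant, not an
optimisation: a (TA)<sub>n</sub> tract trivially "duplicates" itself
and must never be reported as a TSD. (4) Anything else → `neither`.
The TSD comparison slides each element edge outward by up to
`edge_slack` = 2 bp, because consensus termini — and hence probed copy
bounds — are uncertain by a base or two (see the SSR phase note
above); the chance of a spurious ≥ 8 bp exact duplication within this
slack is negligible.

Family summaries report percentages over all full occurrences;
unresolved copies count in the total but in no architecture category,
so microsatellite + tsd + neither + unresolved = 100 up to rounding.
`pct_linked_or_fused` is the union share of copies in a multi-element
array or carrying a fusion truncation (the two are not double-counted).

## Arrays, fusions, nesting, spacing

Consecutive occurrences (families pooled) chain transitively into an
array when their gap is ≤ `max_link_gap` = 100 bp with ≥ 50 %
satellite coverage, or ≤ `max_junction_gap` = 12 bp regardless (a
possible fusion junction; 12 bp is kept below the smallest targeting
satellite so a fusion junction can never be a satellite linker).
Isolated copies are singleton arrays; membership is a partition.

A *fusion* is called at a junction of ≤ 12 bp with no satellite where
both members' consensus alignments are truncated ≥ 5 bp on their
junction-facing ends. Truncations are re-measured by a local alignment
of each member's locus against its consensus rather than read from the
probing bounds, because the infix search prefers to spend the missing
consensus tail as mismatches into the neighbour (cheaper than end
gaps), which hides the truncation and slightly overextends the bounds.

*Nesting* (one element interrupting another — the architecture these
arrays conspicuously lack) is detected per member by a split-host
test: for each family consensus, a local alignment of the consensus
against the regions immediately left and right of the member must (a)
abut the member on the junction-facing sides (within 20 bp, which also
absorbs a duplicated target site), (b) each cover ≥ 30 bp at ≥ 75 %
identity, (c) have abutting consensus coordinates (within 20 bp), and
(d) jointly cover ≥ 60 % but ≤ 100 % + 20 bp of the consensus. The
joint-coverage requirement is what makes chance local hits in random
flanks harmless. Partial probing hits, when available, serve as a
prefilter on which member/family pairs are examined. An array with no
split-host signature is *modular*.

The spacing expectation is the deliberately simple convention
mean = genome_length / n_elements and
expected span of k linked elements = k × mean; it is an arithmetic
yardstick for how non-random observed clustering is, not a stochastic
model of insertion.

## Comparative site classification

For each occurrence in assembly A, anchors of 500 bp are taken
immediately outside the flanking satellites (or outside the TSD
copies), skipping chains of abutting satellites — and, when the other
occurrences on the scaffold are available, abutting array neighbours
too, so an array member's anchors land in unique flanking sequence
rather than inside repeat copies. Each anchor is located in assembly B
by infix alignment at ≥ 90 % identity; an anchor whose second-best
placement is within 5 % (of anchor length, in edit distance) of the
best is *multiply-placed*. Sites with an unplaced/ambiguous anchor, or
with discordant placements (different scaffolds or strands, wrong
order, inter-anchor distance > 20 kb) are `unresolved` — with repeats,
anchoring is the dominant failure mode and this is the honest verdict.
Otherwise the inter-anchor region decides: a consensus match at probe
thresholds → `occupied`; ≥ 80 % satellite coverage with no consensus
match → `empty_satellite` (with the satellite bp reported); mostly-N →
`unresolved`; anything else → `absent`. Calls are symmetric site
states: no attempt is made to distinguish an insertion in A from an
excision/deletion in B, which flank anchoring alone cannot resolve.

## Synthetic genomes and what the validation shows

The generator emulates a fragmented plant assembly: i.i.d. background
at GC 0.35 (a typical plant genome-wide value), 10 scaffolds of
~500 kb by default, and three planted families of 400/400/440 bp with
40/50/120 bp TIRs at 95 % TIR identity — sizes and TIR lengths shaped
like real compact satellite-targeted families. Copies diverge by 2 %
substitutions (indels separately configurable, off by default so that
alignment thresholds are exercised deliberately); 70 % of copies are
inserted between freshly drawn (TA)<sub>n</sub> tracts whose unit
counts follow 6 + Geometric(p = 0.15) (min 12 bp, mean ~25 bp,
emulating variable-length tracts), and 30 % are TSD-inserted into
background with an exact 10 bp duplication (redrawn if the duplicated
word is itself satellite-like). Six arrays of 2–4 members, two
linker-deleting fusions (5–30 bp truncation per facing end), and
optionally nested insertions (a copy TSD-inserted into the middle
30–70 % of a host copy) are planted; a derived assembly B excises a
configurable fraction (default 20 %) of the single satellite-mode
copies, leaving the flanking tracts as one merged satellite. Array
members are excluded from excision so that empty-site truth remains
well-defined per locus. Scaffolds are built as typed piece lists, so
truth coordinates slice exactly to the planted sequences, and output is
byte-identical for identical specs.

Recovery is scored by greedy one-to-one matching at ≥ 50 % reciprocal
overlap; precision = matched/detected, recall = matched/truth (split
nesting hosts excluded from the denominator, since a split host is by
construction not a full copy). Flank accuracy is computed over
matched, non-fused copies — fusion deletes the very flank architecture
being scored. Array recovery is a Rand-style pair agreement of
co-membership; site calls are tallied into a confusion matrix against
the truth state (occupied unless excised).

On this generator the pipeline attains precision, recall and flank
accuracy of 1.0 across seeds, all arrays modular without nesting, the
planted nesting found exactly once, and a diagonal site-call confusion
matrix. That establishes internal correctness of every stage under the
stated conditions — substitution-only divergence, clean assemblies
without gaps, satellite tracts that are perfect repeats, families well
inside the size window. It does not establish performance on real
assemblies, where diverged/degenerate copies, compound imperfect
satellites, assembly gaps and collapsed repeats will lower recall and
blur flank calls; the configurable thresholds exist for exactly that
tuning.

## Problem sizes

The shipped validation uses 5 Mb assemblies (10 × 500 kb) with 90
planted copies for recovery and comparative runs, and 1.2 Mb (4 ×
300 kb) for the modularity scenarios — sizes at which every stage's
behaviour is already fully exercised (tens of copies per family,
multiple arrays, fusions and excisions per run) while a complete
pipeline run takes seconds on one CPU. All stages stream per scaffold,
and the probing cost is linear in assembly size per family, so the
same code runs on real assemblies unchanged.

## Known limitations

- Imperfect satellites are handled only via bounded-interrupt merging;
  heavily degenerate tracts may fall below the targeting threshold.
- Consensus building ignores member insertions relative to the
  centroid; indel-rich families would need a proper MSA.
- The TSD test is exact by default; one mismatch can be allowed, more
  divergence than that defeats it.
- Autonomous partner elements are treated simply as long families; no
  transposase ORF annotation is attempted.
- Elements lying wholly inside assembly gaps are undetectable by
  design.
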