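# Methods

This note documents the models, algorithms and numerical choices behind
`tsakit`, the assumptions they rest on, and what the synthetic-data tests do
and do not demonstrate about real libraries.

## qPCR copy-fold model (`vcqa`)

A single control vector carries one amplicon per genome compartment, so all
three amplicons share one molar concentration on the control side. For
amplification efficiency `E ∈ (0, 1.5]` and cycle thresholds measured on the
vector (`CT_control`) and the sample (`CT_sample`), the efficiency-corrected
relative quantity is `Q = (1+E)^(CT_control − CT_sample)`, and the copy fold
of an organelle is `Q_organelle / Q_nuclear`.

Rounding convention: reported quantities are rounded half-away-from-zero to
4 decimals, and the copy-fold ratio is taken over those 4-decimal
intermediates before integer rounding (also half away from zero). This is
the convention of printed qPCR tables, and it is the convention under which
the canonical worked example reproduces its published copy folds; the
un-rounded ratios differ in the third significant digit. `exact=True`
bypasses all intermediate rounding for analysis use.

Dataset sizing assumes depth proportional to copy number: a dataset of
`G·D/fold` bases (nuclear genome `G`) gives the organelle `D` layers. The
50-layer default for `target_depth` is the usual threshold for a clean short-
read de novo assembly.

## Synthetic libraries (`simgen`)

The generator emulates the study design this package targets: 100 nt
paired-end reads, inserts normal around 500 bp (σ = 50, truncated to
[2·read_length, genome length] and rounded to integers), per-base qualities
fixed at Q40, and three compartments sampled with probabilities proportional
to copy_fold × genome length — plastid with a quadripartite LSC/IRa/SSC/IRb
layout (IRb the reverse complement of IRa), a circular mitochondrion that may
carry a tract copied verbatim from the plastid LSC (the homology trap), and a
linear nuclear decoy. Circular genomes are sampled across the origin; mates
are inner-oriented with the fragment strand chosen uniformly; truth labels
(compartment, fragment start, strands) go to a sidecar table, never into the
FASTQ. Optional per-base substitution errors and 3'-end adaptor read-through
contamination are available for stress tests.

What it does *not* model: indel sequencing errors, quality decay along the
read, PCR duplicates, coverage bias, nuclear repeat structure (nuclear
sequence is i.i.d. uniform) and organellar structural heteroplasmy. Passing
the end-to-end tests therefore shows the pipeline's logic is correct under
clean, uniform coverage — not that it is robust to every artefact of a real
instrument run.

Problem sizes used in the test suite: a compact triple (plastid 5.8 kb,
mito 6 kb, nuclear 8 kb; 14,000 pairs) for module-level checks, and a
study-shaped triple (plastid 15 kb quadripartite, mito 20 kb with a 1 kb
plastid tract, nuclear 50 kb; copy folds 100:10:1; 70,000 pairs, putting the
mitochondrial stratum at ~80 layers and the plastid at ~800) for the
end-to-end recovery check. These are scaled-down analogues of the real
153.5 kb / 223.4 kb problem chosen so the whole suite runs in well under a
minute of assembly time while preserving every structural feature the method
has to negotiate: the depth strata, the IR collapse, and the homology trap.

## Depth-stratified unitig assembly (`assembler`)

Kmers are counted canonically (lexicographic min of kmer and reverse
complement; k odd so no kmer is its own reverse complement; kmers containing
N are skipped). Kmers with count below the frequency threshold are dropped;
each survivor contributes a directed edge in both orientations between its
flanking (k−1)-mers; contigs are maximal non-branching paths. There is no
bubble popping, tip clipping or read threading — the two count thresholds
are the whole cleaning model, which keeps the depth-stratification mechanism
auditable. In this unitig graph the edge-coverage parameter acts on the same
kmer counts as the frequency threshold, so the effective cutoff is their
maximum; both are kept as separate parameters for interface compatibility.

A contig whose first and last (k−1)-mers coincide is a complete cycle,
reported circular with the duplicated overlap trimmed. Deduplication of the
two strand-walks of one unitig uses the canonical sequence; for cycles, the
canonical kmer set. Output order is deterministic (length descending, then
lexicographic).

Consequences exercised by the tests: a repeat-free circular genome at
uniform coverage yields exactly one circular contig equal to the genome up
to rotation and strand; a quadripartite plastid splits at the IR junctions
into single-copy contigs plus one collapsed IR contig at twice the depth.

Defaults (k = 41, frequency 20, edge coverage 20, contigs ≥ 1 kb) are the
published step-2 operating point of the method this package re-implements;
step 1 raises the frequency threshold to sit between the mitochondrial and
plastid kmer-depth strata (150 in the pipeline default, against ~48 and ~480
in the study-shaped fixture).

## Exact placement and pair removal (`exactmap`)

Placements are full-length and gap-free with at most `m` mismatches; N never
matches. Seed-and-verify uses `m+1` non-overlapping seeds of length
`seed_k ≤ ⌊read_length/(m+1)⌋`; by pigeonhole at least one seed is exact, so
the scan provably misses nothing (verified against an exhaustive Hamming scan
in the tests). Circular references receive a wrap-around overhang so
origin-crossing reads place; positions are reported modulo length. A pair is
"plastid" iff either mate has at least one exact placement — the removal rule
whose side effect (deleting homologous mitochondrial tract coverage) the gap
closer must repair.

Shared-region masks collect canonical `min_run`-mers common to the two
genomes and merge them into runs; the complement is the "unique regions"
used for unbiased depth. The default `min_run` = 100 nt defines "similar
region" at read length, a documented choice rather than a published value;
mask boundaries are correct to ±(min_run−1).

Depth reporting attributes each placement to a region when its start falls
inside (so `mapped_bases = mapped_reads × read_length`), rounds layers to the
nearest integer, and counts multi-placed reads once per placement — inside a
collapsed IR the doubled depth is visible by design, so copy-fold/depth
agreement checks should use unique single-copy regions (the mitochondrial
unique region matches its copy-fold expectation within 10% in the tests).

## Reference-guided drafting (`draftbuild`)

Anchors are exact `anchor_k`-mers unique in the reference counted
strand-symmetrically, so kmers inside an inverted repeat (present once
forward, once reverse-complemented) are excluded and a repeat-only scaffold
places nowhere rather than being assigned to one copy silently. Per strand,
the largest colinear anchor chain is taken (longest increasing subsequence);
the better-covering strand wins, ties to '+'; scaffolds whose chain covers
under half their length are rejected as unrelated. On circular references
anchors are first lifted onto the dominant diagonal modulo the reference
length (band ±200 nt, tolerating modest indels), so origin-spanning scaffolds
chain correctly.

Placed scaffolds are ordered by reference position and joined seamlessly
where their ends share an exact overlap (≥ 30 nt); otherwise an N run of
max(reference-implied distance, 100) separates them. Only the ordering
consults the reference: sample-specific insertions inside a scaffold survive
untouched. Heavily overlapping reference claims with irreconcilable
sequences raise an ambiguity error naming both scaffolds — conflicts
surface, they are never resolved silently; a scaffold contained verbatim in
another is dropped as redundant. The wrap-around gap of a circular reference
is internalised by starting the draft mid-way through the first scaffold,
which keeps gap closure a purely linear problem; the final sequence is
therefore a rotation of the genome, and all truth comparisons are up to
rotation and strand.

## Iterative anchored gap closure (`gapclose`)

Each cycle: (1) map all reads to the draft and keep pairs with ≥ 1 mate
placed exactly (anchored); (2) for each gap, collect partner mates whose
anchored mate's position and orientation put them over the gap (window:
insert mean ± 3 σ, inward orientation), oriented onto the draft's forward
strand — a mate is usable even when it also places elsewhere on the draft,
because a read inside one IR copy always maps to the other copy yet its pair
geometry says it belongs over the gap; (3) grow each flank base by base: a
candidate read joins the vote once its first 50 bases match the growing tip
exactly (and its whole current overlap verifies), and the next base requires
a strict majority with ≥ `min_support` (default 3) votes — a tie or thin
support stops extension at that base, never a guessed base; (4) when the two
flank extensions share an exact ≥ 40 nt overlap the gap closes and its Ns
disappear, otherwise the N run shrinks by the extension amounts (floor 1 N
while open). Cycles repeat until an iteration extends nothing anywhere (the
global reading of "no gap extends") or an iteration cap (20) is hit, which
warns and leaves the residual gaps in the gap table for targeted finishing.

Per-round extension is capped at gap length + 2 read lengths and flank edit
windows of neighbouring gaps are split at their midpoint, so edits never
collide and a splice always lands inside the retained window. Safety
properties asserted by the tests: the draft's N count is non-increasing,
bases outside gap neighbourhoods are never rewritten, and with error-free
reads every base written is a true genome base even at `min_support` = 1.

The closure pool is deliberately the *full* clean read set, not the
plastid-removed pool: the homologous tract's fill material was removed with
the plastid pairs and is recoverable only by exact anchoring to the
mitochondrial draft. The tests demonstrate both directions — with the
surviving pool alone the tract gap stays open; with the full pool it closes
exactly. The pipeline's plastid-stage closure is the same computation: a
pair can only contribute fill material if one mate anchors to the draft, so
a pool restriction to anchored pairs changes no vote.

## Genome comparison (`variants`)

Colinear genomes are aligned by chaining anchor kmers unique in both
sequences, with each inter-anchor segment aligned globally at unit
mismatch/gap costs (edlib); no rearrangement handling — unchainable inputs
fail loudly instead of mis-typing events. A maximal run of adjacent
difference columns is one event: SNP (1 ↔ 1), MNP (n ↔ n, every column
differing), indel (one side empty), CV (length-changing with both sides
non-empty). The merging rule is this package's explicit definition of
MNP/CV boundaries. Indels are left-aligned through homopolymers for
deterministic coordinates (VCF export pads them with the preceding base).
Coding annotation marks CDS overlap; only coding SNPs get a synonymy call
(strand-aware codon re-translation under the standard genetic code);
synonymy of indels/MNPs/CVs is reported as not applicable.

## Pipeline (`cli` / `pipeline`)

`run_tsa` wires the stages in the published order (QC → stratified assembly
→ scaffold placement → draft → closure; then exact pair removal → standard
assembly → placement → draft → strict iterative closure; then shared-region
masking and unique-region depth), records per-stage counts (reads kept,
scaffolds total/aligned, gaps total/filled, lengths, depths, a read-
conservation check across the partition), and is byte-reproducible for a
fixed config and read set. Stage failures raise a `PipelineError` naming the
stage. The `tsa` command exposes each stage and the full run from a YAML
config whose defaults are printed into the run report, so a run record is
self-describing.

## Known limitations

- The assembler's unitig-only model cannot separate repeats other than by
  the depth thresholds; real plastid IR boundary fine-structure (short
  dispersed repeats) would fragment more than the simulation shows.
- Exact-match semantics everywhere mean sequencing errors leak pairs through
  the plastid filter and deny anchors to the closer; the published method
  shares this property. Error-rate stress beyond light substitution testing
  is out of scope.
- Gap closure assumes the insert-size model it is given; a mis-stated insert
  geometry starves gaps of candidates rather than mis-filling them.
- `align_genomes` requires colinearity; genomes differing by inversion or
  transposition need external synteny handling first.
- Depth statistics count multi-placements, so IR regions report doubled
  depth by design; use unique regions for copy-fold comparisons.
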