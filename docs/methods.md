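# Methods

## Input model and filtering

The scaffolder consumes a draft assembly (FASTA) and Hi-C read-pair
alignments to it (SAM/BAM, or the ten-column `bed_pairs` text dialect).
Only pairs with both mates mapped are used; secondary and supplementary SAM
records are ignored. A pair is discarded when **either** mate has mapping
quality ≤ `mapq_threshold` (default 30) — multi-mapped reads receive MAPQ 0
from standard aligners, so this one filter also removes them. All
coordinates are 0-based half-open internally; SAM's 1-based positions are
converted at parse time. Coordinate-duplicate pairs are retained by default
(`dedup` enables removal); duplicate links inflate counts multiplicatively
and the greedy construction depends only on relative weights, so
deduplication rarely changes the result.

## Misassembly detection

Physical coverage of a pair is the interval from the leftmost mapped base
of either mate to the rightmost, gap included; per-base physical coverage
sums these intervals (computed with a difference array, O(length + pairs)).
The detector searches for the contiguous interval minimizing
Σ (cov[i] − δ), i.e. the minimum-sum subarray of the mean-shifted coverage,
computed in linear time via prefix sums (the minimum-variant of Kadane's
algorithm). Numerical choices:

- **δ (expected level)**: half the median of the contig's nonzero per-base
  coverage, recomputed per (sub)contig. A per-contig robust statistic
  adapts to uneven pair density across contigs.
- **Acceptance threshold**: a call's deficit magnitude must be at least
  δ × `min_drop_span` (default 1000), the deficit a complete coverage
  dropout of 1 kb would produce. This rejects shallow noise dips while
  accepting genuine junctions, whose dip reaches near zero over tens of kb.
- **Edge handling**: coverage necessarily ramps to zero at contig ends, so
  candidate intervals whose midpoint lies within `edge_margin` (default
  10 kb) of an end are masked and the search continues elsewhere on the
  contig; they never trigger a break.
- **Multiple misjoins**: after an accepted call the contig is split at the
  interval midpoint and detection recurses on the halves, using only pairs
  wholly contained in each half, until no call passes. Splits rename
  `<name>` to `<name>_1`/`<name>_2` recursively; a remap table carries
  original coordinates to post-break coordinates and is applied to every
  alignment before link counting. Total bases are always conserved.
- The stage can be disabled (`--no-break`) when the input contigs were
  already corrected by another technology (e.g. optical maps).

The break point is placed at the flagged interval's midpoint: the deficit
interval is roughly symmetric about the true junction, so the midpoint is
the natural estimator; on simulated chimeras it lands within a few hundred
bp to ~3 kb of the junction.

## Scaffold graph

Window width at each contig end is `min(l, ⌊length/2⌋)` with l = 500 kb by
default, for both link counting and restriction-site counting — the cap
keeps the B and E windows disjoint on short contigs. A read assigns to B
when its interval lies within the first window, to E when it starts in the
last window, otherwise to neither; strand is never used. Restriction-site
counts RE(C) scan the end window for the enzyme motif(s) (IUPAC-expanded;
the reverse complement is additionally scanned for non-palindromic motifs)
and add a pseudocount of 1, so the weight
`W = links/(RE(C1)+RE(C2))` is always finite. A raw-count mode
(`W = links`) exists for runs without sequence or enzyme information.

Construction is greedy: drop candidates with fewer than `min_links`
(default 5) raw pairs; sort by weight descending with deterministic
tie-breaks (raw links descending, then lexicographic node names); add an
edge only when neither end node exists in the graph yet — so the kept Hi-C
edges form a matching on contig ends; then add each linked contig's B–E
edge. Cycles can arise (the classic case: both the BB and EE edges of two
contigs survive, and the two contig edges close a 4-cycle); every cycle is
broken at its minimum-weight Hi-C edge, iterating until acyclic — this
generalizes cleanly to longer cycles formed by whole components closing on
themselves. The result provably has maximum degree 2 and exactly two
degree-1 nodes per component, which the code asserts after every build.

## Layout

Each component's unique degree-1-to-degree-1 path is traversed; a contig
edge crossed B→E yields a forward placement, E→B a reversed one. Layouts
are canonicalized (lexicographically smaller terminal contig first) since a
scaffold and its reverse complement are equivalent. Components with more
than `N_th` contigs (default 3) are seeds. Small scaffolds are dissolved;
each contig is assigned to the seed maximizing the summed weight of
original (pre-pruning) candidate edges between the contig's ends and the
seed's contigs, ties to the smallest seed id, unassignable contigs becoming
singletons (an entirely unassignable small scaffold is kept intact).
Insertion order is by descending assignment weight so well-supported
contigs claim slots first; each insertion maximizes the seed's total
adjacent-pair facing-end weight over all gap positions (both termini
included) and both orientations, evaluated against the seed as it grows
(sequential greedy, no joint re-optimization), ties to the smallest
position then forward orientation. Every choice above is deterministic, so
identical inputs give byte-identical outputs.

## Output

Scaffold FASTA (60-column, gap runs of N, default `gap_size` 500) and AGP
v2.1 (gap type `scaffold`, linkage `yes`, evidence `proximity_ligation`)
describing the identical structure; scaffolds are named `scaffold_<k>` by
decreasing length. Reports: layout TSV, graph edge TSV, break-call BED,
remap TSV, JSON config echo and a counters log.

## Simulator

The generator emulates exactly the contact structure the method assumes:

- Chromosomes are uniform-random DNA (default 4 × 2 Mb), so GC ≈ 0.5 and
  GATC sites occur at their natural ~1/256 bp density.
- Contigs are uniform-length fragments (default 50–200 kb → ~60 contigs),
  each reverse-complemented with probability ½, names shuffled.
  `chimera_rate` of the fragments are fused pairwise — preferentially
  across chromosomes — with the junction recorded.
- Each of `n_pairs` (default 200,000) read pairs is inter-chromosomal with
  probability `p_inter` (default 0.1; both loci uniform, chromosomes
  forced distinct) or intra-chromosomal with a signed exponential mate
  distance (scale `intra_decay_scale`, default 20 kb, reflected at
  chromosome ends). The exponential is the simplest monotone decay
  consistent with the qualitative distance-decay of Hi-C contact maps; the
  20-kb scale reflects that the bulk of ligation products are short-range.
  Reads are emitted directly as MAPQ-60 alignments in contig coordinates —
  sequence-level read simulation and re-alignment are deliberately skipped.

What the simulator does **not** model: restriction-fragment, GC and
mappability biases; topological domains and compartment structure in the
contact map; mapping ambiguity in repeats (every simulated read is placed
with certainty). Passing tests therefore demonstrate the correctness of
the algorithms under the stated contact model, not robustness to the
artefacts of real libraries — on real data the MAPQ filter and parameter
tuning (`l`, `min_links`, break thresholds) carry that burden.

## Verification and problem sizes

The test suite checks every routine against an independent oracle where
one exists: per-base painting for physical coverage, exhaustive O(n²)
subarray search for the low-coverage interval (500 random profiles),
brute-force rebuild-and-sum scoring for insertion (random seeds of ≤ 8
contigs), and the degree/acyclicity/two-endpoints structure on 200 random
candidate-edge sets. End-to-end runs use the default study conditions
(4 × 2 Mb, ~60 contigs, 200k pairs; `p_inter` 0.05 for recovery runs,
0.1 for the contact statistic; chimera rate 0.1 for break recovery) —
sizes chosen so a full suite run completes in well under a minute while
leaving ~300 informative pairs per true junction, comfortably above the
`min_links` floor. `scripts/acceptance.py` recomputes all of these from
scratch under a caller-supplied seed.

## Known limitations

- Spurious inter-chromosomal edges between two otherwise-free chromosome
  ends can join two chromosomes into one scaffold; the method bounds the
  rate (weight sorting, `min_links`) but cannot exclude it, and no
  chromosome-count prior is used by design.
- Cycle removal and greedy edge selection are heuristics; no global
  optimality claim is made for the selected matching.
- Misassembly detection needs the junction's physical-coverage dip to be
  resolvable: junctions within `edge_margin` of a contig end, or contigs
  with very sparse intra-contig pairs, are undetectable.
- Insertion never re-scores seeds jointly after all insertions; a
  different insertion order could in principle yield a heavier layout.
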