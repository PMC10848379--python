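# Methods

## Coordinate and strand conventions

All coordinates are 1-based, fully closed intervals, as mitogenome
annotation tables print them; a feature's length is `end − start + 1`.
The circle's origin lies between position L and position 1. A feature
spanning the origin carries an explicit `wraps` flag — wrap is never
inferred from `start > end` alone, so a malformed table fails loudly
instead of silently producing a 15 kb "feature".

Strands are labelled H (heavy) and L (light). The stored sequence is the
heavy strand. Every per-gene statistic — composition, skews, codon
counts — is computed on the coding (sense) strand, i.e. L-strand genes
are reverse-complemented first. This convention is not optional
decoration: the protein-coding set's published strand asymmetry
(AT-skew −0.182 with four of thirteen genes on the light strand) is only
reproducible on sense-strand sequence, which we verified directly from
the printed percentages ((29.72 − 42.98)/72.70 = −0.182). The
whole-genome row alone uses the deposited heavy strand as stored.

Gene labels are folded onto one canonical vocabulary (`cox1`…`nad4l`,
`trnA`…`trnY` with L1/L2 and S1/S2 isoacceptors, `rrnS`/`rrnL`, `CR`).
Order figures use one-letter tRNA codes and tables use `trn` codes; a
single normalization table prevents join bugs between the two.

## Composition and skews

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C). Both are scale-invariant,
so counts and percentages give identical values; the tests exploit this
by recomputing published skews directly from printed percentages.
Ambiguity code N may appear in sequence but is excluded from both
numerator and denominator of every percentage; a region that is all N
raises rather than returning 0/0.

Report rounding is decimal half-up (2 dp for percentages, 3 dp for
skews) to match printed-table precision; internal values keep full
float precision. Python's builtin banker's rounding would disagree with
printed values (e.g. 1.0545 → 1.054 instead of 1.055), hence the
explicit `Decimal`-based rounding helper.

## Codon usage

Coding sequences are split into consecutive non-overlapping triplets
from position 1 of the sense strand; a trailing 1–2 nt partial codon (an
incomplete terminator completed by polyadenylation in vivo) is dropped
and logged, never padded — deterministic and consistent with "T(AA)"
annotation style. Counts use RNA-alphabet keys.

RSCU(c) = n_c·|F| / Σ_{F} n. Families with zero total yield *missing*
RSCU values, not zeros. Two family maps ship:

- **as-published** — the standard-code grouping that mitogenome
  codon-usage tables conventionally print: leucine split into
  {UUA, UUG} and CUN, serine into UCN and {AGU, AGC}, arginine into CGN
  and {AGA, AGG}, isoleucine {AUU, AUC, AUA}, single-codon families for
  AUG and UGG, and the three terminators {UAA, UAG, UGA} as one family.
  This is the map under which the packaged count table's printed RSCU
  values are arithmetically reproducible (62 of 64 to 3 dp; the printed
  UUA/UUG values are inconsistent with their own printed counts under
  any family assignment and are treated as errata).
- **invertebrate mitochondrial** (translation table 5) — AUA→Met,
  UGA→Trp, AGA/AGG→Ser — selectable where biologically-correct grouping
  matters more than printed-table parity.

Amino-acid usage sums family totals by label, merging split families
(L1+L2 → Leu). Note that the packaged counts make Phe (533) the most
frequent amino acid; the usage function reports what the counts say.

## Annotation geometry

Overlaps are computed on the arc intersection of *every* unordered
feature pair, not just rank-adjacent pairs — nested and offset overlaps
(e.g. a tRNA inside an rRNA's boundary region) are real in these
annotations. Strand is ignored. The control region is excluded from
overlap counting by default: gene/gene overlap counts in mitogenome
descriptions do not count the CR, whose boundaries are operationally
defined and commonly abut a flanking tRNA by a base (the packaged
annotation has exactly such a 1-bp CR–trnM contact; including it is a
flag away). Positions shared under a triple overlap are counted once per
pair.

Spacers are gaps between rank-adjacent features in circular start order
(`gap = next.start − this.end − 1`, including the origin-spanning gap);
only positive gaps are reported, and the CR counts as a feature, never
as a spacer. Ties on start coordinate order the longer feature first,
with a warning.

For annotations without triple overlaps, `Σ lengths − Σ overlap bp +
Σ spacer bp = L` holds exactly; the tests assert it, and check both
totals against a brute-force per-position occupancy scan, on randomized
synthetic annotations.

## Gene orders, adjacencies, breakpoint distance

A gene order is a cyclic sequence of signed labels; equality is rotation
equality. Whole-circle reflection with sign flip is *not* an equality by
default (strands are distinguishable molecules), though the adjacency
representation — each neighbour contact identified with its
reverse-complement reading — cannot separate an order from its
reflected complement, a standard property of breakpoint-type distances
on circular genomes. An unsigned mode reduces contacts to unordered
label pairs for figure-style comparisons where strand changes are not at
issue.

Breakpoint distance = |adjacencies(o1) ∖ adjacencies(o2)|; with equal
label sets it is symmetric, zero on rotations, and satisfies the
triangle inequality (|A∩B| + |B∩C| ≤ n + |A∩C| for n-element adjacency
sets). A single block transposition costs exactly 3 breakpoints, checked
exhaustively on 8-gene circles. Orders over different label universes
are compared after restriction to the common label set, logged.

## Rearrangement model and scenario search

Two composite event types are modelled, matching the TDRL +
recombination narrative for this clade:

- **TDRL event** — tandem duplication of a contiguous block followed by
  loss of one copy of each member (a keep-mask in {first, second} per
  gene), applied atomically. Monotone masks (all survivors in reading
  order) are identities and are excluded from search enumeration.
- **Translocation** — excision of a contiguous block and reinsertion at
  a named position, sign-preserving.

Inversions are deliberately not modelled: the packaged history requires
none, and a strand mismatch should fail verification loudly rather than
be absorbed by an op the model does not claim. Primitive ops
(duplicate / delete-copies) are also exposed so intermediate
duplicate-bearing states can be constructed and inspected.

A scenario's **involved genes** are the members of duplicated or
translocated blocks — not breakpoint-adjacent genes — which is the
definition under which the packaged history involves 11 tRNAs + 4 PCGs.
The packaged history itself encodes the published five steps as 6 ops
(2 TDRL + 4 translocations); it is one plausible history, not provably
minimal, and minimality claims in this package are confined to
`scenario_search` outputs.

`scenario_search` enumerates all minimal scenarios by iterative
deepening. Each depth d is split into forward moves from the source
(⌈d/2⌉ layers) and predecessor moves of the target (⌊d/2⌋ layers) joined
on intermediate states — meet-in-the-middle keeps depth-2 all-minimal
enumeration at ~10³–10⁴ state expansions for 10-gene orders instead of
~10⁷. Predecessors are exact: translocations are closed under inversion,
and the TDRL predecessors of an order are obtained by replacing a
contiguous region X·Y with any proper interleaving of X and Y. States
are canonicalized as the lexicographically least rotation; scenarios are
deduplicated up to identical sequences of intermediate orders and
returned in deterministic lexicographic order. A search-space guard
raises rather than thrash when the estimated frontier exceeds ~5·10⁶
states. Tests cross-check minimal depths against an independent plain
BFS oracle on ≤7-gene orders and verify every returned scenario by
replay.

## Synthetic data

`simulate_genome` realises a feature plan (name, type, length, strand,
gap-or-overlap to next) on a circle: sequence i.i.d. from per-strand
base probabilities (defaults A 0.3778 / T 0.3651 / G 0.0970 / C 0.1601
on the heavy strand, mirroring the reference composition), light-strand
features drawn on their sense strand and stored complemented, PCGs given
an explicit ATG start and TAA stop (truncated for non-multiple-of-3
lengths). The default plan copies the packaged annotation's lengths,
strands and gaps, so "study-shaped" fixtures need no download; the
simulated circle is 15,344 bp with the same 7 gene-overlap geometry
(max 23 bp). Where planned features overlap, the later feature's bases
win in the shared positions; with ≤ 25 bp overlaps this perturbs
composition negligibly (empirical base frequencies stay within 1.5
percentage points of the generator probabilities at 15 kb, asserted
seeded).

What the generator does *not* emulate: codon-usage bias (PCG bodies are
i.i.d. bases, so RSCU on simulated genomes is ≈ flat), realistic tRNA/
rRNA secondary structure, substitution processes, and inversion events.
Passing tests on synthetic data therefore demonstrate bookkeeping
correctness (geometry, lengths, orders, scenario algebra, composition
accounting), not biological realism of sequence content.

`simulate_rearranged_order` applies n random composite events (blocks of
1–7 genes; TDRL masks resampled until non-monotone; translocation
destinations resampled to exclude no-ops) and records the ground-truth
scenario, which verifies against the output by construction. Over 100
seeded 10-gene simulations with 1–2 events, the minimal-scenario search
recovers the planted history (or finds a strictly shorter equivalent) in
≥ 95% of runs; the observed rate is 100/100.

## Packaged reference data and its known inconsistencies

The reference annotation, regional composition percentages and codon
counts are stored verbatim as printed, including internal
inconsistencies, which are surfaced rather than silently fixed:

- nad5 length is 1713 bp by its coordinates but 1680 bp in the
  composition table; nad6 is 492 vs 516. The fixture ships coordinates
  verbatim; derived lengths follow coordinates.
- The printed intergenic column disagrees with recomputation from the
  coordinates in places (e.g. trnQ prints 26 where coordinates give 16),
  and the printed totals (376 bp / 20 regions) differ from the
  coordinate-derived 377 bp / 22 gaps (including the 20 bp
  origin-spanning gap). Geometry is always recomputed from coordinates.
- The composition table's tRNA/rRNA skew cells are row-shifted relative
  to the running text; skews are always recomputed from the percentage
  cells, which are arithmetically consistent with the text values.
- Printed UUA/UUG RSCU values are inconsistent with their own printed
  counts; all 62 other entries reproduce to 3 dp.
- The printed stop-codon counts (94/40/72) cannot arise from 13
  terminators; sequence-derived codon counts are therefore validated on
  synthetic data only, and printed-table parity is checked from the
  printed counts themselves.

## Problem sizes

Scenario searches in tests and analyses run on 7–10-gene orders at
depth ≤ 2 with block length ≤ 7 (the regime where all-minimal
enumeration is exact and fast); the 38-gene published history is
verified by replay, not searched. The recovery analysis uses 100
seeded simulations. These sizes were chosen as the smallest at which
every claimed property is exercised non-trivially.
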