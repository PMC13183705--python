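# Methods

This note documents the model behind `igconvert`, its tunable parameters,
the synthetic-data generator, and the numerical and design choices made
where the problem left them open.

## Detection model

A gene-conversion event is observable only where the transferred donor
tract differs from the acceptor: its footprint is a *mismatch block*, a
maximal run of consecutive mismatching columns between a repertoire
sequence and its assigned functional germline in shared IMGT-gapped
coordinates. Somatic hypermutation (SHM) produces mostly isolated
single-base substitutions, so a minimum block length of 3 nt separates
candidate conversion footprints from SHM background; truly clustered SHM
can still leak through, which is why donor attribution and the gene-order
filter follow.

Block semantics are pure consecutive-mismatch runs plus an explicit
`merge_gap` (default 0): runs separated by at most `merge_gap` non-mismatch
columns merge into one block. This reproduces a 3-nt floor exactly while
letting long events assemble through merging when a user asks for it.
Ambiguity is conservative: `N` bases and gap columns never match and never
mismatch; they terminate runs unless merged across. Block `length` counts
non-gap read columns, and `read_subseq` is the read's ungapped sequence
over the block.

### Donor attribution

For a block with read subsequence *q*, every pseudogene's ungapped
sequence is scanned for the segment minimizing the unit-cost edit
(Levenshtein) distance to *q*; the best hit is kept if the distance is at
most `max_lev` (default 1). A small cap bounds false attribution while
tolerating one SHM hit or sequencing error inside a tract. The exhaustive
scan is the normative definition. It is computed with a semi-global
(free-start) DP whose rows are vectorized; candidate segments at the
optimal distance are then enumerated exactly. Blocks of at least 18 nt use
a seed-and-extend path: the query is cut into non-overlapping 8-mers, and
with at least `max_lev + 1` such seeds the q-gram pigeonhole argument
guarantees any segment within `max_lev` edits contains one seed exactly,
at a diagonal within ±`max_lev` of the segment start. The seeded path
therefore returns the same result as the exhaustive scan (and falls back
to it when the guarantee does not hold); the test suite checks the
equivalence against an independent all-substrings oracle.

Ties at equal distance break by, in order: (1) greater total flanking
identity between donor and read context (consecutive identical nt
immediately 5' plus 3' of the block, each side capped at `flank_w` = 6);
(2) smaller |donor offset − block start|; (3) lexicographic donor name;
(4) offset, then length. Rationale for (1): real conversion requires
flanking homology, so among equally distant segments the one whose
neighborhood matches the read is the more plausible template. Donor
coordinates are reported in ungapped donor space because pseudogene IMGT
gap annotations are often unreliable; acceptor/block coordinates stay
IMGT-gapped. Self-donation is impossible by construction (donors are drawn
only from the pseudogene set).

### Gene-order filter

Conversion templates lie 5' of their targets in the IGH locus, so events
whose donor ranks 3' of (downstream of) the acceptor are removed. Order is
read only from the explicit gene-order table — IMGT localizer numbers do
not encode physical order reliably — with ranks increasing 5'→3' and
"upstream" meaning strictly smaller rank. Orientation flags are stored but
do not modify the filter: the filter is positional only, and whether
inverted genes deserve special treatment is left as an explicit
non-decision (the data formats carry strand so a future rule can be added
without migration). Events whose donor or acceptor lacks an order entry
are excluded and logged rather than guessed at.

## Characterization

**Flanking identity.** Walking outward from the block in the
donor-anchored alignment (acceptor position of the block start pairs with
the donor offset), the 5'/3' flank lengths count consecutive identical
acceptor/donor nucleotides. The *expanded event* extends the block by
these lengths (clamped to the sequence); its length counts non-gap
columns. The expanded event is the inferred minimal extent of the
conversion tract, since over the flanks donor and acceptor are
indistinguishable.

**AID motifs.** The four hotspot classes are WRCY, RGYW, TW and WA
(IUPAC: W = A/T, R = A/G, Y = C/T), scanned on the coding strand only —
matching how V-region hotspot columns are annotated — with a flag for
reverse-strand scanning. All overlapping occurrences are reported; `N`
never matches; scanning skips gap columns but reports gapped coordinates.
The block-to-motif distance is 0 on overlap and otherwise 1 + (nucleotides
strictly between the nearest boundaries), so an immediately adjacent motif
is at distance 1; a configuration switch (`adjacency="gap"`) counts only
the intervening nucleotides. The overlap category is *full* when a single
motif contains the block, *partial* on any intersection, else *none*; the
three categories partition all events by construction.

**Positional profile.** Over the range from the minimum event start to the
maximum event end, each position's percentage is 100 × (events containing
the position) / denominator. The denominator defaults to the number of
events (per-event inclusion frequency); a flag switches to the number of
sequences. The choice is recorded in the profile object because the
quantity is only interpretable with it.

**Non-B DNA motifs.** Seven classes are scanned with thresholds modeled on
the conventions of the standard non-B motif search tools (all
configurable): direct repeats DR (identical arms ≥ 10 nt, spacer ≤ 10),
inverted repeats IR (reverse-complement arms ≥ 6 nt, spacer ≤ 100), mirror
repeats MR (reversed arms ≥ 10 nt, spacer ≤ 100), short tandem repeats STR
(unit 1–9 nt, ≥ 3 copies, total ≥ 12 nt), G-quadruplex GQ
(`G{3,}([ACGT]{1,7}G{3,}){3,}`), Z-DNA (alternating purine–pyrimidine runs
of GC/GT/AC-type steps, ≥ 10 nt), and A-phased repeats APR (≥ 3 A-tracts
of 3–9 nt whose starts recur every 8–12 nt). Maximality semantics are
normative and mirrored by the brute-force test oracles: for DR, one
occurrence per (equality-run, arm-shift) pair, arms as long as the run
allows capped at the shift so arms never overlap, anchored at the run
start; for IR/MR, the arm-maximal occurrence per (center, spacer);
for STR, the left-maximal tandem array per unit length, deduplicated by
interval. Different classes may overlap freely.

## Repertoire-level summaries

Per-sample accounting tracks raw → preprocessed → quality-filtered →
annotated → unique → detector-positive → order-filtered counts. `%GC` is
100 × filtered / unique, where the numerator counts GC⁺ *unique sequences*
(sequences with ≥ 1 surviving event) rather than raw events — a sequence
is the unit the percentage is asserted over — with an `events_numerator`
switch for the alternative. Percentages round half-up to 2 decimals; the
Mean row is the arithmetic mean of the per-sample values (rounded the same
way) and the Total row holds column sums. The package bundles the
published per-horse pipeline counts of an eight-animal equine IGHV IgG
experiment as the reference input for this table.

The quality filter applies a Phred threshold of 30 to the merged-overlap
region of a read and 20 to the read ends. When merger metadata is absent
the overlap region defaults to the central interval `[50, len − 50)`;
this default is declared, not inferred, and configurable. Uniqueness
collapsing keys on the exact gapped sequence per sample, so IMGT gaps are
part of identity.

## The synthetic-data generator

The simulator emulates the structure the detector targets: a small locus
(default 4 functional genes of 300 nt, 6 pseudogenes), pseudogenes derived
from functional genes at a target identity of 0.65 (the 60–68% range
observed between frequently used functional/pseudogene pairs), implant
sites consisting of a 6-nt identical 5' anchor, a divergent tract and a
1-nt identical 3' anchor (the dominant flank configuration of real
events), a 10% per-read implant probability, tract lengths of 3–30 nt
(real footprints are short-dominated), SHM at 0.01/base with a 3× rate
multiplier inside WRCY/RGYW motifs, and leaders sharing a 5–26 nt 3'
suffix between pseudogene and source.

Construction details worth recording:

* The divergence budget `(1 − identity) × length` is spent on tract
  positions first, then outside the anchor/tract islands; anchors are
  never touched, so every site satisfies the implant preconditions by
  construction. At identity 1.0 the budget is zero and pseudogenes equal
  their sources (all implants silent). Because a gapped global alignment
  recovers some matches around substitution clusters, realized
  `pairwise_identity` runs slightly above the raw substitution fraction;
  the builder iteratively adds mutations until the measured identity sits
  within ±2 percentage points of the target.
* Tract strings of ≥ 6 nt are re-randomized until they occur in exactly
  one pseudogene, making donor attribution unambiguous at edit distance 0.
  Trinucleotide tracts recur by chance in any realistic locus; their
  attribution rests on the flank tie-breaks, which is the realistic
  regime.
* Silent conversions (donor segment = acceptor segment) are generated and
  recorded but are invisible to any mismatch-based detector; recovery
  metrics exclude them from the sensitivity denominator and report their
  count separately.
* One `numpy` generator seeded by a single integer drives every stochastic
  step; identical (config, seed) gives byte-identical outputs.

What the simulator does **not** emulate: V(D)J junctional diversity,
clonal lineage structure, indel SHM, quality-correlated sequencing error,
allelic variation. Passing recovery tests therefore demonstrates the
correctness of the detection machinery under the stated generative model,
not the end-to-end error rate on real repertoires, where annotation error
and junctional trimming add failure modes outside this package's scope.

Recovery scoring: a truth record is recovered when some filtered event on
the same read overlaps its tract by ≥ 1 nt; precision is the fraction of
events overlapping some truth record; donor accuracy the fraction of
recovered records whose overlapping event names the true donor.

## Numerical choices

* **Pairwise identity** uses a global affine-gap alignment (match +1,
  mismatch 0, gap open −2 for the first base, −1 per extension) over
  ungapped sequences, with identity = matched columns / alignment columns.
  Because co-optimal alignments can differ in match count, the value is
  pinned down lexicographically: the optimal-score alignment with the most
  matches, then the fewest columns. All three components are additive
  along an alignment path, so the Gotoh recursion remains valid over this
  total order; the implementation packs the triple into one `int64` per
  cell with radix weights sized from the sequence lengths, letting each DP
  row run as vector operations (the within-row affine-gap dependency is
  closed out by a prefix-maximum scan in a gap-extension-shifted domain).
  The result is deterministic and traceback-free.
* **Edit distances** are delegated to `edlib`; empty-string edge cases are
  handled explicitly.
* **Rounding** of percentages is half-up (via `decimal`) to avoid
  banker's-rounding surprises in table cells.
* Degenerate inputs fail loudly and specifically: empty functional sets,
  duplicate germline records, quality/sequence length mismatches (per-read
  rejection, not abort), missing order entries (exclusion with logging),
  zero-unique accounting rows, unsatisfiable simulator identity targets.

## Problem sizes in tests and the acceptance script

The test-suite simulations use 200–1000 reads over the default 4 + 6 gene
locus, sizes at which every recovery property the generator guarantees is
already expressed; the acceptance script uses 1000 reads for the recovery
and GC⁺-fraction runs and 300 for the downstream-donor run. Oracle
equivalence runs on 1000 random pairs (edit distance), 200 donor-search
cases, 1000 sequences of 350 nt (AID scan) and 100 sequences of 300 nt
(direct repeats). Uniform random DNA almost never contains two identical
10-mers, so half of the direct-repeat comparison sequences carry planted
repeats with randomized arms, spacers and positions; without planting, the
comparison would be between empty sets.

## Known limitations

* Detection operates on V regions only; D/J segments and light chains are
  untested (nothing structural precludes them).
* `max_lev` > 2 makes the pigeonhole guarantee of the seeded search
  lapse for mid-length blocks; the code then silently uses the exhaustive
  scan, which is correct but slower.
* The gene-order filter needs donors present in the order table; donors
  absent from it are dropped rather than passed through, biasing %GC
  downward if the table is incomplete.
* Flanking identity is computed on the substitution-aligned donor anchor;
  donors hit with an indel (`lev` counts insertions/deletions) shift the
  3' anchor by the length difference, which the implementation respects
  but which makes flank lengths less interpretable at `max_lev` > 1.
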