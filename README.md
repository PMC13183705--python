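# igconvert

Detection and characterization of **gene-conversion events in IGHV antibody
repertoires**.

In species with restricted V-gene usage — horses being a striking case, with
pseudogenes outnumbering functional IGHV genes roughly three to one —
antibody diversity can be generated by *gene conversion*: non-reciprocal
transfer of a sequence tract from a donor pseudogene into a rearranged
functional V gene (the acceptor). `igconvert` finds the footprints of such
events in bulk BCR repertoire data and characterizes the sequence context
they occur in. It is aimed at immunogenetics researchers working with
AIRR-style annotated repertoires and an IMGT-gapped germline reference.

## The method

For each unique productive repertoire sequence aligned to its assigned
functional germline gene *F* (shared IMGT-gapped coordinates):

1. **Mismatch blocks.** Extract maximal runs of ≥ `min_block_len` (default 3)
   consecutive mismatching columns. `N` and gap columns are neutral; runs
   separated by ≤ `merge_gap` columns merge.
2. **Donor attribution.** For each block with read subsequence *q*, scan
   every pseudogene *P* for the segment *s* minimizing the Levenshtein
   distance `lev(q, s)`; keep the hit if `lev ≤ max_lev` (default 1). Ties
   break on flanking identity with the read context, donor-offset proximity,
   then donor name. Blocks ≥ 18 nt use an exact 8-mer seed-and-extend search
   whose result provably equals the exhaustive scan.
3. **Gene-order filter.** Conversion templates lie 5′ of their targets, so
   events whose donor ranks 3′ of the acceptor in the locus order table are
   discarded.
4. **Characterization.** Each surviving event is annotated with the 5′/3′
   flanking-identity lengths between acceptor and donor (the *expanded
   event* interval they imply), the distance to the nearest AID hotspot
   motif (WRCY / RGYW / TW / WA; an adjacent motif is at distance 1), the
   full/partial/none hotspot-overlap category, and non-B DNA motif context
   (direct/inverted/mirror repeats, STRs, G-quadruplex, Z-DNA, A-phased
   repeats).
5. **Summaries.** Per-sample accounting with
   `%GC = 100 · GC⁺ unique sequences / unique sequences`, family and gene
   usage, the donor→acceptor event matrix, positional event percentages and
   FASTA export of the 10-nt windows flanking expanded events for external
   motif discovery.

A built-in simulator (`igconvert.simulate`) generates toy loci and
repertoires with implanted tracts, AID-biased somatic hypermutation and a
ground-truth table, so the whole pipeline is testable offline.

## Worked example

```python
import igconvert as ig
from igconvert.simulate import SimulationConfig, simulate_repertoire

cfg = SimulationConfig(n_reads=1000, seed=42)   # 10% implant rate, 1% SHM
gset, reads, truth = simulate_repertoire(cfg)
unique = ig.collapse_unique(reads)
detected = ig.detect_repertoire(unique, gset, apply_order_filter=False)
filtered = ig.gene_order_filter(detected, gset.order)
ig.characterize_events(filtered, gset, {r.read_id: r for r in unique})
m = ig.evaluate_recovery(truth, filtered)
```

prints (via the obvious `print` statements):

```
reads: 1000  unique: 995  implants: 88
events detected: 96  after order filter: 95
GC+ unique sequences: 89 (8.94%)
sensitivity: 1.000  precision: 0.989  donor accuracy: 1.000
example event: read read00061: acceptor IGHV3-F3 block [19,49) donor IGHV3-P3@19
  lev 0 flanks (6,1) expanded [13,50) aid_dist 0 overlap partial
```

Reading: of 995 unique sequences, 89 (8.94%) carry at least one surviving
event — close to the 10% implant rate, the shortfall being implants lost to
SHM and collapsing. Every implanted tract was recovered (`sensitivity 1.0`)
and attributed to its true donor; one detected event was an SHM artifact
(`precision 0.989`). The example event is a 30-nt block matching pseudogene
IGHV3-P3 exactly (`lev 0`), flanked by 6 identical nt 5′ and 1 nt 3′, so the
inferred conversion tract (the expanded event) spans 37 nt.

The same flow is available from the shell:

```bash
igconvert simulate --seed 42 --out-dir sim/
igconvert detect --germline sim/germline.fasta --order sim/order.tsv \
                 --repertoire sim/repertoire.tsv --out events.tsv
igconvert characterize --events events.tsv --germline sim/germline.fasta \
                 --order sim/order.tsv --repertoire sim/repertoire.tsv \
                 --out events.annotated.tsv
igconvert summarize --events events.annotated.tsv \
                 --repertoire sim/repertoire.tsv --out-dir report/
```

## Data formats

* **Germline FASTA**: header `name*allele|functionality` with
  functionality ∈ {F, ORF, P}; `.` allowed as IMGT gap.
* **Gene-order table**: TSV `gene_name  position  [strand]`; ranks increase
  5′→3′.
* **Repertoire / event tables**: AIRR-style TSV (`sequence_id`, `sequence`,
  `v_call`, `productive`, `duplicate_count`); event tables add
  `gc_`-prefixed columns (block and donor coordinates, flanks, expanded
  interval, AID annotations). Block coordinates are IMGT-gapped acceptor
  coordinates; `gc_donor_offset` is in ungapped donor coordinates.
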