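"""Core gene-conversion detector.

A candidate gene-conversion event is a maximal contiguous run of mismatches
between a repertoire V-region sequence and its assigned functional germline
gene (a *mismatch block*), attributed to a pseudogene *donor* whose sequence
contains a segment within a small edit distance of the block. Events whose
donor lies 3' (downstream) of the acceptor in the locus are discarded by the
gene-order filter, because conversion templates sit 5' of their targets.

Coordinate conventions:

* block ``start``/``end`` are 0-based half-open intervals in the shared
  IMGT-gapped coordinates of read and acceptor;
* ``donor_offset`` is 0-based in the donor's **ungapped** sequence
  (pseudogenes may lack reliable IMGT gaps);
* block ``length`` counts non-gap read columns.

'N' bases and '.' gap columns are neutral: they never mismatch, never
match, and therefore terminate mismatch runs (unless ``merge_gap`` absorbs
them). This avoids fabricating events from ambiguous base calls.

The donor search is normatively an exhaustive scan over every segment of
every pseudogene; for long blocks a seed-and-extend path (exact 8-mer
seeds, pigeonhole-complete for the configured edit cap) produces the
identical result faster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from .germline import GAP_CHAR, GeneOrderTable, GermlineGene, GermlineSet
from .repertoire import AnnotatedRead

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable knobs of the detector (defaults are the analysis conditions)."""

    min_block_len: int = 3      # shortest reported mismatch block (nt)
    merge_gap: int = 0          # mismatch runs separated by <= this many columns merge
    max_lev: int = 1            # maximum edit distance to a donor segment
    flank_w: int = 6            # flank window width for donor tie-breaking (nt)
    seed_len: int = 8           # exact-seed length of the seeded donor search
    seeded_min_block: int = 18  # blocks at least this long use the seeded path


@dataclass(frozen=True)
class MismatchBlock:
    """Maximal run of read-vs-germline mismatches in shared gapped coordinates."""

    start: int
    end: int
    length: int
    read_subseq: str


@dataclass(frozen=True)
class DonorHit:
    """Best-matching pseudogene segment for one mismatch block."""

    donor_name: str
    donor_offset: int
    donor_length: int
    lev_distance: int


@dataclass
class ConversionEvent:
    """A donor-attributed mismatch block with its characterization fields."""

    read_id: str
    sample_id: str
    acceptor: str          # functional gene name (no allele)
    v_call: str            # the read's full v_call
    block: MismatchBlock
    donor: DonorHit
    passed_order_filter: bool = False
    five_prime_identical_len: int | None = None
    three_prime_identical_len: int | None = None
    expanded_start: int | None = None
    expanded_end: int | None = None
    aid_distance: int | None = None
    hotspot_overlap: str | None = None  # 'full' | 'partial' | 'none'
    extra: dict = field(default_factory=dict)

    # -- table round-trip --------------------------------------------------

    def to_row(self) -> dict:
        row = {
            "sequence_id": self.read_id,
            "sample_id": self.sample_id,
            "v_call": self.v_call,
            "gc_donor": self.donor.donor_name,
            "gc_block_start": self.block.start,
            "gc_block_end": self.block.end,
            "gc_block_length": self.block.length,
            "gc_read_subseq": self.block.read_subseq,
            "gc_donor_offset": self.donor.donor_offset,
            "gc_donor_length": self.donor.donor_length,
            "gc_lev_distance": self.donor.lev_distance,
            "gc_passed_order_filter": self.passed_order_filter,
            "gc_five_prime_identical_len": self.five_prime_identical_len,
            "gc_three_prime_identical_len": self.three_prime_identical_len,
            "gc_expanded_start": self.expanded_start,
            "gc_expanded_end": self.expanded_end,
            "gc_aid_distance": self.aid_distance,
            "gc_hotspot_overlap": self.hotspot_overlap,
        }
        row["gc_acceptor"] = self.acceptor
        row.update(self.extra)
        return row

    @classmethod
    def from_row(cls, d: dict, extra: dict | None = None) -> "ConversionEvent":
        extra = dict(extra or {})
        acceptor = extra.pop("gc_acceptor", None) or d.get("gc_acceptor") or d["v_call"].split("*")[0]

        def opt_int(key: str) -> int | None:
            v = d.get(key, "")
            return None if v in ("", None) else int(v)

        return cls(
            read_id=d["sequence_id"],
            sample_id=d["sample_id"],
            acceptor=acceptor,
            v_call=d["v_call"],
            block=MismatchBlock(
                start=int(d["gc_block_start"]),
                end=int(d["gc_block_end"]),
                length=int(d["gc_block_length"]),
                read_subseq=d["gc_read_subseq"],
            ),
            donor=DonorHit(
                donor_name=d["gc_donor"],
                donor_offset=int(d["gc_donor_offset"]),
                donor_length=int(d["gc_donor_length"]),
                lev_distance=int(d["gc_lev_distance"]),
            ),
            passed_order_filter=d["gc_passed_order_filter"] in ("T", "True", "true", "1", True),
            five_prime_identical_len=opt_int("gc_five_prime_identical_len"),
            three_prime_identical_len=opt_int("gc_three_prime_identical_len"),
            expanded_start=opt_int("gc_expanded_start"),
            expanded_end=opt_int("gc_expanded_end"),
            aid_distance=opt_int("gc_aid_distance"),
            hotspot_overlap=d.get("gc_hotspot_overlap") or None,
            extra=extra,
        )


# ---------------------------------------------------------------------------
# Edit distance
# ---------------------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution, insertion, deletion)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b)["editDistance"]


# ---------------------------------------------------------------------------
# Mismatch-block extraction
# ---------------------------------------------------------------------------

def ungapped_index(gapped_seq: str, gapped_pos: int) -> int:
    """Number of non-gap characters strictly before ``gapped_pos``."""
    return gapped_pos - gapped_seq.count(GAP_CHAR, 0, gapped_pos)


def extract_mismatch_blocks(
    read: AnnotatedRead,
    germ: GermlineGene,
    min_block_len: int = 3,
    merge_gap: int = 0,
) -> list[MismatchBlock]:
    """Maximal runs of consecutive mismatching columns between read and germline.

    Runs separated by at most ``merge_gap`` non-mismatch columns merge into a
    single block; blocks whose non-gap length is below ``min_block_len`` are
    discarded. Columns where either sequence holds '.' or 'N' are neutral.
    """
    r, g = read.gapped_seq, germ.gapped_seq
    if len(r) != len(g):
        raise ValueError(
            f"read {read.read_id}: length {len(r)} does not match germline "
            f"{germ.label} length {len(g)} in shared gapped coordinates"
        )
    # mismatch column: both bases unambiguous and different
    mism = [
        (rc in NUCLEOTIDES and gc in NUCLEOTIDES and rc != gc)
        for rc, gc in zip(r, g)
    ]
    runs: list[list[int]] = []  # [start, end) pairs, mutable for merging
    i = 0
    n = len(mism)
    while i < n:
        if mism[i]:
            j = i
            while j < n and mism[j]:
                j += 1
            if runs and i - runs[-1][1] <= merge_gap:
                runs[-1][1] = j
            else:
                runs.append([i, j])
            i = j
        else:
            i += 1
    blocks = []
    for start, end in runs:
        segment = r[start:end]
        subseq = segment.replace(GAP_CHAR, "")
        length = len(subseq)
        if length >= min_block_len:
            blocks.append(MismatchBlock(start=start, end=end, length=length, read_subseq=subseq))
    return blocks


# ---------------------------------------------------------------------------
# Donor search
# ---------------------------------------------------------------------------

def _sellers_end_distances(query: str, target: str) -> np.ndarray:
    """Minimum edit distance of ``query`` to any target substring ending at j.

    Semi-global DP (free start in the target), row-vectorized; the in-row
    insertion dependency is resolved with a prefix-minimum scan.
    """
    t = np.frombuffer(target.encode("ascii"), dtype=np.uint8)
    width = len(target) + 1
    idx = np.arange(width, dtype=np.int32)
    prev = np.zeros(width, dtype=np.int32)
    cand = np.empty(width, dtype=np.int32)
    for ch in query:
        cost = (t != ord(ch)).astype(np.int32)
        cand[0] = prev[0] + 1
        np.minimum(prev[1:] + 1, prev[:-1] + cost, out=cand[1:])
        prev = np.minimum.accumulate(cand - idx) + idx
    return prev


def _minimal_segments(query: str, target: str, max_lev: int) -> list[tuple[int, int, int]]:
    """All (offset, length, dist) with minimal dist <= max_lev, exhaustively."""
    m = len(query)
    dist_by_end = _sellers_end_distances(query, target)
    dmin = int(dist_by_end[1:].min()) if len(target) else m
    if dmin > max_lev:
        return []
    hits: list[tuple[int, int, int]] = []
    for j in np.flatnonzero(dist_by_end[1:] == dmin) + 1:
        j = int(j)
        for length in range(max(1, m - dmin), m + dmin + 1):
            o = j - length
            if o < 0:
                continue
            if levenshtein(query, target[o:j]) == dmin:
                hits.append((o, length, dmin))
    return hits


def _seeded_segments(
    query: str, target: str, max_lev: int, seed_len: int
) -> list[tuple[int, int, int]]:
    """Seed-and-extend donor scan; identical result to the exhaustive scan.

    Completeness: with edit distance <= max_lev and at least max_lev + 1
    disjoint ``seed_len``-mers in the query, one seed occurs exactly in the
    target at a diagonal within +/- max_lev of the segment start (pigeonhole
    q-gram argument). Falls back to the exhaustive scan when the guarantee
    does not hold.
    """
    m = len(query)
    n_seeds = m // seed_len
    if n_seeds < max_lev + 1:
        return _minimal_segments(query, target, max_lev)
    offsets: set[int] = set()
    for si in range(n_seeds):
        qpos = si * seed_len
        seed = query[qpos : qpos + seed_len]
        found = target.find(seed)
        while found >= 0:
            base = found - qpos
            for delta in range(-max_lev, max_lev + 1):
                offsets.add(base + delta)
            found = target.find(seed, found + 1)
    hits: list[tuple[int, int, int]] = []
    best = max_lev + 1
    for o in sorted(offsets):
        for length in range(max(1, m - max_lev), m + max_lev + 1):
            if o < 0 or o + length > len(target):
                continue
            d = levenshtein(query, target[o : o + length])
            if d < best:
                best = d
                hits = [(o, length, d)]
            elif d == best:
                hits.append((o, length, d))
    return hits if best <= max_lev else []


def _flank_identity_score(
    read_ungapped: str, r5: int, r3: int, donor_seq: str, offset: int, length: int, flank_w: int
) -> int:
    """Consecutive identical nt immediately 5' + 3' of the block vs the donor
    segment context, each side capped at ``flank_w``."""
    score = 0
    k = 0
    while k < flank_w and r5 - 1 - k >= 0 and offset - 1 - k >= 0:
        if read_ungapped[r5 - 1 - k] != donor_seq[offset - 1 - k]:
            break
        k += 1
    score += k
    k = 0
    dend = offset + length
    while k < flank_w and r3 + k < len(read_ungapped) and dend + k < len(donor_seq):
        if read_ungapped[r3 + k] != donor_seq[dend + k]:
            break
        k += 1
    score += k
    return score


def search_donor(
    block: MismatchBlock,
    read: AnnotatedRead,
    pseudos: Sequence[GermlineGene],
    max_lev: int = 1,
    flank_w: int = 6,
    seed_len: int = 8,
    seeded_min_block: int = 18,
    force_exhaustive: bool = False,
) -> DonorHit | None:
    """Best pseudogene segment for a mismatch block, or None.

    Scans every pseudogene's ungapped sequence for the segment minimizing
    edit distance to the block's read subsequence; returns the best hit if
    that distance is <= ``max_lev``. Ties break on (1) greater 5'+3' flank
    identity versus the read context (width ``flank_w``), (2) smaller
    ``|donor_offset - block.start|``, (3) lexicographic donor name, then
    (offset, length) for full determinism.
    """
    if not pseudos:
        raise ValueError("empty pseudogene set: no donor candidates")
    query = block.read_subseq
    read_ungapped = read.gapped_seq.replace(GAP_CHAR, "")
    r5 = ungapped_index(read.gapped_seq, block.start)
    r3 = ungapped_index(read.gapped_seq, block.end)

    use_seeded = not force_exhaustive and block.length >= seeded_min_block
    candidates: list[tuple[tuple, DonorHit]] = []
    best_dist = max_lev + 1
    for gene in pseudos:
        target = gene.ungapped_seq
        if use_seeded:
            segs = _seeded_segments(query, target, max_lev, seed_len)
        else:
            segs = _minimal_segments(query, target, max_lev)
        for o, length, d in segs:
            if d > best_dist:
                continue
            best_dist = min(best_dist, d)
            flank = _flank_identity_score(read_ungapped, r5, r3, target, o, length, flank_w)
            key = (d, -flank, abs(o - block.start), gene.name, o, length)
            candidates.append((key, DonorHit(gene.name, o, length, d)))
    if not candidates:
        return None
    candidates = [(k, h) for k, h in candidates if h.lev_distance == best_dist]
    candidates.sort(key=lambda kh: kh[0])
    return candidates[0][1]


# ---------------------------------------------------------------------------
# Event detection and the gene-order filter
# ---------------------------------------------------------------------------

def detect_events(
    read: AnnotatedRead, gset: GermlineSet, config: DetectionConfig = DetectionConfig()
) -> list[ConversionEvent]:
    """Mismatch blocks of one read attributed to pseudogene donors.

    Blocks with no donor segment within ``config.max_lev`` are dropped; the
    result is one event per (block, best donor). Detection ignores
    ``duplicate_count`` entirely.
    """
    germ = gset.by_label(read.v_call)
    if germ.name not in gset.functional_names:
        raise ValueError(f"read {read.read_id}: v_call {read.v_call!r} is not a functional gene")
    pseudos = gset.pseudogenes()
    blocks = extract_mismatch_blocks(read, germ, config.min_block_len, config.merge_gap)
    events = []
    for block in blocks:
        hit = search_donor(
            block, read, pseudos,
            max_lev=config.max_lev, flank_w=config.flank_w,
            seed_len=config.seed_len, seeded_min_block=config.seeded_min_block,
        )
        if hit is None:
            continue
        events.append(
            ConversionEvent(
                read_id=read.read_id,
                sample_id=read.sample_id,
                acceptor=germ.name,
                v_call=read.v_call,
                block=block,
                donor=hit,
            )
        )
    return events


def gene_order_filter(
    events: Iterable[ConversionEvent], order: GeneOrderTable
) -> list[ConversionEvent]:
    """Keep exactly the events whose donor is 5' (smaller rank) of the acceptor.

    Events with a donor or acceptor missing from the order table are excluded
    and logged. Idempotent: surviving events all satisfy the rank test.
    """
    kept = []
    n_removed = 0
    for ev in events:
        if ev.donor.donor_name not in order or ev.acceptor not in order:
            logger.warning(
                "gene_order_filter: %s -> %s lacks an order entry; event on %s excluded",
                ev.donor.donor_name, ev.acceptor, ev.read_id,
            )
            n_removed += 1
            continue
        if order.rank(ev.donor.donor_name) < order.rank(ev.acceptor):
            ev.passed_order_filter = True
            kept.append(ev)
        else:
            n_removed += 1
    logger.info("gene_order_filter: removed %d event(s), kept %d", n_removed, len(kept))
    return kept


def detect_repertoire(
    reads: Iterable[AnnotatedRead],
    gset: GermlineSet,
    config: DetectionConfig = DetectionConfig(),
    apply_order_filter: bool = True,
) -> list[ConversionEvent]:
    """Run detection over a repertoire; optionally apply the gene-order filter."""
    events: list[ConversionEvent] = []
    for read in reads:
        events.extend(detect_events(read, gset, config))
    if apply_order_filter:
        events = gene_order_filter(events, gset.order)
    return events
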