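"""Event characterization: flanking identity, AID motifs, non-B DNA context.

Detected mismatch blocks are the *visible* footprint of a conversion tract;
the true tract usually extends into flanking sequence over which donor and
acceptor are identical. This module annotates events with:

* 5'/3' flanking-identity lengths and the *expanded event* interval they
  imply;
* distance to the nearest AID hotspot motif (WRCY, RGYW, TW, WA) and the
  full/partial/no-overlap category against those motifs;
* positional event percentages across the V region;
* non-B DNA motif context (direct/inverted/mirror repeats, short tandem
  repeats, G-quadruplex, Z-DNA, A-phased repeats).

AID motifs are scanned on the coding strand only by default, matching how
hotspot columns are annotated for V regions; 'N' never matches a motif, and
gap columns are skipped while coordinates stay gapped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .detection import ConversionEvent, ungapped_index
from .germline import GAP_CHAR, GermlineGene, GermlineSet
from .repertoire import AnnotatedRead

logger = logging.getLogger(__name__)

AID_MOTIF_PATTERNS: dict[str, str] = {
    "WRCY": "[AT][AG]C[CT]",
    "RGYW": "[AG]G[CT][AT]",
    "TW": "T[AT]",
    "WA": "[AT]A",
}
AID_CLASSES = tuple(AID_MOTIF_PATTERNS)
NONB_CLASSES = ("APR", "DR", "GQ", "IR", "MR", "STR", "Z")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class MotifOccurrence:
    """One motif instance; coordinates in the event coordinate system."""

    motif_class: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"motif interval [{self.start},{self.end}) is empty")
        if self.motif_class not in AID_CLASSES + NONB_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")


@dataclass
class PositionalProfile:
    """Per-position event-inclusion percentage over [min start, max end)."""

    start: int
    end: int
    percentages: list[float]
    denominator: str  # 'events' or 'sequences', recorded in output metadata

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": range(self.start, self.end), "percentage": self.percentages}
        )


class UndefinedDistance:
    """Distinguished 'no motif on this sequence' result."""

    def __repr__(self) -> str:  # pragma: no cover
        return "UNDEFINED_DISTANCE"


UNDEFINED_DISTANCE = UndefinedDistance()


# ---------------------------------------------------------------------------
# Flanking identity and the expanded event
# ---------------------------------------------------------------------------

def flanking_identity(
    event: ConversionEvent, acceptor: GermlineGene, donor: GermlineGene
) -> tuple[int, int]:
    """Consecutive identical acceptor/donor nt immediately 5' and 3' of the block.

    The donor-anchored alignment is implied by ``donor_offset``: acceptor
    position ``block.start`` (ungapped) pairs with donor position
    ``donor_offset``. Both walks stop at the first difference or sequence
    boundary.
    """
    acc = acceptor.ungapped_seq
    don = donor.ungapped_seq
    hit = event.donor
    if not (0 <= hit.donor_offset and hit.donor_offset + hit.donor_length <= len(don)):
        raise ValueError(
            f"donor_offset {hit.donor_offset}+{hit.donor_length} outside donor {donor.label}"
        )
    a5 = ungapped_index(acceptor.gapped_seq, event.block.start)
    a3 = ungapped_index(acceptor.gapped_seq, event.block.end)
    d5 = hit.donor_offset
    d3 = hit.donor_offset + hit.donor_length

    five = 0
    while a5 - 1 - five >= 0 and d5 - 1 - five >= 0 and acc[a5 - 1 - five] == don[d5 - 1 - five]:
        five += 1
    three = 0
    while a3 + three < len(acc) and d3 + three < len(don) and acc[a3 + three] == don[d3 + three]:
        three += 1
    return five, three


def expanded_event(
    event: ConversionEvent, gapped_seq: str | None = None
) -> tuple[int, int, int]:
    """(expanded_start, expanded_end, expanded_len) from the stored flanks.

    The expanded interval extends the block by the 5'/3' flanking-identity
    lengths, clamped to the sequence; ``expanded_len`` counts non-gap columns
    when ``gapped_seq`` is supplied, plain columns otherwise.
    """
    if event.five_prime_identical_len is None or event.three_prime_identical_len is None:
        raise ValueError("flanking_identity must be computed before expanded_event")
    start = max(0, event.block.start - event.five_prime_identical_len)
    end = event.block.end + event.three_prime_identical_len
    if gapped_seq is not None:
        end = min(end, len(gapped_seq))
        length = sum(1 for c in gapped_seq[start:end] if c != GAP_CHAR)
    else:
        length = end - start
    return start, end, length


# ---------------------------------------------------------------------------
# AID hotspot motifs
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_aid_motifs(
    seq: str,
    classes: Sequence[str] = AID_CLASSES,
    both_strands: bool = False,
) -> list[MotifOccurrence]:
    """All (overlapping) AID hotspot motif occurrences in ``seq``.

    Scanning skips gap columns but reports gapped coordinates; 'N' never
    matches. With ``both_strands`` the reverse complement is scanned too and
    its matches are mapped back to forward coordinates.
    """
    seq = seq.upper()
    ungapped = []
    gapped_pos = []
    for i, c in enumerate(seq):
        if c != GAP_CHAR:
            ungapped.append(c)
            gapped_pos.append(i)
    text = "".join(ungapped)
    occ: list[MotifOccurrence] = []

    def scan(t: str, mapper) -> None:
        for cls in classes:
            pat = re.compile(f"(?=({AID_MOTIF_PATTERNS[cls]}))")
            for m in pat.finditer(t):
                s, e = m.start(1), m.end(1)
                occ.append(MotifOccurrence(cls, *mapper(s, e)))

    def fwd(s: int, e: int) -> tuple[int, int]:
        return gapped_pos[s], gapped_pos[e - 1] + 1

    scan(text, fwd)
    if both_strands:
        n = len(text)
        scan(_revcomp(text), lambda s, e: fwd(n - e, n - s))
    occ.sort(key=lambda o: (o.start, o.end, o.motif_class))
    return occ


def nearest_aid_distance(
    event: ConversionEvent,
    motifs: Sequence[MotifOccurrence],
    adjacency: str = "plus_one",
):
    """Distance (nt) from the block to the nearest motif.

    0 when a motif overlaps the block; an immediately adjacent motif gives 1
    (``adjacency='plus_one'``, the default convention: 1 + nucleotides
    strictly between the nearest boundaries). ``adjacency='gap'`` counts only
    the intervening nucleotides. Returns :data:`UNDEFINED_DISTANCE` when no
    motif exists.
    """
    if not motifs:
        return UNDEFINED_DISTANCE
    bs, be = event.block.start, event.block.end
    best: int | None = None
    for m in motifs:
        if m.start < be and bs < m.end:
            return 0
        gap = (bs - m.end) if m.end <= bs else (m.start - be)
        best = gap if best is None else min(best, gap)
    assert best is not None
    return best + 1 if adjacency == "plus_one" else best


def hotspot_overlap_category(
    event: ConversionEvent, hotspots: Sequence[MotifOccurrence]
) -> str:
    """'full' if some hotspot contains the block, else 'partial' on any
    intersection, else 'none'. The three categories partition all events."""
    bs, be = event.block.start, event.block.end
    partial = False
    for h in hotspots:
        if h.start <= bs and be <= h.end:
            return "full"
        if h.start < be and bs < h.end:
            partial = True
    return "partial" if partial else "none"


# ---------------------------------------------------------------------------
# Positional event percentages
# ---------------------------------------------------------------------------

def positional_event_percentage(
    events: Sequence[ConversionEvent],
    n_sequences: int | None = None,
    denominator: str = "events",
) -> PositionalProfile:
    """How often each position in [min start, max end) lies inside an event.

    The default denominator is the number of events (per-event inclusion
    frequency); ``denominator='sequences'`` divides by ``n_sequences``
    instead. Empty input yields an empty profile.
    """
    if denominator not in ("events", "sequences"):
        raise ValueError(f"unknown denominator {denominator!r}")
    if not events:
        return PositionalProfile(0, 0, [], denominator)
    if denominator == "sequences":
        if n_sequences is None or n_sequences < 1:
            raise ValueError("denominator='sequences' requires n_sequences >= 1")
        denom = n_sequences
    else:
        denom = len(events)
    lo = min(e.block.start for e in events)
    hi = max(e.block.end for e in events)
    counts = [0] * (hi - lo)
    for e in events:
        for p in range(e.block.start, e.block.end):
            counts[p - lo] += 1
    return PositionalProfile(lo, hi, [100.0 * c / denom for c in counts], denominator)


# ---------------------------------------------------------------------------
# Non-B DNA motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NonBParams:
    """Thresholds of the non-B motif scanner (scanner-convention defaults)."""

    dr_arm_min: int = 10
    dr_spacer_max: int = 10
    ir_arm_min: int = 6
    ir_spacer_max: int = 100
    mr_arm_min: int = 10
    mr_spacer_max: int = 100
    str_min_total: int = 12
    str_unit_max: int = 9
    str_min_copies: int = 3
    z_min: int = 10
    apr_tract_min: int = 3
    apr_tract_max: int = 9
    apr_min_tracts: int = 3
    apr_period: tuple[int, int] = (8, 12)  # allowed start-to-start spacing

    def validate(self) -> None:
        for name in ("dr_arm_min", "ir_arm_min", "mr_arm_min"):
            if getattr(self, name) < 3:
                raise ValueError(f"{name} must be >= 3, got {getattr(self, name)}")
        if self.str_min_copies < 2 or self.str_unit_max < 1 or self.z_min < 2:
            raise ValueError("invalid STR/Z parameters")


def _scan_direct_repeats(seq: str, arm_min: int, spacer_max: int) -> list[MotifOccurrence]:
    """Maximal direct repeats: two identical arms >= arm_min, spacer <= spacer_max.

    For every arm shift d (= arm length + spacer) each maximal equality run of
    seq against itself shifted by d yields at most one occurrence: arms as
    long as the run allows (capped at d so the arms do not overlap), anchored
    at the run start.
    """
    n = len(seq)
    occ = []
    for d in range(arm_min, n - arm_min + 1):
        i = 0
        limit = n - d
        while i < limit:
            if seq[i] == seq[i + d]:
                j = i
                while j < limit and seq[j] == seq[j + d]:
                    j += 1
                run = j - i
                arm = min(run, d)
                spacer = d - arm
                if arm >= arm_min and spacer <= spacer_max:
                    occ.append(MotifOccurrence("DR", i, i + d + arm))
                i = j
            else:
                i += 1
    return occ


def _scan_symmetric_repeats(
    seq: str, cls: str, arm_min: int, spacer_max: int, mirror: bool
) -> list[MotifOccurrence]:
    """Inverted (reverse-complement arms) or mirror (reversed arms) repeats.

    Arms extend outward from every possible center gap; each (center, spacer)
    contributes its arm-maximal occurrence when the arms reach ``arm_min``.
    """
    n = len(seq)
    comp = _COMPLEMENT
    seen: set[tuple[int, int]] = set()
    for c1 in range(1, n):
        for spacer in range(0, min(spacer_max, n - c1) + 1):
            c2 = c1 + spacer
            k = 0
            while c1 - 1 - k >= 0 and c2 + k < n:
                left = seq[c1 - 1 - k]
                right = seq[c2 + k]
                if mirror:
                    if left != right or left == "N":
                        break
                else:
                    if left == "N" or right == "N" or left != right.translate(comp):
                        break
                k += 1
            if k >= arm_min:
                seen.add((c1 - k, c2 + k))
    return [MotifOccurrence(cls, s, e) for s, e in sorted(seen)]


def _scan_strs(seq: str, unit_max: int, min_copies: int, min_total: int) -> list[MotifOccurrence]:
    """Short tandem repeats: unit 1..unit_max, >= min_copies copies, total >= min_total."""
    n = len(seq)
    found: dict[tuple[int, int], int] = {}  # interval -> smallest unit
    for u in range(1, unit_max + 1):
        i = 0
        limit = n - u
        while i < limit:
            if seq[i] == seq[i + u]:
                j = i
                while j < limit and seq[j] == seq[j + u]:
                    j += 1
                total = (j - i) + u
                copies = total // u
                if copies >= min_copies and total >= min_total:
                    key = (i, i + total)
                    found.setdefault(key, u)
                i = j
            else:
                i += 1
    return [MotifOccurrence("STR", s, e) for (s, e) in sorted(found)]


_GQ_RE = re.compile(r"G{3,}(?:[ACGT]{1,7}G{3,}){3,}")
_Z_STEPS = frozenset({"GC", "CG", "GT", "TG", "AC", "CA"})


def _scan_gq(seq: str) -> list[MotifOccurrence]:
    """G-quadruplex-forming repeats: four G-tracts (>=3 G) with 1-7 nt loops."""
    return [MotifOccurrence("GQ", m.start(), m.end()) for m in _GQ_RE.finditer(seq)]


def _scan_z(seq: str, z_min: int) -> list[MotifOccurrence]:
    """Z-DNA motifs: maximal alternating purine-pyrimidine runs built from
    GC/GT/AC steps (AT steps excluded), length >= z_min."""
    n = len(seq)
    occ = []
    i = 0
    while i < n - 1:
        if seq[i : i + 2] in _Z_STEPS:
            j = i
            while j < n - 1 and seq[j : j + 2] in _Z_STEPS:
                j += 1
            if j + 1 - i >= z_min:
                occ.append(MotifOccurrence("Z", i, j + 1))
            i = j + 1
        else:
            i += 1
    return occ


def _scan_apr(
    seq: str, tract_min: int, tract_max: int, min_tracts: int, period: tuple[int, int]
) -> list[MotifOccurrence]:
    """A-phased repeats: >= min_tracts A-tracts of tract_min..tract_max nt whose
    starts recur with ~10 nt periodicity."""
    tracts = [
        (m.start(), m.end())
        for m in re.finditer("A+", seq)
        if tract_min <= m.end() - m.start() <= tract_max
    ]
    occ = []
    i = 0
    while i < len(tracts):
        chain = [tracts[i]]
        j = i
        while j + 1 < len(tracts) and period[0] <= tracts[j + 1][0] - tracts[j][0] <= period[1]:
            chain.append(tracts[j + 1])
            j += 1
        if len(chain) >= min_tracts:
            occ.append(MotifOccurrence("APR", chain[0][0], chain[-1][1]))
        i = j + 1
    return occ


def scan_nonb_motifs(seq: str, params: NonBParams = NonBParams()) -> list[MotifOccurrence]:
    """All non-B DNA motif occurrences of the seven classes in ``seq``.

    Occurrences are maximal within each class; different classes may overlap
    freely. Coordinates are positions in ``seq`` as given.
    """
    params.validate()
    seq = seq.upper().replace(GAP_CHAR, "")
    occ: list[MotifOccurrence] = []
    occ += _scan_apr(seq, params.apr_tract_min, params.apr_tract_max, params.apr_min_tracts, params.apr_period)
    occ += _scan_direct_repeats(seq, params.dr_arm_min, params.dr_spacer_max)
    occ += _scan_gq(seq)
    occ += _scan_symmetric_repeats(seq, "IR", params.ir_arm_min, params.ir_spacer_max, mirror=False)
    occ += _scan_symmetric_repeats(seq, "MR", params.mr_arm_min, params.mr_spacer_max, mirror=True)
    occ += _scan_strs(seq, params.str_unit_max, params.str_min_copies, params.str_min_total)
    occ += _scan_z(seq, params.z_min)
    occ.sort(key=lambda o: (o.start, o.end, o.motif_class))
    return occ


def motif_offsets(
    events: Sequence[ConversionEvent], motifs: Sequence[MotifOccurrence]
) -> list[int]:
    """Signed motif-start minus block-start offsets for histogramming."""
    return [m.start - e.block.start for e in events for m in motifs]


# ---------------------------------------------------------------------------
# Whole-event annotation
# ---------------------------------------------------------------------------

def characterize_events(
    events: Iterable[ConversionEvent],
    gset: GermlineSet,
    reads_by_id: Mapping[str, AnnotatedRead],
    adjacency: str = "plus_one",
) -> list[ConversionEvent]:
    """Fill flank/expanded/AID fields on events in place and return them.

    AID motifs are scanned on each event's read sequence, so distances and
    overlap categories share the event coordinate system.
    """
    events = list(events)
    donors: dict[str, GermlineGene] = {}
    for g in gset.pseudogenes():
        donors.setdefault(g.name, g)
    motif_cache: dict[str, list[MotifOccurrence]] = {}
    for ev in events:
        acceptor = gset.by_label(ev.v_call)
        donor = donors[ev.donor.donor_name]
        five, three = flanking_identity(ev, acceptor, donor)
        ev.five_prime_identical_len = five
        ev.three_prime_identical_len = three
        read = reads_by_id[ev.read_id]
        ev.expanded_start, ev.expanded_end, _ = expanded_event(ev, read.gapped_seq)
        if read.read_id not in motif_cache:
            motif_cache[read.read_id] = scan_aid_motifs(read.gapped_seq)
        motifs = motif_cache[read.read_id]
        dist = nearest_aid_distance(ev, motifs, adjacency=adjacency)
        ev.aid_distance = None if isinstance(dist, UndefinedDistance) else dist
        ev.hotspot_overlap = hotspot_overlap_category(ev, motifs)
    return events
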