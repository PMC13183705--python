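"""Repertoire I/O: quality filtering, unique-sequence collapsing, AIRR tables.

The detection pipeline consumes unique annotated productive V-region
sequences. This module provides the steps that get a repertoire there:

* :func:`quality_filter` — Phred-score filter with separate thresholds for
  the merged-overlap region (default Q30) and the read ends (default Q20);
* :func:`collapse_unique` — per-sample collapsing of identical productive
  sequences with duplicate counts;
* :func:`assign_functional_gene` — best-identity V assignment, plumbing for
  synthetic reads (real data arrives pre-annotated);
* :func:`read_events` / :func:`write_events` — round-trip-stable TSV I/O for
  conversion-event tables, AIRR-style columns plus ``gc_``-prefixed fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .germline import GermlineSet, pairwise_identity

if TYPE_CHECKING:  # pragma: no cover
    from .detection import ConversionEvent

logger = logging.getLogger(__name__)

DEFAULT_OVERLAP_MIN = 30
DEFAULT_END_MIN = 20
DEFAULT_END_TRIM = 50  # default central overlap interval: [trim, len - trim)


class SchemaError(ValueError):
    """Raised when a table is missing a mandatory column."""


@dataclass(frozen=True)
class QualityRead:
    """A raw read with per-base Phred scores and an optional overlap interval."""

    read_id: str
    seq: str
    quals: tuple[int, ...]
    overlap_interval: tuple[int, int] | None = None

    def validate(self) -> None:
        if len(self.quals) != len(self.seq):
            raise ValueError(f"{self.read_id}: {len(self.quals)} quality values for {len(self.seq)} bases")
        if self.overlap_interval is not None:
            lo, hi = self.overlap_interval
            if not (0 <= lo <= hi <= len(self.seq)):
                raise ValueError(f"{self.read_id}: overlap interval {self.overlap_interval} outside read")


@dataclass(frozen=True)
class AnnotatedRead:
    """One productive V-region sequence with its assigned functional germline."""

    read_id: str
    sample_id: str
    gapped_seq: str
    v_call: str
    productive: bool = True
    duplicate_count: int = 1


def read_fastq(path: str | Path, overlap_interval: tuple[int, int] | None = None) -> Iterator[QualityRead]:
    """Stream Sanger Phred+33 FASTQ records as :class:`QualityRead`."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield QualityRead(
            read_id=rec.id,
            seq=str(rec.seq).upper(),
            quals=tuple(rec.letter_annotations["phred_quality"]),
            overlap_interval=overlap_interval,
        )


def quality_filter(
    reads: Iterable[QualityRead],
    overlap_min: int = DEFAULT_OVERLAP_MIN,
    end_min: int = DEFAULT_END_MIN,
    default_trim: int = DEFAULT_END_TRIM,
) -> Iterator[QualityRead]:
    """Yield reads whose overlap-region bases are all >= overlap_min and whose
    end bases are all >= end_min.

    Reads without an overlap interval use the central default
    ``[default_trim, len - default_trim)``. Malformed reads (quality/sequence
    length mismatch) are rejected per-read with a logged reason, never abort
    the stream. Order-preserving and idempotent.
    """
    if not (overlap_min >= end_min >= 0):
        raise ValueError(f"require overlap_min >= end_min >= 0, got {overlap_min} < {end_min}")
    n_in = n_pass = 0
    for read in reads:
        n_in += 1
        try:
            read.validate()
        except ValueError as exc:
            logger.warning("quality_filter: rejecting %s (%s)", read.read_id, exc)
            continue
        interval = read.overlap_interval
        if interval is None:
            lo = min(default_trim, len(read.seq))
            hi = max(lo, len(read.seq) - default_trim)
            interval = (lo, hi)
        lo, hi = interval
        inside_ok = all(q >= overlap_min for q in read.quals[lo:hi])
        outside_ok = all(q >= end_min for q in read.quals[:lo]) and all(
            q >= end_min for q in read.quals[hi:]
        )
        if inside_ok and outside_ok:
            n_pass += 1
            yield read
    logger.info("quality_filter: %d/%d reads passed", n_pass, n_in)


def collapse_unique(reads: Iterable[AnnotatedRead]) -> list[AnnotatedRead]:
    """Collapse productive reads to one record per (sample_id, gapped_seq).

    Non-productive records are dropped before collapsing. The surviving
    record keeps the first-seen read_id and v_call; ``duplicate_count`` sums
    the input counts. Output order follows first appearance.
    """
    collapsed: dict[tuple[str, str], AnnotatedRead] = {}
    n_productive = 0
    for read in reads:
        if not read.productive:
            continue
        n_productive += 1
        key = (read.sample_id, read.gapped_seq)
        if key in collapsed:
            prev = collapsed[key]
            collapsed[key] = replace(prev, duplicate_count=prev.duplicate_count + read.duplicate_count)
        else:
            collapsed[key] = read
    out = list(collapsed.values())
    per_sample: dict[str, int] = {}
    for r in out:
        per_sample[r.sample_id] = per_sample.get(r.sample_id, 0) + 1
    for sample, n in sorted(per_sample.items()):
        logger.info("collapse_unique: sample %s -> %d unique sequences", sample, n)
    return out


def assign_functional_gene(read_seq: str, gset: GermlineSet) -> tuple[str, float]:
    """Assign the functional germline with maximal pairwise identity.

    Deterministic tie-break: higher identity, then lexicographically smaller
    gene label. This is plumbing for synthetic reads; real repertoires come
    annotated by a dedicated V annotator.
    """
    candidates = gset.functional_genes()
    if not candidates:
        raise ValueError("empty functional gene set")
    best: tuple[float, str] | None = None
    for gene in candidates:
        ident = pairwise_identity(read_seq, gene.ungapped_seq)
        key = (-ident, gene.label)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[1], -best[0]


# ---------------------------------------------------------------------------
# AIRR-style repertoire tables
# ---------------------------------------------------------------------------

REPERTOIRE_COLUMNS = ["sequence_id", "sample_id", "sequence", "v_call", "productive", "duplicate_count"]


def write_repertoire(reads: Iterable[AnnotatedRead], path: str | Path) -> None:
    rows = [
        {
            "sequence_id": r.read_id,
            "sample_id": r.sample_id,
            "sequence": r.gapped_seq,
            "v_call": r.v_call,
            "productive": "T" if r.productive else "F",
            "duplicate_count": r.duplicate_count,
        }
        for r in reads
    ]
    pd.DataFrame(rows, columns=REPERTOIRE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_repertoire(path: str | Path) -> list[AnnotatedRead]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sequence_id", "sequence", "v_call"):
        if col not in df.columns:
            raise SchemaError(f"repertoire table {path} missing mandatory column {col!r}")
    reads = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        reads.append(
            AnnotatedRead(
                read_id=d["sequence_id"],
                sample_id=d.get("sample_id", "sample"),
                gapped_seq=d["sequence"].upper(),
                v_call=d["v_call"],
                productive=d.get("productive", "T") in ("T", "TRUE", "True", "true", "1"),
                duplicate_count=int(d.get("duplicate_count") or 1),
            )
        )
    return reads


# ---------------------------------------------------------------------------
# Conversion-event tables
# ---------------------------------------------------------------------------

# Mandatory columns of the event table; gc_-prefixed fields are this tool's.
EVENT_COLUMNS = [
    "sequence_id",
    "sample_id",
    "v_call",
    "gc_donor",
    "gc_block_start",
    "gc_block_end",
    "gc_block_length",
    "gc_read_subseq",
    "gc_donor_offset",
    "gc_donor_length",
    "gc_lev_distance",
    "gc_passed_order_filter",
    "gc_five_prime_identical_len",
    "gc_three_prime_identical_len",
    "gc_expanded_start",
    "gc_expanded_end",
    "gc_aid_distance",
    "gc_hotspot_overlap",
]

_OPTIONAL_INT_FIELDS = {
    "gc_five_prime_identical_len",
    "gc_three_prime_identical_len",
    "gc_expanded_start",
    "gc_expanded_end",
    "gc_aid_distance",
}


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "T" if value else "F"
    return str(value)


def write_events(events: Iterable["ConversionEvent"], path: str | Path) -> None:
    """Write events as TSV. Unknown columns carried in ``event.extra`` are
    appended after the standard schema, preserving round-trip stability."""
    events = list(events)
    extra_cols: list[str] = []
    for ev in events:
        for k in ev.extra:
            if k not in extra_cols:
                extra_cols.append(k)
    cols = EVENT_COLUMNS + extra_cols
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ev in events:
            row = ev.to_row()
            fh.write("\t".join(_fmt(row.get(c)) for c in cols) + "\n")


def read_events(path: str | Path) -> list["ConversionEvent"]:
    """Read an event TSV written by :func:`write_events`.

    Raises :class:`SchemaError` naming the first missing mandatory column.
    Unknown columns are preserved in ``event.extra``.
    """
    from .detection import ConversionEvent  # deferred: avoids import cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"event table {path} missing mandatory column {col!r}")
    extra_cols = [c for c in df.columns if c not in EVENT_COLUMNS]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        extra = {c: d[c] for c in extra_cols}
        out.append(ConversionEvent.from_row(d, extra=extra))
    return out
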