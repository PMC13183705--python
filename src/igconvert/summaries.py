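"""Repertoire-level summaries: pipeline accounting, usage tables, flank export.

Aggregates per-read conversion events into the tables a repertoire study
reports: per-sample pipeline accounting with the percentage of unique
sequences carrying at least one filtered event (%GC), functional-gene and
pseudogene family usage, the donor-acceptor event matrix (chord-diagram
ready), and FASTA export of the sequence windows flanking expanded events
for external motif discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .detection import ConversionEvent
from .germline import gene_family
from .repertoire import AnnotatedRead

logger = logging.getLogger(__name__)

ACCOUNTING_COLUMNS = [
    "sample_id", "n_raw", "n_preproc", "n_quality", "n_annotated",
    "n_unique", "n_detected", "n_filtered", "pct_gc",
]

# Published per-horse pipeline counts from an eight-animal equine IGHV IgG
# sequencing experiment: raw reads, pre-processed reads, Phred-filtered,
# annotated, unique productive, detector-positive, and order-filtered
# sequence counts. Bundled as the reference input for the repertoire-level
# accounting table.
EQUINE_IGHV_PIPELINE_COUNTS: list[dict] = [
    {"sample_id": "horse1", "n_raw": 94501, "n_preproc": 91830, "n_quality": 38430,
     "n_annotated": 38430, "n_unique": 33984, "n_detected": 5158, "n_filtered": 2653},
    {"sample_id": "horse2", "n_raw": 222339, "n_preproc": 216902, "n_quality": 75118,
     "n_annotated": 75118, "n_unique": 62435, "n_detected": 7379, "n_filtered": 3730},
    {"sample_id": "horse3", "n_raw": 452715, "n_preproc": 444022, "n_quality": 202685,
     "n_annotated": 202685, "n_unique": 132912, "n_detected": 16012, "n_filtered": 8042},
    {"sample_id": "horse4", "n_raw": 133538, "n_preproc": 131481, "n_quality": 57447,
     "n_annotated": 57447, "n_unique": 51791, "n_detected": 6741, "n_filtered": 3141},
    {"sample_id": "horse5", "n_raw": 210964, "n_preproc": 203754, "n_quality": 89070,
     "n_annotated": 89070, "n_unique": 65152, "n_detected": 11612, "n_filtered": 6493},
    {"sample_id": "horse6", "n_raw": 288611, "n_preproc": 278484, "n_quality": 111060,
     "n_annotated": 111060, "n_unique": 73434, "n_detected": 11591, "n_filtered": 6035},
    {"sample_id": "horse7", "n_raw": 408483, "n_preproc": 341226, "n_quality": 26064,
     "n_annotated": 26064, "n_unique": 18078, "n_detected": 2794, "n_filtered": 1342},
    {"sample_id": "horse8", "n_raw": 481150, "n_preproc": 456456, "n_quality": 154359,
     "n_annotated": 154359, "n_unique": 103354, "n_detected": 8869, "n_filtered": 3780},
]


@dataclass(frozen=True)
class SampleAccounting:
    """Per-sample pipeline counts; pct_gc = 100 x n_filtered / n_unique."""

    sample_id: str
    n_raw: int
    n_preproc: int
    n_quality: int
    n_annotated: int
    n_unique: int
    n_detected: int
    n_filtered: int
    pct_gc: float

    def __post_init__(self) -> None:
        if not (self.n_filtered <= self.n_detected <= self.n_unique <= self.n_annotated):
            raise ValueError(
                f"{self.sample_id}: counts must satisfy "
                f"filtered <= detected <= unique <= annotated, got "
                f"{self.n_filtered}/{self.n_detected}/{self.n_unique}/{self.n_annotated}"
            )


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def gc_percentage_table(per_sample_counts: Iterable[Mapping]) -> pd.DataFrame:
    """Accounting table with per-sample %GC plus Mean and Total rows.

    Each input mapping needs ``sample_id``, ``n_unique`` and ``n_filtered``;
    the remaining count columns default to 0 when absent. Per-sample
    pct_gc = 100 x n_filtered / n_unique rounded half-up to 2 decimals; the
    Mean row holds arithmetic means of the per-sample values (pct_gc rounded
    the same way); the Total row holds column sums (no percentage).
    """
    rows = []
    for rec in per_sample_counts:
        n_unique = int(rec["n_unique"])
        n_filtered = int(rec["n_filtered"])
        if n_unique == 0:
            raise ValueError(f"sample {rec.get('sample_id')!r}: n_unique is 0, %GC undefined")
        acct = SampleAccounting(
            sample_id=str(rec["sample_id"]),
            n_raw=int(rec.get("n_raw", 0)),
            n_preproc=int(rec.get("n_preproc", 0)),
            n_quality=int(rec.get("n_quality", 0)),
            n_annotated=int(rec.get("n_annotated", n_unique)),
            n_unique=n_unique,
            n_detected=int(rec.get("n_detected", n_filtered)),
            n_filtered=n_filtered,
            pct_gc=round_half_up(100.0 * n_filtered / n_unique),
        )
        rows.append(vars(acct))
    if not rows:
        raise ValueError("no samples supplied")
    df = pd.DataFrame(rows, columns=ACCOUNTING_COLUMNS)
    count_cols = ACCOUNTING_COLUMNS[1:-1]
    mean_row = {"sample_id": "Mean", **{c: df[c].mean() for c in count_cols},
                "pct_gc": round_half_up(float(df["pct_gc"].mean()))}
    total_row = {"sample_id": "Total", **{c: int(df[c].sum()) for c in count_cols},
                 "pct_gc": None}
    return pd.concat([df, pd.DataFrame([mean_row, total_row])], ignore_index=True)


def accounting_from_pipeline(
    sample_id: str,
    n_raw: int,
    n_preproc: int,
    n_quality: int,
    n_annotated: int,
    unique_reads: Sequence[AnnotatedRead],
    detected_events: Sequence[ConversionEvent],
    filtered_events: Sequence[ConversionEvent],
    events_numerator: bool = False,
) -> dict:
    """One accounting record from actual pipeline outputs.

    %GC counts GC+ unique sequences by default (sequences with at least one
    surviving event); ``events_numerator`` switches to raw event counts.
    """
    n_unique = len(unique_reads)
    n_detected = len({e.read_id for e in detected_events})
    if events_numerator:
        n_filtered = len(filtered_events)
    else:
        n_filtered = len({e.read_id for e in filtered_events})
    return {
        "sample_id": sample_id, "n_raw": n_raw, "n_preproc": n_preproc,
        "n_quality": n_quality, "n_annotated": n_annotated, "n_unique": n_unique,
        "n_detected": n_detected, "n_filtered": n_filtered,
    }


# ---------------------------------------------------------------------------
# Usage tables and the donor-acceptor matrix
# ---------------------------------------------------------------------------

def family_usage(events: Sequence[ConversionEvent]) -> dict[str, pd.DataFrame]:
    """Family- and gene-level usage frequencies, acceptors and donors apart.

    Returns four tables keyed 'acceptor_family', 'acceptor_gene',
    'donor_family', 'donor_gene', each with count and percentage columns
    summing to 100 (up to rounding).
    """
    def tabulate(names: list[str], level: str) -> pd.DataFrame:
        if not names:
            return pd.DataFrame(columns=[level, "count", "percentage"])
        keys = [gene_family(n) for n in names] if level == "family" else names
        counts = pd.Series(keys).value_counts()
        return pd.DataFrame({
            level: counts.index,
            "count": counts.values,
            "percentage": 100.0 * counts.values / counts.values.sum(),
        })

    acceptors = [e.acceptor for e in events]
    donors = [e.donor.donor_name for e in events]
    return {
        "acceptor_family": tabulate(acceptors, "family"),
        "acceptor_gene": tabulate(acceptors, "gene"),
        "donor_family": tabulate(donors, "family"),
        "donor_gene": tabulate(donors, "gene"),
    }


@dataclass
class DonorAcceptorMatrix:
    """Event counts per ordered (donor pseudogene, acceptor functional gene)."""

    counts: dict[tuple[str, str], int]

    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"donor": d, "acceptor": a, "count": c}
            for (d, a), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["donor", "acceptor", "count"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DonorAcceptorMatrix":
        return cls({(r.donor, r.acceptor): int(r.count) for r in df.itertuples(index=False)})


def donor_acceptor_matrix(events: Sequence[ConversionEvent]) -> DonorAcceptorMatrix:
    """Frequency table of pseudogene -> functional-gene combinations."""
    counts: dict[tuple[str, str], int] = {}
    for e in events:
        key = (e.donor.donor_name, e.acceptor)
        counts[key] = counts.get(key, 0) + 1
    return DonorAcceptorMatrix(counts)


# ---------------------------------------------------------------------------
# Flank-window export for external motif discovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlankWindow:
    """One flanking window of an expanded event, ready for motif discovery."""

    read_id: str
    event_index: int
    side: str  # '5p' | '3p'
    seq: str
    truncated: bool

    @property
    def fasta_id(self) -> str:
        flag = "|truncated" if self.truncated else ""
        return f"{self.read_id}|event{self.event_index}|{self.side}{flag}"


def extract_flank_windows(
    events: Sequence[ConversionEvent],
    reads_by_id: Mapping[str, AnnotatedRead],
    w: int = 10,
) -> list[FlankWindow]:
    """The ``w`` nt immediately 5' of expanded_start and 3' of expanded_end.

    Events whose expanded region starts at position 0 have no 5' window;
    windows shortened by a sequence boundary are flagged truncated.
    """
    if w < 1:
        raise ValueError(f"window width must be >= 1, got {w}")
    windows = []
    for idx, ev in enumerate(events):
        if ev.expanded_start is None or ev.expanded_end is None:
            raise ValueError(f"event {idx} on {ev.read_id} lacks expanded coordinates")
        seq = reads_by_id[ev.read_id].gapped_seq
        es, ee = ev.expanded_start, ev.expanded_end
        if es > 0:
            lo = max(0, es - w)
            windows.append(FlankWindow(ev.read_id, idx, "5p", seq[lo:es], truncated=es - w < 0))
        if ee < len(seq):
            hi = min(len(seq), ee + w)
            windows.append(FlankWindow(ev.read_id, idx, "3p", seq[ee:hi], truncated=ee + w > len(seq)))
    return windows


def write_flank_fasta(windows: Iterable[FlankWindow], path_5p: str | Path, path_3p: str | Path) -> None:
    with open(path_5p, "w") as f5, open(path_3p, "w") as f3:
        for win in windows:
            fh = f5 if win.side == "5p" else f3
            fh.write(f">{win.fasta_id}\n{win.seq}\n")
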