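"""Germline reference handling for IGHV gene-conversion analysis.

Loads sets of germline V genes (functional genes and pseudogenes) from
IMGT-gapped FASTA together with a locus gene-order table, and provides the
inter-gene sequence comparisons the rest of the pipeline builds on:

* :func:`load_germline_set` — validated :class:`GermlineSet` construction;
* :func:`upstream_pseudogenes` — pseudogenes 5' of a functional gene, the
  basis of the gene-order filter;
* :func:`pairwise_identity` — global-alignment percent identity between two
  genes (used e.g. to compare the most-used functional genes with their
  pseudogene donors);
* :func:`leader_identity_suffix` — length of the shared 3' end of two
  leader regions, evidence that conversion tracts can extend into the
  leader.

Gene order is always taken from the explicit order table, never inferred
from IMGT localizer numbers, which do not reliably encode physical order.
Ranks increase 5' -> 3' along the locus; "upstream" means strictly smaller
rank. Orientation flags are stored but do not influence the order filter.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

GAP_CHAR = "."
VALID_FUNCTIONALITY = frozenset({"F", "ORF", "P"})
_NAME_RE = re.compile(r"^(?P<family>[A-Za-z]+\d+)-(?P<localizer>[A-Za-z0-9]+)$")

# pairwise_identity scoring (fixed; see docs/methods.md)
MATCH_SCORE = 1.0
MISMATCH_SCORE = 0.0
GAP_OPEN = -2.0   # cost of the first base of a gap
GAP_EXTEND = -1.0  # cost of each subsequent base


class GermlineError(ValueError):
    """Raised for malformed or inconsistent germline inputs."""


def gene_family(name: str) -> str:
    """Family prefix of an IMGT-style gene name (``IGHV4-21`` -> ``IGHV4``)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise GermlineError(f"gene name {name!r} does not parse as <locus><family>-<localizer>")
    return m.group("family")


@dataclass(frozen=True)
class GermlineGene:
    """One reference V gene, functional (F/ORF) or pseudogene (P)."""

    name: str
    allele: str | None
    functionality: str
    gapped_seq: str
    leader_seq: str | None = None

    def __post_init__(self) -> None:
        if self.functionality not in VALID_FUNCTIONALITY:
            raise GermlineError(
                f"{self.label}: functionality {self.functionality!r} not in {sorted(VALID_FUNCTIONALITY)}"
            )
        gene_family(self.name)  # validates the name shape

    @property
    def label(self) -> str:
        return f"{self.name}{self.allele or ''}"

    @property
    def ungapped_seq(self) -> str:
        return self.gapped_seq.replace(GAP_CHAR, "")

    @property
    def family(self) -> str:
        return gene_family(self.name)

    @property
    def is_pseudogene(self) -> bool:
        return self.functionality == "P"


@dataclass
class GeneOrderTable:
    """Physical 5'->3' order of genes along the locus.

    ``entries`` maps gene name -> integer locus rank; smaller rank = more 5'.
    """

    entries: dict[str, int]
    orientation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranks = list(self.entries.values())
        if len(set(ranks)) != len(ranks):
            raise GermlineError("gene-order table has duplicated locus ranks")

    def rank(self, gene_name: str) -> int:
        try:
            return self.entries[gene_name]
        except KeyError:
            raise GermlineError(f"gene {gene_name!r} absent from the gene-order table") from None

    def __contains__(self, gene_name: str) -> bool:
        return gene_name in self.entries

    def shifted(self, k: int) -> "GeneOrderTable":
        """Copy with every rank shifted by ``k`` (order-preserving)."""
        return GeneOrderTable({g: r + k for g, r in self.entries.items()}, dict(self.orientation))


@dataclass
class GermlineSet:
    """Validated germline reference: genes, locus order, and the F/P split."""

    genes: list[GermlineGene]
    order: GeneOrderTable
    functional_names: set[str] = field(default_factory=set)
    pseudogene_names: set[str] = field(default_factory=set)
    unordered_names: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.functional_names:
            self.functional_names = {g.name for g in self.genes if g.functionality in ("F", "ORF")}
        if not self.pseudogene_names:
            self.pseudogene_names = {g.name for g in self.genes if g.is_pseudogene}
        overlap = self.functional_names & self.pseudogene_names
        if overlap:
            raise GermlineError(f"genes listed as both functional and pseudogene: {sorted(overlap)}")
        if not self.functional_names:
            raise GermlineError("empty functional gene set: nothing to detect against")
        self.unordered_names = {g.name for g in self.genes if g.name not in self.order}
        if self.unordered_names:
            logger.warning(
                "%d gene(s) absent from the order table (unusable for the order filter): %s",
                len(self.unordered_names), sorted(self.unordered_names),
            )

    # -- lookups -----------------------------------------------------------

    def functional_genes(self) -> list[GermlineGene]:
        return [g for g in self.genes if g.name in self.functional_names]

    def pseudogenes(self) -> list[GermlineGene]:
        return [g for g in self.genes if g.name in self.pseudogene_names]

    def by_label(self, v_call: str) -> GermlineGene:
        """Resolve a v_call (``name`` or ``name*allele``) to a gene record."""
        for g in self.genes:
            if g.label == v_call or g.name == v_call:
                return g
        known = sorted({g.label for g in self.genes})
        raise GermlineError(f"v_call {v_call!r} not in germline set; known: {known}")


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _parse_header(header: str) -> tuple[str, str | None, str]:
    """Parse ``name*allele|functionality`` FASTA headers."""
    parts = header.split("|")
    if len(parts) < 2:
        raise GermlineError(f"FASTA record {header!r}: expected 'name*allele|functionality' header")
    label, functionality = parts[0].strip(), parts[1].strip()
    if "*" in label:
        name, allele = label.split("*", 1)
        allele = "*" + allele
    else:
        name, allele = label, None
    return name, allele, functionality


def load_germline_set(fasta_path: str | Path, order_path: str | Path) -> GermlineSet:
    """Load and validate a germline set from FASTA + gene-order table.

    FASTA headers are ``name*allele|functionality`` with '.' permitted in the
    sequence for IMGT gaps. The order table is tab-separated with columns
    ``gene_name``, ``position`` (integer or ordinal; normalized to internal
    ranks) and optional ``strand``. Duplicate name+allele pairs are rejected;
    genes absent from the order table are retained but flagged.
    """
    genes: list[GermlineGene] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        try:
            name, allele, functionality = _parse_header(rec.description)
        except GermlineError:
            raise
        seq = str(rec.seq).upper()
        if not seq:
            raise GermlineError(f"FASTA record {rec.description!r}: empty sequence")
        bad = set(seq) - set("ACGTN.")
        if bad:
            raise GermlineError(f"FASTA record {rec.description!r}: invalid characters {sorted(bad)}")
        gene = GermlineGene(name=name, allele=allele, functionality=functionality, gapped_seq=seq)
        if gene.label in seen:
            raise GermlineError(f"duplicate germline record {gene.label!r}")
        seen.add(gene.label)
        genes.append(gene)
    if not genes:
        raise GermlineError(f"no FASTA records parsed from {fasta_path}")

    order = load_gene_order(order_path)
    return GermlineSet(genes=genes, order=order)


def load_gene_order(order_path: str | Path) -> GeneOrderTable:
    """Read a tab-separated gene-order table into a :class:`GeneOrderTable`."""
    entries: dict[str, int] = {}
    orientation: dict[str, str] = {}
    with open(order_path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None and fields[0].lower() in ("gene_name", "gene", "name"):
                header = [f.lower() for f in fields]
                continue
            if len(fields) < 2:
                raise GermlineError(f"{order_path}:{lineno}: expected at least 2 tab-separated columns")
            gene, pos = fields[0], fields[1]
            try:
                rank = int(pos)
            except ValueError:
                raise GermlineError(f"{order_path}:{lineno}: position {pos!r} is not an integer") from None
            if gene in entries:
                raise GermlineError(f"{order_path}:{lineno}: duplicate order entry for {gene!r}")
            entries[gene] = rank
            if len(fields) >= 3 and fields[2]:
                orientation[gene] = fields[2]
    if not entries:
        raise GermlineError(f"no entries parsed from gene-order table {order_path}")
    return GeneOrderTable(entries=entries, orientation=orientation)


def write_germline_set(gset: GermlineSet, fasta_path: str | Path, order_path: str | Path) -> None:
    """Serialize a GermlineSet to the FASTA + order-table formats of the loader."""
    with open(fasta_path, "w") as fh:
        for g in gset.genes:
            fh.write(f">{g.label}|{g.functionality}\n{g.gapped_seq}\n")
    with open(order_path, "w") as fh:
        fh.write("gene_name\tposition\tstrand\n")
        for gene, rank in sorted(gset.order.entries.items(), key=lambda kv: kv[1]):
            strand = gset.order.orientation.get(gene, "+")
            fh.write(f"{gene}\t{rank}\t{strand}\n")


# ---------------------------------------------------------------------------
# Locus-order queries
# ---------------------------------------------------------------------------

def upstream_pseudogenes(functional_name: str, gset: GermlineSet) -> set[str]:
    """Pseudogenes located strictly 5' of ``functional_name`` in the locus.

    Pseudogenes lacking an order entry are never returned (they are unusable
    for the order filter).
    """
    f_rank = gset.order.rank(functional_name)
    return {
        name for name in gset.pseudogene_names
        if name in gset.order and gset.order.rank(name) < f_rank
    }


# ---------------------------------------------------------------------------
# Pairwise identity (global affine-gap alignment)
# ---------------------------------------------------------------------------


# Alignment values are lexicographic (score, matches, -columns) tuples: the
# optimal-score alignment, ties broken by most matched columns, then fewest
# alignment columns. All three components are additive along a path, so the
# Gotoh recursion is valid over this total order and the resulting identity
# is fully determined (no dependence on traceback order).
_NEG_VALUE = (float("-inf"), 0, 0)


def _gotoh_value(a: str, b: str) -> tuple[float, int, int]:
    """Optimal (score, matches, -columns) of a global affine-gap alignment.

    States: H (best of all), E (gap in a: consume b), F (gap in b: consume a).
    The lexicographic value is packed into one int64 per cell
    (``A*score + B*matches - columns`` with radix weights large enough that
    higher components dominate), which lets each DP row run as numpy vector
    ops; the within-row affine-gap dependency is closed out with a
    prefix-maximum scan in a gap-extension-shifted domain.
    """
    import numpy as np

    n, m = len(a), len(b)
    B = n + m + 1                       # columns fit below one 'matches' unit
    A = B * (min(n, m) + 1) + (n + m + 1)  # matches+columns fit below one 'score' unit
    openc = int(GAP_OPEN) * A - 1       # per-column increments, packed
    extc = int(GAP_EXTEND) * A - 1
    sub_match = int(MATCH_SCORE) * A + B - 1
    sub_mis = int(MISMATCH_SCORE) * A - 1
    NEG = -(1 << 62)

    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    j1 = np.arange(1, m + 1, dtype=np.int64)
    Hprev = np.empty(m + 1, dtype=np.int64)
    Hprev[0] = 0
    Hprev[1:] = openc + (j1 - 1) * extc
    Fprev = np.full(m + 1, NEG, dtype=np.int64)
    shift = extc * np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        sub = np.where(bv == ord(a[i - 1]), sub_match, sub_mis)
        F = np.maximum(Hprev + openc, Fprev + extc)
        col0 = openc + (i - 1) * extc
        F[0] = col0
        C = np.empty(m + 1, dtype=np.int64)
        C[0] = col0
        np.maximum(Hprev[:-1] + sub, F[1:], out=C[1:])
        # horizontal gaps: in the shifted domain D = C - j*extc the row optimum
        # is H'[j] = max(D[j], (openc - extc) + max_{k<j} D[k]); gap-opening
        # cells never raise the running prefix max, so one accumulate suffices.
        D = C - shift
        P = np.maximum.accumulate(D)
        H = np.empty(m + 1, dtype=np.int64)
        H[0] = col0
        H[1:] = np.maximum(D[1:], (openc - extc) + P[:-1]) + shift[1:]
        Hprev, Fprev = H, F
    packed = int(Hprev[m]) + (n + m)    # offset so the sub-score part is >= 0
    score = packed // A
    rem = packed - A * score
    matches = rem // B
    columns = (n + m) - (rem - B * matches)
    return float(score), int(matches), -int(columns)


def pairwise_identity(a: GermlineGene | str, b: GermlineGene | str) -> float:
    """Percent identity of a global alignment of the two ungapped sequences.

    Scoring: match +1, mismatch 0, gap open -2 / extend -1 (affine; a gap of
    length k costs 2 + (k - 1)). Identity = matched columns / alignment
    columns x 100, taken from the optimal-score alignment with the most
    matches (fewest columns on further ties) -- a well-defined quantity.
    Symmetric; for substitution-only pairs it equals per-position identity.
    """
    sa = a.ungapped_seq if isinstance(a, GermlineGene) else a.replace(GAP_CHAR, "")
    sb = b.ungapped_seq if isinstance(b, GermlineGene) else b.replace(GAP_CHAR, "")
    if not sa or not sb:
        raise GermlineError("pairwise_identity requires two non-empty sequences")
    score, matches, neg_columns = _gotoh_value(sa, sb)
    return 100.0 * matches / -neg_columns


def alignment_score(a: str, b: str) -> float:
    """Optimal global affine-gap alignment score under the fixed scoring."""
    if not a or not b:
        raise GermlineError("alignment_score requires two non-empty sequences")
    return _gotoh_value(a, b)[0]



# ---------------------------------------------------------------------------
# Leader-region homology
# ---------------------------------------------------------------------------

class NoLeader:
    """Distinguished result when a gene carries no leader sequence."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NO_LEADER"


NO_LEADER = NoLeader()


def leader_identity_suffix(f: GermlineGene, p: GermlineGene):
    """Length of the longest identical 3' suffix of the two leader regions.

    The leader 3' end abuts the V region, so a shared suffix means homology
    immediately upstream of the V gene — room for a conversion tract to
    extend past the detected mismatch region. Returns :data:`NO_LEADER`
    (not 0) when either gene lacks a leader.
    """
    if f.leader_seq is None or p.leader_seq is None:
        return NO_LEADER
    la, lb = f.leader_seq, p.leader_seq
    n = 0
    while n < min(len(la), len(lb)) and la[len(la) - 1 - n] == lb[len(lb) - 1 - n]:
        n += 1
    return n
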