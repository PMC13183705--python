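"""Synthetic germline loci and repertoires with implanted conversion tracts.

Every pipeline stage is testable without downloads: this module generates a
toy V locus (functional genes plus pseudogenes at a target identity, with
seeded implant sites), a repertoire of reads carrying implanted donor
tracts and AID-hotspot-biased point mutations, the ground-truth table of
every implant, and recovery metrics for a detection run.

Implant sites are built into each pseudogene at locus-construction time: an
``anchor_5p``-nt identical flank, a tract region whose bases diverge from
the acceptor (first in line when the identity budget is spent), and an
``anchor_3p``-nt identical flank. A conversion is *silent* when the donor
tract equals the acceptor segment; silent implants are generated and
recorded but cannot be seen by any mismatch-based detector, so recovery
metrics exclude them from the sensitivity denominator and report them
separately.

A single integer seed drives one generator threaded through all stochastic
steps; identical (config, seed) gives byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .characterize import scan_aid_motifs
from .detection import ConversionEvent
from .germline import GeneOrderTable, GermlineGene, GermlineSet, pairwise_identity
from .repertoire import AnnotatedRead

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_SITE_RETRIES = 50


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic locus and repertoire."""

    n_functional: int = 4
    n_pseudo: int = 6
    v_length: int = 300
    pseudo_identity: float = 0.65      # target identity to the source functional gene
    n_reads: int = 1000
    implant_fraction: float = 0.1      # probability a read carries one tract
    tract_len_range: tuple[int, int] = (3, 30)
    anchor_5p: int = 6                 # identical flank required 5' of the tract
    anchor_3p: int = 1                 # identical flank required 3' of the tract
    shm_rate: float = 0.01             # per-base substitution probability
    hotspot_multiplier: float = 3.0    # SHM rate factor inside WRCY/RGYW
    downstream_donor_fraction: float = 0.0  # implants drawn from 3'-ranked donors
    upstream_share: float = 0.7        # chance a pseudogene sits 5' of its source
    sites_per_pseudo: int = 3
    leader_len: int = 60
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "pseudo_identity": self.pseudo_identity,
            "implant_fraction": self.implant_fraction,
            "shm_rate": self.shm_rate,
            "downstream_donor_fraction": self.downstream_donor_fraction,
            "upstream_share": self.upstream_share,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.n_functional < 1 or self.n_pseudo < 1:
            raise ValueError("need at least one functional gene and one pseudogene")
        lo, hi = self.tract_len_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid tract_len_range {self.tract_len_range}")
        if self.hotspot_multiplier < 0:
            raise ValueError("hotspot_multiplier must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "tract_len_range" in data:
            data["tract_len_range"] = tuple(data["tract_len_range"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class ImplantSite:
    """One seeded implant site of a pseudogene (coordinates shared with the
    source functional gene; substitution-only derivation keeps them aligned)."""

    tract_start: int
    tract_end: int

    @property
    def tract_len(self) -> int:
        return self.tract_end - self.tract_start


@dataclass(frozen=True)
class PseudoMeta:
    source: str             # functional gene the pseudogene derives from
    is_upstream: bool       # ranked 5' of its source in the order table
    sites: tuple[ImplantSite, ...]


@dataclass(frozen=True)
class GroundTruthRecord:
    """One implanted tract, for recovery scoring against detected events."""

    read_id: str
    acceptor: str
    donor: str
    tract_start: int
    tract_end: int
    donor_offset: int
    is_upstream_donor: bool
    silent: bool


# ---------------------------------------------------------------------------
# Locus construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    alts = [b for b in "ACGT" if b != base]
    return alts[rng.integers(0, 3)]


def _layout_sites(
    rng: np.random.Generator, cfg: SimulationConfig
) -> list[ImplantSite]:
    """Place non-overlapping implant sites (anchor + tract + anchor) along a gene."""
    lo, hi = cfg.tract_len_range
    sites = []
    cursor = int(rng.integers(5, 15))
    for _ in range(cfg.sites_per_pseudo):
        tract_len = int(rng.integers(lo, hi + 1))
        start = cursor + cfg.anchor_5p
        end = start + tract_len
        if end + cfg.anchor_3p > cfg.v_length:
            break
        sites.append(ImplantSite(start, end))
        cursor = end + cfg.anchor_3p + int(rng.integers(3, 12))
    if not sites:
        raise ValueError(
            "no implant site fits: v_length too small for anchors + tract_len_range"
        )
    return sites


def _derive_pseudogene(
    rng: np.random.Generator,
    source_seq: str,
    sites: Sequence[ImplantSite],
    cfg: SimulationConfig,
) -> str:
    """Mutate a copy of the source toward the target identity.

    The divergence budget (1 - pseudo_identity) x length is spent on tract
    positions first (making implants detectable), then on positions outside
    the anchor/tract islands. Anchors are never touched, so every site
    satisfies the implant preconditions by construction.
    """
    n = len(source_seq)
    budget = round((1.0 - cfg.pseudo_identity) * n)
    seq = list(source_seq)
    tract_positions = [p for s in sites for p in range(s.tract_start, s.tract_end)]
    island = set()
    for s in sites:
        island.update(range(s.tract_start - cfg.anchor_5p, s.tract_end + cfg.anchor_3p))
    spend_in_tracts = min(budget, len(tract_positions))
    for p in tract_positions[:spend_in_tracts]:
        seq[p] = _mutate_base(rng, source_seq[p])
    remaining = budget - spend_in_tracts
    outside = [p for p in range(n) if p not in island]
    if remaining > len(outside):
        raise ValueError(
            f"unsatisfiable identity/anchor combination: need {remaining} more "
            f"divergent positions but only {len(outside)} lie outside implant sites"
        )
    if remaining:
        chosen = rng.choice(len(outside), size=remaining, replace=False)
        for k in chosen:
            p = outside[k]
            seq[p] = _mutate_base(rng, source_seq[p])
        pool = [outside[k] for k in range(len(outside)) if k not in set(chosen)]
    else:
        pool = list(outside)
    # The gapped global alignment recovers some matches around substitution
    # clusters, so the realized pairwise identity runs a little above the raw
    # substitution fraction; keep mutating until it sits inside the +/-2pp
    # band around the target.
    target_pct = 100.0 * cfg.pseudo_identity
    for _ in range(200):
        ident = pairwise_identity("".join(seq), source_seq)
        if ident <= target_pct + 1.5:
            break
        if not pool:
            raise ValueError(
                "unsatisfiable identity/anchor combination: no positions left "
                "outside implant sites to reach the identity target"
            )
        step = max(1, min(len(pool), int((ident - target_pct) * n / 300)))
        picks = rng.choice(len(pool), size=step, replace=False)
        for k in sorted(picks, reverse=True):
            p = pool[k]
            seq[p] = _mutate_base(rng, source_seq[p])
            pool.pop(k)
    return "".join(seq)


def _build_locus(cfg: SimulationConfig, rng: np.random.Generator):
    """Construct genes, implant-site metadata and the order table."""
    cfg.validate()
    functionals: list[GermlineGene] = []
    leaders: dict[str, str] = {}
    for i in range(cfg.n_functional):
        name = f"IGHV{i + 1}-F{i + 1}"
        leaders[name] = _random_seq(rng, cfg.leader_len)
        functionals.append(
            GermlineGene(
                name=name, allele="*01", functionality="F",
                gapped_seq=_random_seq(rng, cfg.v_length),
                leader_seq=leaders[name],
            )
        )

    pseudos: list[GermlineGene] = []
    meta: dict[str, PseudoMeta] = {}
    for j in range(cfg.n_pseudo):
        src = functionals[j % cfg.n_functional]
        name = f"IGHV{(j % cfg.n_functional) + 1}-P{j + 1}"
        sites = _layout_sites(rng, cfg)
        seq = _derive_pseudogene(rng, src.gapped_seq, sites, cfg)
        # pseudogene leader: shared 3' suffix with the source, mutated elsewhere
        suffix_len = int(rng.integers(5, 27))
        src_leader = leaders[src.name]
        leader = [
            c if k >= cfg.leader_len - suffix_len else _mutate_base(rng, c)
            for k, c in enumerate(src_leader)
        ]
        is_upstream = bool(rng.random() < cfg.upstream_share)
        pseudos.append(
            GermlineGene(name=name, allele="*01", functionality="P",
                         gapped_seq=seq, leader_seq="".join(leader))
        )
        meta[name] = PseudoMeta(source=src.name, is_upstream=is_upstream, sites=tuple(sites))

    _enforce_tract_uniqueness(rng, functionals, pseudos, meta, cfg)

    # layout: each functional gene preceded by its upstream pseudogenes and
    # followed by its downstream ones; ranks increase 5' -> 3'.
    order_entries: dict[str, int] = {}
    rank = 1
    for f in functionals:
        ups = [p for p in pseudos if meta[p.name].source == f.name and meta[p.name].is_upstream]
        downs = [p for p in pseudos if meta[p.name].source == f.name and not meta[p.name].is_upstream]
        for p in ups:
            order_entries[p.name] = rank
            rank += 1
        order_entries[f.name] = rank
        rank += 1
        for p in downs:
            order_entries[p.name] = rank
            rank += 1
    order = GeneOrderTable(order_entries, {g: "+" for g in order_entries})
    gset = GermlineSet(genes=functionals + pseudos, order=order)
    return gset, meta


def _enforce_tract_uniqueness(
    rng: np.random.Generator,
    functionals: list[GermlineGene],
    pseudos: list[GermlineGene],
    meta: dict[str, PseudoMeta],
    cfg: SimulationConfig,
) -> None:
    """Re-randomize divergent tract bases whose string recurs in another
    pseudogene, so donor attribution is unambiguous for tracts >= 6 nt.
    Very short tracts (3-5 nt) recur by chance in any realistic locus and
    are left alone — attribution then rests on the flank tie-breaks."""
    sources = {f.name: f.gapped_seq for f in functionals}
    for idx, gene in enumerate(pseudos):
        m = meta[gene.name]
        seq = gene.gapped_seq
        for site in m.sites:
            if site.tract_len < 6:
                continue
            src_seq = sources[m.source]
            if seq[site.tract_start : site.tract_end] == src_seq[site.tract_start : site.tract_end]:
                continue  # fully silent site (high target identity): nothing to disambiguate
            for _ in range(_MAX_SITE_RETRIES):
                tract = seq[site.tract_start : site.tract_end]
                others = [p.gapped_seq for p in pseudos if p.name != gene.name]
                if not any(tract in other for other in others):
                    break
                new = [
                    _mutate_base(rng, src_seq[p]) if seq[p] != src_seq[p] else seq[p]
                    for p in range(site.tract_start, site.tract_end)
                ]
                seq = seq[: site.tract_start] + "".join(new) + seq[site.tract_end :]
        if seq != gene.gapped_seq:
            pseudos[idx] = replace(gene, gapped_seq=seq)


def simulate_germline_locus(config: SimulationConfig, seed: int | None = None) -> GermlineSet:
    """Generate a toy germline locus; deterministic for (config, seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gset, _ = _build_locus(config, rng)
    return gset


# ---------------------------------------------------------------------------
# Implantation and SHM
# ---------------------------------------------------------------------------

def implant_conversion(
    read_seq: str,
    acceptor: GermlineGene,
    donor: GermlineGene,
    tract: tuple[int, int],
    anchors: tuple[int, int] = (6, 1),
) -> str:
    """Replace the tract interval of an acceptor-derived read with the donor
    segment at the same (substitution-aligned) coordinates.

    Requires ``anchors[0]`` identical acceptor/donor nt immediately 5' of the
    tract and ``anchors[1]`` immediately 3'; raises when the site does not
    satisfy them (callers may relax the anchors). A donor segment identical
    to the acceptor segment yields an unchanged read (silent conversion).
    """
    start, end = tract
    a5, a3 = anchors
    acc, don = acceptor.ungapped_seq, donor.ungapped_seq
    if not (0 <= start <= end <= len(read_seq) and end <= len(don)):
        raise ValueError(f"tract {tract} outside read/donor bounds")
    if start - a5 < 0 or end + a3 > min(len(acc), len(don)):
        raise ValueError(f"anchors {anchors} do not fit around tract {tract}")
    if acc[start - a5 : start] != don[start - a5 : start]:
        raise ValueError(f"no {a5}-nt identical 5' anchor at tract {tract}")
    if acc[end : end + a3] != don[end : end + a3]:
        raise ValueError(f"no {a3}-nt identical 3' anchor at tract {tract}")
    return read_seq[:start] + don[start:end] + read_seq[end:]


def apply_shm(
    read_seq: str,
    shm_rate: float,
    hotspot_multiplier: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Independent per-base substitutions, elevated inside WRCY/RGYW motifs.

    Substitutions pick uniformly among the three alternative bases;
    deterministic given the seed (or generator).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if shm_rate == 0.0:
        return read_seq
    rates = np.full(len(read_seq), shm_rate)
    for occ in scan_aid_motifs(read_seq, classes=("WRCY", "RGYW")):
        rates[occ.start : occ.end] = min(1.0, shm_rate * hotspot_multiplier)
    hit = rng.random(len(read_seq)) < rates
    out = list(read_seq)
    for p in np.flatnonzero(hit):
        if out[p] in "ACGT":
            out[p] = _mutate_base(rng, out[p])
    return "".join(out)


# ---------------------------------------------------------------------------
# Repertoire simulation
# ---------------------------------------------------------------------------

def simulate_repertoire(
    config: SimulationConfig,
) -> tuple[GermlineSet, list[AnnotatedRead], list[GroundTruthRecord]]:
    """Simulate the germline set, n_reads reads and the ground-truth table.

    Each read copies a functional acceptor, carries one implanted tract with
    probability ``implant_fraction`` (donor drawn 3' of the acceptor with
    probability ``downstream_donor_fraction``, else 5'), then undergoes SHM.
    v_call is the true acceptor. Fully reproducible from config.seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gset, meta = _build_locus(config, rng)
    functionals = gset.functional_genes()
    pseudos = {g.name: g for g in gset.pseudogenes()}
    up_names = [n for n, m in meta.items() if m.is_upstream]
    down_names = [n for n, m in meta.items() if not m.is_upstream]

    reads: list[AnnotatedRead] = []
    truth: list[GroundTruthRecord] = []
    for i in range(config.n_reads):
        read_id = f"read{i:05d}"
        implant = bool(rng.random() < config.implant_fraction)
        if implant:
            use_down = bool(rng.random() < config.downstream_donor_fraction)
            pool = down_names if use_down else up_names
            if not pool:
                kind = "downstream" if use_down else "upstream"
                raise ValueError(
                    f"no {kind} pseudogene available; adjust upstream_share"
                )
            donor_name = pool[rng.integers(0, len(pool))]
            m = meta[donor_name]
            donor = pseudos[donor_name]
            acceptor = gset.by_label(m.source + "*01")
            site = m.sites[rng.integers(0, len(m.sites))]
            seq = implant_conversion(
                acceptor.ungapped_seq, acceptor, donor,
                (site.tract_start, site.tract_end),
                (config.anchor_5p, config.anchor_3p),
            )
            silent = seq == acceptor.ungapped_seq
            truth.append(
                GroundTruthRecord(
                    read_id=read_id, acceptor=acceptor.name, donor=donor_name,
                    tract_start=site.tract_start, tract_end=site.tract_end,
                    donor_offset=site.tract_start,
                    is_upstream_donor=m.is_upstream, silent=silent,
                )
            )
        else:
            acceptor = functionals[rng.integers(0, len(functionals))]
            seq = acceptor.ungapped_seq
        seq = apply_shm(seq, config.shm_rate, config.hotspot_multiplier, rng)
        reads.append(
            AnnotatedRead(
                read_id=read_id, sample_id="sim", gapped_seq=seq,
                v_call=acceptor.label, productive=True, duplicate_count=1,
            )
        )
    n_silent = sum(t.silent for t in truth)
    logger.info(
        "simulate_repertoire: %d reads, %d implants (%d silent)",
        len(reads), len(truth), n_silent,
    )
    return gset, reads, truth


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def evaluate_recovery(
    truth: Sequence[GroundTruthRecord], detected_events: Sequence[ConversionEvent]
) -> dict:
    """Score detected (filtered) events against the ground truth.

    A truth record is recovered when some event on the same read overlaps its
    tract by >= 1 nt; sensitivity excludes silent conversions from the
    denominator (reported separately); precision is the fraction of events
    matching some truth record; donor_accuracy the fraction of recovered
    records whose overlapping event names the true donor.
    """
    by_read: dict[str, list[ConversionEvent]] = {}
    for ev in detected_events:
        by_read.setdefault(ev.read_id, []).append(ev)

    def overlapping(t: GroundTruthRecord) -> list[ConversionEvent]:
        return [
            ev for ev in by_read.get(t.read_id, [])
            if ev.block.start < t.tract_end and t.tract_start < ev.block.end
        ]

    visible = [t for t in truth if not t.silent]
    recovered = [t for t in visible if overlapping(t)]
    donor_correct = [
        t for t in recovered if any(ev.donor.donor_name == t.donor for ev in overlapping(t))
    ]
    matched_events = sum(
        1
        for ev in detected_events
        if any(
            t.read_id == ev.read_id
            and ev.block.start < t.tract_end
            and t.tract_start < ev.block.end
            for t in truth
        )
    )
    n_events = len(detected_events)
    return {
        "sensitivity": len(recovered) / len(visible) if visible else float("nan"),
        "precision": matched_events / n_events if n_events else float("nan"),
        "donor_accuracy": len(donor_correct) / len(recovered) if recovered else float("nan"),
        "n_truth": len(truth),
        "n_silent": len(truth) - len(visible),
        "n_events": n_events,
    }


# ---------------------------------------------------------------------------
# Truth-table I/O
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "read_id", "acceptor", "donor", "tract_start", "tract_end",
    "donor_offset", "is_upstream_donor", "silent",
]


def write_truth(truth: Sequence[GroundTruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write(
                f"{t.read_id}\t{t.acceptor}\t{t.donor}\t{t.tract_start}\t{t.tract_end}"
                f"\t{t.donor_offset}\t{'T' if t.is_upstream_donor else 'F'}"
                f"\t{'T' if t.silent else 'F'}\n"
            )


def read_truth(path: str | Path) -> list[GroundTruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth-table header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                GroundTruthRecord(
                    read_id=f[0], acceptor=f[1], donor=f[2],
                    tract_start=int(f[3]), tract_end=int(f[4]), donor_offset=int(f[5]),
                    is_upstream_donor=f[6] == "T", silent=f[7] == "T",
                )
            )
    return out
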