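"""Mismatch-block extraction, donor search, event detection, order filter."""

import random
from dataclasses import replace

import pytest

from igconvert.detection import (
    ConversionEvent,
    DetectionConfig,
    DonorHit,
    MismatchBlock,
    detect_events,
    extract_mismatch_blocks,
    gene_order_filter,
    levenshtein,
    search_donor,
)
from igconvert.germline import GeneOrderTable, GermlineGene, GermlineError
from igconvert.repertoire import AnnotatedRead
from oracles import brute_force_donor_hits, dp_levenshtein


def _read(seq, read_id="r1", v_call="IGHV1-2*01"):
    return AnnotatedRead(read_id, "s1", seq, v_call)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("", "", 0), ("ACG", "ACG", 0), ("", "ACG", 3), ("ACG", "", 3),
         ("ACG", "AGG", 1), ("ACGT", "CGT", 1), ("AAAA", "TTTT", 4)],
    )
    def test_known_distances(self, a, b, expected):
        assert levenshtein(a, b) == expected

    def test_matches_dp_oracle_on_random_short_pairs(self):
        rng = random.Random(23)
        for _ in range(200):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 30)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 30)))
            assert levenshtein(a, b) == dp_levenshtein(a, b)

    def test_symmetry_and_identity_of_indiscernibles(self):
        rng = random.Random(4)
        for _ in range(50):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 20)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 20)))
            assert levenshtein(a, b) == levenshtein(b, a)
            assert (levenshtein(a, b) == 0) == (a == b)


class TestExtractMismatchBlocks:
    def _germ(self, seq):
        return GermlineGene("IGHV1-2", "*01", "F", seq)

    def test_identical_read_yields_no_blocks(self):
        germ = self._germ("ACGTACGTAC")
        assert extract_mismatch_blocks(_read("ACGTACGTAC"), germ) == []

    def test_single_central_run(self):
        germ = self._germ("AAAAAAAAAA")
        blocks = extract_mismatch_blocks(_read("AAATTTAAAA"), germ, 3, 0)
        assert blocks == [MismatchBlock(3, 6, 3, "TTT")]

    def test_run_below_min_length_discarded(self):
        germ = self._germ("AAAAAAAAAA")
        assert extract_mismatch_blocks(_read("AATAAAAAAA"), germ, 3, 0) == []

    def test_merge_gap_joins_nearby_runs(self):
        germ = self._germ("AAAAAAAAAA")
        read = _read("AAATTATTAA")  # runs [3,5) and [6,8) split by one match
        assert extract_mismatch_blocks(read, germ, 3, 0) == []
        merged = extract_mismatch_blocks(read, germ, 3, 1)
        assert merged == [MismatchBlock(3, 8, 5, "TTATT")]

    def test_n_and_gap_columns_are_neutral(self):
        germ = self._germ("AAAAAAAAAA")
        # N breaks the run: two sub-runs of 2, both below min length
        assert extract_mismatch_blocks(_read("AAATTNTTAA"), germ, 3, 0) == []
        # gap column likewise neutral
        germ_gap = self._germ("AAAA.AAAAA")
        assert extract_mismatch_blocks(_read("AAAT.TAAAA"), germ_gap, 3, 0) == []
        # merge_gap absorbs the neutral column
        blocks = extract_mismatch_blocks(_read("AAATTNTTAA"), germ, 3, 1)
        assert blocks == [MismatchBlock(3, 8, 5, "TTNTT")]

    def test_block_length_counts_non_gap_read_columns(self):
        germ = self._germ("AAAAAAAAAAAA")
        read = _read("AAATTTTAAAAA")
        blocks = extract_mismatch_blocks(read, germ, 3, 0)
        assert blocks[0].length == 4 == len(blocks[0].read_subseq)

    def test_length_mismatch_names_the_read(self):
        germ = self._germ("AAAA")
        with pytest.raises(ValueError, match="r1"):
            extract_mismatch_blocks(_read("AAAAA"), germ)

    def test_terminal_runs_are_maximal(self):
        germ = self._germ("AAAAAAAAAA")
        blocks = extract_mismatch_blocks(_read("TTTAAAATTT"), germ, 3, 0)
        assert [(b.start, b.end) for b in blocks] == [(0, 3), (7, 10)]


class TestSearchDonor:
    def _pseudo(self, name, seq):
        return GermlineGene(name, "*01", "P", seq)

    def test_exact_donor_segment_found_at_distance_zero(self, toy_gset):
        read = _read(toy_gset.by_label("IGHV1-2*01").ungapped_seq[:16] + "CCC"
                     + toy_gset.by_label("IGHV1-2*01").ungapped_seq[19:])
        block = MismatchBlock(16, 19, 3, "CCC")
        hit = search_donor(block, read, toy_gset.pseudogenes())
        assert hit == DonorHit("IGHV1-1", 16, 3, 0)

    def test_no_segment_within_cap_returns_none(self):
        pseudos = [self._pseudo("IGHV1-9", "GGGGGGGGGGGG")]
        read = _read("AAATTTTTTAAA")
        block = MismatchBlock(3, 9, 6, "TTTTTT")
        assert search_donor(block, read, pseudos, max_lev=1) is None

    def test_zero_threshold_returns_only_identical_segments(self):
        pseudos = [self._pseudo("IGHV1-9", "AACCGTTGCACC")]
        read = _read("TTTTCGTTTTTT")
        block = MismatchBlock(3, 8, 5, "TCGTT")
        hit = search_donor(block, read, pseudos, max_lev=0)
        assert hit is None  # best hit is distance 1
        hit = search_donor(MismatchBlock(4, 8, 4, "CGTT"), read, pseudos, max_lev=0)
        assert hit is not None and hit.lev_distance == 0
        assert pseudos[0].ungapped_seq[hit.donor_offset : hit.donor_offset + hit.donor_length] == "CGTT"

    def test_empty_pseudogene_set_errors(self):
        with pytest.raises(ValueError):
            search_donor(MismatchBlock(0, 3, 3, "AAA"), _read("AAA"), [])

    def test_flank_identity_breaks_distance_ties(self):
        # both donors contain the block string; d_good shares the read flanks
        read = _read("ACGTACCCCTACGT")
        block = MismatchBlock(6, 9, 3, "CCC")
        d_good = self._pseudo("IGHV1-8", "ACGTACCCCTACGA")  # flanking context matches
        d_bad = self._pseudo("IGHV1-7", "GGGGGGCCCGGGGG")
        hit = search_donor(block, read, [d_bad, d_good], max_lev=1)
        assert hit.donor_name == "IGHV1-8"

    def test_seeded_path_equals_exhaustive_on_random_cases(self):
        rng = random.Random(77)
        for case in range(40):
            donors = [
                self._pseudo(f"IGHV1-P{k}", "".join(rng.choice("ACGT") for _ in range(150)))
                for k in range(3)
            ]
            qlen = rng.randint(18, 36)
            query = "".join(rng.choice("ACGT") for _ in range(qlen))
            if case % 2 == 0:  # plant the query (possibly mutated) in one donor
                d = rng.randrange(3)
                pos = rng.randint(0, 150 - qlen)
                planted = list(query)
                if case % 4 == 0:
                    planted[rng.randrange(qlen)] = rng.choice("ACGT")
                s = donors[d].gapped_seq
                donors[d] = self._pseudo(
                    donors[d].name, s[:pos] + "".join(planted) + s[pos + qlen :]
                )
            pad = "".join(rng.choice("ACGT") for _ in range(10))
            read = _read(pad + query + pad)
            block = MismatchBlock(10, 10 + qlen, qlen, query)
            seeded = search_donor(block, read, donors, max_lev=1)
            exhaustive = search_donor(block, read, donors, max_lev=1, force_exhaustive=True)
            assert seeded == exhaustive

    def test_exhaustive_scan_matches_brute_force_oracle(self):
        rng = random.Random(13)
        for _ in range(20)	:
            donor_seq = "".join(rng.choice("ACGT") for _ in range(80))
            query = donor_seq[30:38]
            donors = [self._pseudo("IGHV1-5", donor_seq)]
            read = _read("T" * 10 + query + "T" * 10)
            block = MismatchBlock(10, 18, 8, query)
            hit = search_donor(block, read, donors, max_lev=1)
            oracle_hits = brute_force_donor_hits(query, donor_seq, 1)
            assert hit is not None
            assert (hit.donor_offset, hit.donor_length, hit.lev_distance) in oracle_hits
            assert hit.lev_distance == min(h[2] for h in oracle_hits)


class TestDetectEvents:
    def test_germline_identical_read_gives_no_events(self, toy_gset):
        read = _read(toy_gset.by_label("IGHV1-2*01").ungapped_seq)
        assert detect_events(read, toy_gset) == []

    def test_implanted_tract_recovers_true_donor(self, toy_gset):
        acc = toy_gset.by_label("IGHV1-2*01").ungapped_seq
        read = _read(acc[:16] + "CCC" + acc[19:])
        events = detect_events(read, toy_gset)
        assert len(events) == 1
        ev = events[0]
        assert ev.donor.donor_name == "IGHV1-1"
        assert ev.donor.lev_distance == 0
        assert (ev.block.start, ev.block.end) == (16, 19)

    def test_isolated_shm_like_mismatches_yield_nothing(self, toy_gset):
        acc = list(toy_gset.by_label("IGHV1-2*01").ungapped_seq)
        for p in (2, 9, 21, 28, 35):  # five isolated single mismatches
            acc[p] = {"A": "G", "C": "T", "G": "A", "T": "C"}[acc[p]]
        assert detect_events(_read("".join(acc)), toy_gset) == []

    def test_unresolvable_v_call_errors_listing_known_genes(self, toy_gset):
        read = _read("ACGT" * 10, v_call="IGHV9-9*01")
        with pytest.raises(GermlineError, match="IGHV1-2"):
            detect_events(read, toy_gset)

    def test_detection_invariant_to_duplicate_count(self, toy_gset):
        acc = toy_gset.by_label("IGHV1-2*01").ungapped_seq
        base = _read(acc[:16] + "CCC" + acc[19:])
        heavy = replace(base, duplicate_count=500)
        assert detect_events(base, toy_gset) == detect_events(heavy, toy_gset)


def _mk_event(donor, acceptor="IGHV1-2"):
    return ConversionEvent(
        read_id="r", sample_id="s", acceptor=acceptor, v_call=acceptor + "*01",
        block=MismatchBlock(0, 3, 3, "AAA"), donor=DonorHit(donor, 0, 3, 0),
    )


class TestGeneOrderFilter:
    ORDER = GeneOrderTable({"IGHV1-P1": 3, "IGHV1-2": 10, "IGHV1-P2": 12})

    def test_upstream_donor_kept(self):
        kept = gene_order_filter([_mk_event("IGHV1-P1")], self.ORDER)
        assert len(kept) == 1 and kept[0].passed_order_filter

    def test_downstream_donor_removed(self):
        assert gene_order_filter([_mk_event("IGHV1-P2")], self.ORDER) == []

    def test_mixed_list_equals_direct_rank_comparison(self):
        rng = random.Random(9)
        order = GeneOrderTable({f"IGHV1-P{i}": 2 * i for i in range(20)} | {"IGHV1-2": 21})
        events = [_mk_event(f"IGHV1-P{rng.randrange(20)}") for _ in range(50)]
        kept = gene_order_filter(events, order)
        expected = [e for e in events if order.rank(e.donor.donor_name) < 21]
        assert kept == expected

    def test_idempotent(self):
        events = [_mk_event("IGHV1-P1"), _mk_event("IGHV1-P2")]
        once = gene_order_filter(events, self.ORDER)
        assert gene_order_filter(once, self.ORDER) == once

    def test_unordered_donor_excluded_not_fatal(self):
        assert gene_order_filter([_mk_event("IGHV1-P9")], self.ORDER) == []

    def test_empty_input_empty_output(self):
        assert gene_order_filter([], self.ORDER) == []


def test_seeded_search_only_engaged_for_long_blocks(toy_gset):
    """Short blocks always use the exhaustive path; configuration is honored."""
    cfg = DetectionConfig()
    assert cfg.seeded_min_block == 18
    assert cfg.min_block_len == 3
    assert cfg.max_lev == 1
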