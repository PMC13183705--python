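"""Flanking identity, expanded events, AID motifs, non-B motifs, profiles."""

import random

import pytest

from igconvert.characterize import (
    UNDEFINED_DISTANCE,
    MotifOccurrence,
    NonBParams,
    expanded_event,
    flanking_identity,
    hotspot_overlap_category,
    motif_offsets,
    nearest_aid_distance,
    positional_event_percentage,
    scan_aid_motifs,
    scan_nonb_motifs,
)
from igconvert.detection import ConversionEvent, DonorHit, MismatchBlock
from igconvert.germline import GermlineGene
from oracles import brute_force_direct_repeats, naive_aid_scan, outward_flank_walk


def _event(start, end, donor_offset=None, donor_len=None, donor="IGHV1-1",
           five=None, three=None):
    ev = ConversionEvent(
        read_id="r1", sample_id="s1", acceptor="IGHV1-2", v_call="IGHV1-2*01",
        block=MismatchBlock(start, end, end - start, "X" * (end - start)),
        donor=DonorHit(donor, donor_offset if donor_offset is not None else start,
                       donor_len if donor_len is not None else end - start, 0),
    )
    ev.five_prime_identical_len = five
    ev.three_prime_identical_len = three
    return ev


class TestFlankingIdentity:
    def test_constructed_six_and_one_flanks(self, toy_gset):
        acc = toy_gset.by_label("IGHV1-2*01")
        don = toy_gset.by_label("IGHV1-1*01")
        # P1 shares GGATCC (6 nt) before the tract [16,19) and T (1 nt) after
        ev = _event(16, 19)
        assert flanking_identity(ev, acc, don) == (6, 1)

    def test_block_at_position_zero_has_no_five_prime_flank(self):
        acc = GermlineGene("IGHV1-2", "*01", "F", "AAATTTT")
        don = GermlineGene("IGHV1-1", "*01", "P", "CCCTTTT")
        ev = _event(0, 3, donor_offset=0)
        assert flanking_identity(ev, acc, don) == (0, 4)

    def test_donor_offset_out_of_bounds_errors(self):
        acc = GermlineGene("IGHV1-2", "*01", "F", "AAAA")
        don = GermlineGene("IGHV1-1", "*01", "P", "AAAA")
        ev = _event(0, 3, donor_offset=3, donor_len=3)
        with pytest.raises(ValueError):
            flanking_identity(ev, acc, don)

    def test_random_trios_match_outward_walk_oracle(self):
        rng = random.Random(31)
        for _ in range(100):
            n = rng.randint(20, 60)
            acc = "".join(rng.choice("ACGT") for _ in range(n))
            don = "".join(rng.choice("ACGT") for _ in range(n))
            start = rng.randint(0, n - 4)
            end = rng.randint(start + 1, min(n, start + 8))
            a = GermlineGene("IGHV1-2", "*01", "F", acc)
            d = GermlineGene("IGHV1-1", "*01", "P", don)
            ev = _event(start, end, donor_offset=start, donor_len=end - start)
            assert flanking_identity(ev, a, d) == outward_flank_walk(
                acc, don, start, start, end, end
            )


class TestExpandedEvent:
    def test_three_nt_block_with_canonical_flanks_expands_to_ten(self):
        ev = _event(16, 19, five=6, three=1)
        start, end, length = expanded_event(ev)
        assert (start, end, length) == (10, 20, 10)

    def test_zero_flanks_keep_block_interval(self):
        ev = _event(5, 9, five=0, three=0)
        assert expanded_event(ev) == (5, 9, 4)

    def test_flanks_clamped_at_sequence_bounds(self):
        ev = _event(2, 5, five=6, three=3)
        start, end, length = expanded_event(ev, gapped_seq="ACGTACG")
        assert (start, end) == (0, 7)
        assert length == 7

    def test_expanded_length_counts_non_gap_columns(self):
        ev = _event(4, 7, five=2, three=1)
        start, end, length = expanded_event(ev, gapped_seq="AC.TACGTAC")
        assert (start, end) == (2, 8)
        assert length == 5  # one gap column inside the expanded interval

    def test_requires_flanks_first(self):
        with pytest.raises(ValueError):
            expanded_event(_event(4, 7))


class TestScanAidMotifs:
    def test_agct_matches_wrcy_and_rgyw(self):
        occ = scan_aid_motifs("AGCT")
        assert {(o.motif_class, o.start, o.end) for o in occ} == {
            ("WRCY", 0, 4), ("RGYW", 0, 4)
        }

    def test_g_run_matches_nothing(self):
        assert scan_aid_motifs("GGGG") == []

    def test_ta_matches_tw_and_wa(self):
        occ = scan_aid_motifs("TA")
        assert {(o.motif_class, o.start, o.end) for o in occ} == {
            ("TW", 0, 2), ("WA", 0, 2)
        }

    def test_n_never_matches(self):
        assert scan_aid_motifs("ANCT") == []

    def test_gapped_coordinates_reported(self):
        occ = scan_aid_motifs("A.G.CT")
        assert ("WRCY", 0, 6) in {(o.motif_class, o.start, o.end) for o in occ}

    def test_matches_naive_all_window_oracle(self):
        rng = random.Random(19)
        for _ in range(100):
            seq = "".join(rng.choice("ACGTN.") for _ in range(80))
            got = [(o.motif_class, o.start, o.end) for o in scan_aid_motifs(seq)]
            assert got == naive_aid_scan(seq)


class TestNearestAidDistance:
    @pytest.mark.parametrize(
        "motif, block, expected",
        [((2, 6), (4, 7), 0),   # overlap
         ((0, 4), (4, 7), 1),   # immediately adjacent
         ((0, 4), (6, 9), 3),   # two intervening nt + 1
         ((10, 14), (4, 7), 4)],
    )
    def test_distance_convention(self, motif, block, expected):
        ev = _event(*block)
        motifs = [MotifOccurrence("WRCY", *motif)]
        assert nearest_aid_distance(ev, motifs) == expected

    def test_gap_only_convention_switch(self):
        ev = _event(4, 7)
        motifs = [MotifOccurrence("WRCY", 0, 4)]
        assert nearest_aid_distance(ev, motifs, adjacency="gap") == 0

    def test_no_motifs_is_undefined_not_zero(self):
        assert nearest_aid_distance(_event(4, 7), []) is UNDEFINED_DISTANCE


class TestHotspotOverlapCategory:
    @pytest.mark.parametrize(
        "block, hotspot, expected",
        [((2, 5), (0, 8), "full"),
         ((2, 5), (4, 9), "partial"),
         ((2, 5), (10, 20), "none"),
         ((2, 5), (2, 5), "full")],
    )
    def test_categories(self, block, hotspot, expected):
        ev = _event(*block)
        assert hotspot_overlap_category(ev, [MotifOccurrence("TW", *hotspot)]) == expected

    def test_categories_partition_all_events(self):
        rng = random.Random(8)
        events = [_event(s, s + rng.randint(1, 6)) for s in rng.sample(range(80), 30)]
        hotspots = [
            MotifOccurrence("WA", s, s + rng.randint(2, 6)) for s in rng.sample(range(80), 15)
        ]
        cats = [hotspot_overlap_category(e, hotspots) for e in events]
        assert all(c in ("full", "partial", "none") for c in cats)
        assert len(cats) == len(events)


class TestPositionalEventPercentage:
    def test_two_overlapping_events(self):
        events = [_event(1, 4), _event(2, 5)]
        prof = positional_event_percentage(events)
        assert (prof.start, prof.end) == (1, 5)
        assert prof.percentages == [50.0, 100.0, 100.0, 50.0]

    def test_single_event_covers_block_at_100(self):
        prof = positional_event_percentage([_event(3, 7)])
        assert (prof.start, prof.end) == (3, 7)
        assert prof.percentages == [100.0] * 4

    def test_empty_events_empty_profile(self):
        prof = positional_event_percentage([])
        assert prof.to_frame().empty

    def test_sequence_denominator(self):
        prof = positional_event_percentage([_event(0, 2)], n_sequences=4,
                                           denominator="sequences")
        assert prof.percentages == [25.0, 25.0]

    def test_percentages_bounded(self):
        rng = random.Random(2)
        events = [_event(s, s + rng.randint(1, 9)) for s in rng.choices(range(50), k=40)]
        prof = positional_event_percentage(events)
        assert all(0.0 <= p <= 100.0 for p in prof.percentages)


class TestNonBMotifs:
    def test_g_quadruplex_example(self):
        occ = scan_nonb_motifs("GGGTGGGTGGGTGGG")
        gq = [o for o in occ if o.motif_class == "GQ"]
        assert gq == [MotifOccurrence("GQ", 0, 15)]

    def test_short_tandem_repeat_example(self):
        occ = scan_nonb_motifs("CAGCAGCAGCAG")
        strs = [o for o in occ if o.motif_class == "STR"]
        assert MotifOccurrence("STR", 0, 12) in strs

    def test_z_dna_example(self):
        occ = scan_nonb_motifs("GCGCGCGCGCGC")
        assert MotifOccurrence("Z", 0, 12) in occ

    def test_direct_repeat_detected(self):
        arm = "ACGTTACGGA"  # 10 nt
        seq = "TT" + arm + "CCC" + arm + "TT"
        occ = scan_nonb_motifs(seq)
        dr = [(o.start, o.end) for o in occ if o.motif_class == "DR"]
        assert (2, 2 + 10 + 3 + 10) in dr

    def test_inverted_repeat_detected(self):
        arm = "ACGTGA"
        rc = "TCACGT"
        seq = "GG" + arm + "TTT" + rc + "GG"
        occ = scan_nonb_motifs(seq)
        ir = [(o.start, o.end) for o in occ if o.motif_class == "IR"]
        assert (2, 2 + 6 + 3 + 6) in ir

    def test_mirror_repeat_detected(self):
        arm = "ACGTGACGTG"
        seq = "GG" + arm + "CC" + arm[::-1] + "TT"
        occ = scan_nonb_motifs(seq)
        mr = [(o.start, o.end) for o in occ if o.motif_class == "MR"]
        assert (2, 2 + 10 + 2 + 10) in mr

    def test_a_phased_repeat_detected(self):
        seq = "AAAACGTCGG" * 3 + "CGT"  # A-tract starts every 10 nt
        occ = scan_nonb_motifs(seq)
        apr = [o for o in occ if o.motif_class == "APR"]
        assert apr and apr[0].start == 0

    def test_invalid_params_raise_config_error(self):
        with pytest.raises(ValueError, match="arm_min"):
            scan_nonb_motifs("ACGT", NonBParams(dr_arm_min=2))

    def test_dr_calls_match_quadratic_oracle_on_randomized_sequences(self):
        rng = random.Random(55)
        params = NonBParams()
        for case in range(20):
            seq = list("".join(rng.choice("ACGT") for _ in range(120)))
            if case % 2 == 0:  # plant a repeat so the comparison is non-trivial
                arm_len = rng.randint(10, 14)
                arm = "".join(rng.choice("ACGT") for _ in range(arm_len))
                spacer = rng.randint(0, 10)
                pos = rng.randint(0, 120 - (2 * arm_len + spacer))
                seq[pos : pos + arm_len] = arm
                seq[pos + arm_len + spacer : pos + 2 * arm_len + spacer] = arm
            s = "".join(seq)
            got = {
                (o.start, o.end)
                for o in scan_nonb_motifs(s, params)
                if o.motif_class == "DR"
            }
            assert got == brute_force_direct_repeats(s, params.dr_arm_min, params.dr_spacer_max)


class TestMotifOffsets:
    def test_signed_offsets(self):
        events = [_event(10, 13)]
        motifs = [MotifOccurrence("DR", 0, 5), MotifOccurrence("DR", 10, 15)]
        assert motif_offsets(events, motifs) == [-10, 0]

    def test_empty_inputs(self):
        assert motif_offsets([], [MotifOccurrence("DR", 0, 5)]) == []
        assert motif_offsets([_event(0, 3)], []) == []
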