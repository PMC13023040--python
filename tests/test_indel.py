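"""Alignment, event normalization, microhomology and pattern classification."""

import numpy as np
import pytest

from repairmap.indel import (
    AlleleCall,
    ConfigurationError,
    RepairEvent,
    TargetLocus,
    align_read,
    apply_events,
    breakpoint_profile,
    call_repair_events,
    classify_allele,
    classify_reads,
    detect_microhomology,
    left_normalize,
    locate_cut_site,
    summarize_spectrum,
    format_event,
    parse_event,
)
from repairmap.patterns import EDITED_PATTERNS, UNEDITED

from oracles import (
    brute_force_mh,
    equivalent_deletion_placements,
    event_alignment_score,
    gotoh_score,
)


class TestCutSite:
    @pytest.mark.parametrize(
        "ps, plen, pam, strand, expected",
        [
            (0, 20, 20, "+", 17),
            (10, 20, 30, "+", 27),
            (13, 20, 10, "-", 16),  # mirror of the + rule on the - strand
        ],
    )
    def test_blunt_cut_three_nt_from_pam(self, ps, plen, pam, strand, expected):
        assert locate_cut_site(ps, plen, pam, strand) == expected

    def test_nonadjacent_pam_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            locate_cut_site(0, 20, 25, "+")

    def test_minus_strand_rule_mirrors_plus_via_revcomp(self, rng):
        # Cutting at c on the + strand of the reverse complement must equal
        # cutting at len - c on the forward sequence.
        n = 60
        for _ in range(20):
            ps = int(rng.integers(5, 30))
            cut_plus = locate_cut_site(ps, 20, ps + 20, "+")
            # The same physical site annotated on the - strand of a length-n
            # sequence: protospacer at n-(ps+20), PAM immediately 5' of it.
            ps_minus = n - (ps + 20)
            cut_minus = locate_cut_site(ps_minus, 20, ps_minus - 3, "-")
            assert cut_minus == n - cut_plus


class TestAlignment:
    def test_identical_read_has_no_events(self, syn_locus):
        assert align_read(syn_locus.locus.ref_seq, syn_locus.locus) == []

    def test_single_insertion_matches_dp_oracle(self):
        ref = "ACGTACGTACGT"
        locus = TargetLocus(ref_seq=ref + "A" * 11 + "TGG" + "C" * 10,
                            protospacer_start=3)
        read = ref[:6] + "T" + ref[6:] + "A" * 11 + "TGG" + "C" * 10
        events = align_read(read, locus)
        ins = [e for e in events if e.kind == "insertion"]
        assert len(events) == 1 and len(ins) == 1
        assert (ins[0].start, ins[0].length, ins[0].inserted_seq) == (6, 1, "T")
        assert event_alignment_score(len(locus.ref_seq), events) == pytest.approx(
            gotoh_score(locus.ref_seq, read)
        )

    def test_three_bp_deletion_matches_dp_oracle(self):
        ref = "ACGTACGTACGT" + "A" * 11 + "TGG" + "C" * 10
        locus = TargetLocus(ref_seq=ref, protospacer_start=3)
        read = ref[:5] + ref[8:]
        events = align_read(read, locus)
        assert [e.kind for e in events] == ["deletion"]
        # left-normalization may slide the 3-bp deletion inside the repeat
        assert events[0].length == 3
        assert apply_events(ref, events) == read
        assert event_alignment_score(len(ref), events) == pytest.approx(
            gotoh_score(ref, read)
        )

    def test_alignment_round_trip_on_generated_reads(self, syn_locus, labeled_reads):
        for _, seq in labeled_reads[:300]:
            events = align_read(seq, syn_locus.locus)
            assert apply_events(syn_locus.locus.ref_seq, events) == seq


class TestLeftNormalize:
    def test_ambiguous_deletion_takes_minimum_placement(self):
        # Enumeration oracle: placements {3,4,5,6} all yield "AAATGCAAAT".
        ref = "AAATGCTTTTGCAAAT"
        placements = equivalent_deletion_placements(ref, 6, 6)
        assert min(placements) == 3
        ev = left_normalize(RepairEvent("deletion", 6, 6), ref)
        assert ev.start == 3

    def test_unambiguous_deletion_unchanged(self):
        ev = left_normalize(RepairEvent("deletion", 3, 2), "ACGGTTCA")
        assert ev.start == 3

    def test_insertion_in_homopolymer_run_anchors_leftmost(self):
        ref = "CGAAATC"
        for anchor in (2, 3, 4, 5):
            ev = left_normalize(RepairEvent("insertion", anchor, 1, "A"), ref)
            assert ev.start == 2

    def test_idempotent_and_allele_preserving_random(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(500):
            ref = "".join(rng.choice(bases, size=30))
            L = int(rng.integers(1, 9))
            start = int(rng.integers(0, 30 - L))
            ev = RepairEvent("deletion", start, L)
            norm = left_normalize(ev, ref)
            assert left_normalize(norm, ref) == norm
            assert apply_events(ref, [norm]) == apply_events(ref, [ev])
            assert norm.start == min(equivalent_deletion_placements(ref, start, L))


class TestMicrohomology:
    @pytest.mark.parametrize(
        "ref, start, length, expected",
        [
            ("AAATGCTTTTGCAAAT", 3, 6, 3),  # normalized form of the TGC repeat
            ("ACGGTTCA", 3, 2, 0),
            ("CCTAGCGGTAGCAA", 2, 6, 4),  # TAGC...TAGC flanks
        ],
    )
    def test_known_junctions(self, ref, start, length, expected):
        ev = left_normalize(RepairEvent("deletion", start, length), ref)
        assert detect_microhomology(ev, ref) == expected
        assert brute_force_mh(ref, ev.start, length) == expected

    def test_matches_exhaustive_oracle_on_random_30mers(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(2_000):
            ref = "".join(rng.choice(bases, size=30))
            L = int(rng.integers(1, 12))
            start = int(rng.integers(0, 30 - L))
            ev = left_normalize(RepairEvent("deletion", start, L), ref)
            assert detect_microhomology(ev, ref) == brute_force_mh(ref, ev.start, L)


class TestWindow:
    @pytest.mark.parametrize(
        "event, kept",
        [
            (RepairEvent("substitution", 53, 1, sub_bases=((53, "A", "C"),)), True),
            (RepairEvent("substitution", 70, 1, sub_bases=((70, "A", "C"),)), False),
            (RepairEvent("deletion", 42, 10), True),  # spans cut-8..cut+2
        ],
    )
    def test_overlap_semantics(self, event, kept):
        retained = call_repair_events([event], cut_site=50, window_bp=5)
        assert (event in retained) == kept


class TestClassification:
    R = "ACGTACGTAAGGTACGTACG"

    @pytest.mark.parametrize(
        "events, expected",
        [
            ([RepairEvent("insertion", 8, 1, "A")], "1bp Ins"),
            ([RepairEvent("insertion", 8, 3, "TTT")], "Large Ins"),
            ([RepairEvent("deletion", 7, 4)], None),  # MH decided below
            ([], UNEDITED),
            ([RepairEvent("substitution", 8, 1, sub_bases=((8, "A", "C"),))], "Mut"),
        ],
    )
    def test_basic_labels(self, events, expected):
        call = classify_allele(events, self.R)
        if expected is not None:
            assert call.pattern == expected

    def test_mh_split_by_threshold(self):
        ref = "AAATGCTTTTGCAAAT"
        # 6-bp deletion with 3-bp MH
        ev = left_normalize(RepairEvent("deletion", 6, 6), ref)
        assert classify_allele([ev], ref).pattern == "MH Large Del"
        assert classify_allele([ev], ref, mh_min=4).pattern == "NonMH Large Del"
        # 4-bp deletion, no flanking identity
        ev4 = RepairEvent("deletion", 6, 4)
        ref2 = "ACGTACCGTGACTGACAGT"
        call = classify_allele([left_normalize(ev4, ref2)], ref2)
        assert call.pattern in ("MH Small Del", "NonMH Small Del")
        assert (call.pattern == "MH Small Del") == (call.mh_len >= 2)

    def test_small_large_boundary_at_five_bp(self):
        ref = "ACGTAGTCCAGTTGACCTGA"
        for L, cls in [(5, "Small"), (6, "Large")]:
            call = classify_allele([RepairEvent("deletion", 4, L)], ref)
            assert cls in call.pattern

    def test_complex_allele_dominant_event_and_deletion_tie_break(self):
        ref = "ACGTAGTCCAGTTGACCTGA"
        dele = RepairEvent("deletion", 4, 2)
        ins = RepairEvent("insertion", 10, 2, "TT")
        assert "Del" in classify_allele([dele, ins], ref).pattern
        big_ins = RepairEvent("insertion", 10, 3, "TTT")
        assert classify_allele([dele, big_ins], ref).pattern == "Large Ins"

    def test_substitutions_beside_indel_do_not_trigger_mut(self):
        ref = "ACGTAGTCCAGTTGACCTGA"
        sub = RepairEvent("substitution", 2, 1, sub_bases=((2, "G", "A"),))
        call = classify_allele([sub, RepairEvent("insertion", 8, 1, "G")], ref)
        assert call.pattern == "1bp Ins"

    def test_templated_insertion_flag(self):
        ref = "ACGTAGTCCAGTTGACCTGA"
        dup = classify_allele([RepairEvent("insertion", 8, 2, "TC")], ref)
        assert dup.templated  # "TC" duplicates ref[6:8]
        other = classify_allele([RepairEvent("insertion", 8, 2, "GG")], ref)
        assert not other.templated

    def test_total_and_order_invariant(self, rng):
        ref = "ACGTAGTCCAGTTGACCTGA"
        events = [
            RepairEvent("deletion", 3, 2),
            RepairEvent("insertion", 9, 1, "T"),
            RepairEvent("substitution", 14, 1, sub_bases=((14, "A", "G"),)),
        ]
        labels = set()
        for _ in range(6):
            perm = [events[i] for i in rng.permutation(3)]
            call = classify_allele(perm, ref)
            labels.add(call.pattern)
            assert call.pattern in EDITED_PATTERNS
        assert len(labels) == 1


class TestSpectrum:
    def test_proportions_and_editing_fraction(self):
        calls = (
            [AlleleCall((), "1bp Ins", read_count=30)]
            + [AlleleCall((), "MH Small Del", read_count=50)]
            + [AlleleCall((), "Mut", read_count=20)]
            + [AlleleCall((), UNEDITED, read_count=25)]
        )
        spec = summarize_spectrum(calls)
        assert spec.proportions["1bp Ins"] == pytest.approx(0.3)
        assert spec.proportions["MH Small Del"] == pytest.approx(0.5)
        assert spec.proportions["Mut"] == pytest.approx(0.2)
        assert sum(spec.proportions.values()) == pytest.approx(1.0, abs=1e-9)
        assert spec.editing_fraction == pytest.approx(100 / 125)

    def test_all_unedited_flagged_empty(self):
        spec = summarize_spectrum([AlleleCall((), UNEDITED, read_count=10)])
        assert spec.empty and spec.editing_fraction == 0.0

    def test_generator_round_trip_recovers_proportions(self, syn_locus):
        from repairmap.simulate import SpectrumSpec, gen_edited_reads

        probs = {"1bp Ins": 0.4, "MH Small Del": 0.4, "Mut": 0.2}
        reads = gen_edited_reads(syn_locus, SpectrumSpec(pattern_probs=probs),
                                 4_000, seed=7)
        spectrum = classify_reads([s for _, s in reads], syn_locus.locus)
        for p, true_p in probs.items():
            se = np.sqrt(true_p * (1 - true_p) / 4_000)
            assert abs(spectrum.proportions[p] - true_p) < 3 * se


class TestBreakpointProfile:
    def test_symmetric_deletion_ratio_one(self):
        call = AlleleCall((RepairEvent("deletion", 48, 4),), "NonMH Small Del")
        _, ratio = breakpoint_profile([call], cut_site=50)
        assert ratio == pytest.approx(1.0)

    def test_all_distal_flagged_infinite(self):
        call = AlleleCall((RepairEvent("deletion", 44, 4),), "NonMH Small Del")
        _, ratio = breakpoint_profile([call], cut_site=50, pam_is_downstream=True)
        assert ratio == float("inf")

    def test_distal_shifted_simulation_recovers_ratio(self, rng):
        # Each deleted base lands distal (5' of the cut) with probability 0.7.
        calls = []
        for _ in range(3_000):
            distal = rng.random() < 0.7
            start = 49 if distal else 50
            calls.append(AlleleCall((RepairEvent("deletion", start, 1),),
                                    "NonMH Small Del"))
        _, ratio = breakpoint_profile(calls, cut_site=50)
        assert ratio == pytest.approx(7 / 3, rel=0.1)


class TestEventStrings:
    @pytest.mark.parametrize("ev", [
        RepairEvent("deletion", 5, 8),
        RepairEvent("insertion", 17, 1, "T"),
        RepairEvent("substitution", 16, 1, sub_bases=((16, "C", "A"),)),
        RepairEvent("substitution", 4, 2, sub_bases=((4, "C", "A"), (5, "G", "T"))),
    ])
    def test_round_trip(self, ev):
        assert parse_event(format_event(ev)) == ev
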