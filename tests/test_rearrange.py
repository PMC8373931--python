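"""Segment-map compilation, mutant sequence assembly, liftover and chain I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neotad as nt
from conftest import marker_track, random_rearrangement


def compile_ops(*ops, length=100, convention="0based", chrom="chrT"):
    return nt.compile_rearrangement(
        nt.RearrangementSpec(chrom, list(ops), convention), length
    )


class TestCompile:
    def test_simple_inversion_structure(self):
        m = compile_ops(nt.Inversion(10, 20))
        assert m.mut_length == 100
        assert len(m.blocks) == 3
        assert [b.flipped for b in m.blocks] == [False, True, False]
        assert (m.blocks[1].wt_start, m.blocks[1].wt_end) == (10, 20)

    def test_tandem_duplication_adds_length_and_double_maps(self):
        m = compile_ops(nt.Duplication(10, 40))
        assert m.mut_length == 130
        hits = nt.lift_position(m, 20, "wt_to_mut")
        assert len(hits) == 2
        assert all(o == "same" for _, o in hits)

    def test_deletion_shrinks_and_drops_positions(self):
        m = compile_ops(nt.Deletion(10, 20))
        assert m.mut_length == 90
        assert nt.lift_position(m, 15, "wt_to_mut") == []
        assert nt.lift_position(m, 5, "wt_to_mut") == [(5, "same")]
        assert nt.lift_position(m, 25, "wt_to_mut") == [(15, "same")]

    def test_one_based_convention_matches_zero_based(self):
        a = compile_ops(nt.Inversion(11, 20), convention="1based")
        b = compile_ops(nt.Inversion(10, 20), convention="0based")
        assert a.blocks == b.blocks

    def test_overlapping_operations_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            compile_ops(nt.Inversion(10, 30), nt.Deletion(20, 40))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            compile_ops(nt.Inversion(90, 120))

    def test_mutant_axis_always_tiles(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = nt.compile_rearrangement(random_rearrangement(rng, 200), 200)
            ends = [b.mut_end for b in m.blocks]
            starts = [b.mut_start for b in m.blocks]
            assert starts[0] == 0 and ends[-1] == m.mut_length
            assert all(e == s for e, s in zip(ends[:-1], starts[1:]))


class TestMutantSequence:
    def test_inversion_is_reverse_complement(self):
        # revcomp of "CGTT" (positions 2..5) is "AACG"
        m = compile_ops(nt.Inversion(2, 6), length=8)
        assert nt.build_mutant_sequence("AACGTTAC", m) == "AAAACGAC"

    def test_identity_map_copies_sequence(self):
        m = compile_ops(length=8)
        assert nt.build_mutant_sequence("AACGTTAC", m) == "AACGTTAC"

    def test_inversion_is_an_involution(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=100))
        m = compile_ops(nt.Inversion(17, 63))
        mut = nt.build_mutant_sequence(seq, m)
        assert mut != seq
        assert nt.build_mutant_sequence(mut, m) == seq

    def test_length_mismatch_rejected(self):
        m = compile_ops(nt.Inversion(2, 6), length=8)
        with pytest.raises(ValueError, match="length"):
            nt.build_mutant_sequence("AACG", m)

    def test_duplication_doubles_kmer_multiset(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=100))
        m = compile_ops(nt.Duplication(30, 50))
        mut = nt.build_mutant_sequence(seq, m)
        k = 5
        region = seq[30:50]

        def kmers(s):
            return pd.Series([s[i : i + k] for i in range(len(s) - k + 1)]).value_counts()

        wt_k = kmers(seq)
        mut_k = kmers(mut)
        for kmer, count in kmers(region).items():
            assert mut_k[kmer] >= wt_k.get(kmer, 0) + count


class TestLiftover:
    def test_positions_inside_inversion_mirror(self):
        m = compile_ops(nt.Inversion(10, 20))
        assert nt.lift_position(m, 12) == [(17, "flipped")]
        assert nt.lift_position(m, 5) == [(5, "same")]

    def test_lift_agrees_with_marker_tracking(self):
        """Exhaustive agreement with the sequence-level oracle over random specs."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            length = int(rng.integers(20, 120))
            m = nt.compile_rearrangement(random_rearrangement(rng, length), length)
            for pos in range(length):
                assert sorted(nt.lift_position(m, pos)) == marker_track(length, m, pos)

    def test_round_trip_features_through_inversion(self):
        m = compile_ops(nt.Inversion(10, 60))
        feats = pd.DataFrame(
            {
                "chrom": "chrT",
                "start": [2, 15, 40, 70],
                "end": [8, 25, 50, 90],
                "name": list("abcd"),
                "score": 0,
                "strand": ["+", "+", "-", "+"],
            }
        )
        lifted, rep1 = nt.lift_features(m, feats, "split", "wt_to_mut")
        assert rep1["n_split"] == 0
        back, rep2 = nt.lift_features(m, lifted, "split", "mut_to_wt")
        got = back.sort_values("start", ignore_index=True)
        want = feats.sort_values("start", ignore_index=True)
        pd.testing.assert_frame_equal(
            got[["start", "end", "strand"]], want[["start", "end", "strand"]]
        )

    def test_strand_flips_inside_inversion(self):
        m = compile_ops(nt.Inversion(10, 60))
        feats = pd.DataFrame(
            {"chrom": "chrT", "start": [20], "end": [30], "name": ["x"],
             "score": [0], "strand": ["+"]}
        )
        lifted, _ = nt.lift_features(m, feats)
        assert lifted.loc[0, "strand"] == "-"

    def test_breakpoint_spanning_feature_policies(self):
        m = compile_ops(nt.Inversion(10, 60))
        feats = pd.DataFrame(
            {"chrom": "chrT", "start": [5], "end": [15], "name": ["x"],
             "score": [0], "strand": ["+"]}
        )
        dropped, rep = nt.lift_features(m, feats, span_policy="drop")
        assert len(dropped) == 0 and rep["n_dropped"] == 1
        split, rep = nt.lift_features(m, feats, span_policy="split")
        assert len(split) == 2 and rep["n_split"] == 1
        assert (split["end"] - split["start"]).sum() == 10

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        start=st.integers(0, 80),
        size=st.integers(1, 19),
        pos=st.integers(0, 99),
    )
    def test_inversion_lift_is_involutive_per_position(self, start, size, pos):
        m = compile_ops(nt.Inversion(start, start + size))
        (mut_pos, orient) = nt.lift_position(m, pos, "wt_to_mut")[0]
        back = nt.lift_position(m, mut_pos, "mut_to_wt")
        assert back == [(pos, orient)]


class TestChain:
    def test_identity_map_single_chain(self):
        m = compile_ops(length=100)
        text = nt.write_chain(m)
        assert text.count("chain ") == 1

    def test_inversion_three_chains_with_minus_strand(self):
        m = compile_ops(nt.Inversion(10, 20))
        text = nt.write_chain(m)
        headers = [l for l in text.splitlines() if l.startswith("chain")]
        assert len(headers) == 3
        strands = [h.split()[9] for h in headers]
        assert strands == ["+", "-", "+"]

    def test_parse_back_equivalence_and_idempotence(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            m = nt.compile_rearrangement(random_rearrangement(rng, 300), 300)
            text = nt.write_chain(m)
            m2 = nt.parse_chain(text)
            assert m2.blocks == m.blocks
            assert sorted(m2.deletions) == sorted(m.deletions)
            assert nt.write_chain(m2) == text
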