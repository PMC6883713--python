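"""Branch points, U2 duplex bonds, decoy counters, junction folding."""

import numpy as np
import pytest

from splicegc.signals import (BranchPointCall, best_branch_point, count_t_rich,
                              count_tna, duplex_max_bonds, exon_signal_features,
                              has_multiple_bps, junction_mfe, maxpair_engine,
                              predict_branch_points, rnafold_engine,
                              u2_binding_bonds)
from tests._oracles import (branch_point_scan, duplex_enumerate, fold_enumerate,
                            t_rich_scan, tna_scan)


def random_seqs(n, length, seed, alphabet="ACGT"):
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(list(alphabet), size=length)) for _ in range(n)]


class TestBranchPoints:
    def test_perfect_consensus_scores_two(self):
        calls = predict_branch_points("AACTGACAA")
        assert len(calls) == 1
        assert calls[0].score == 2
        assert calls[0].offset == -4  # A of CTGAC, 4 nt from the 3' end

    def test_two_mismatches_fail(self):
        # AAGAA context around the central A: only the A matches
        assert predict_branch_points("GGAAGAAGG") == []

    def test_no_adenine_no_calls(self):
        assert predict_branch_points("G" * 50) == []

    def test_short_sequence_gives_empty_list(self):
        assert predict_branch_points("CTA") == []

    def test_one_mismatch_retained_at_permissive_threshold(self):
        # ATGAC: first Y position mismatched -> score 1
        seq = "AAATGACAA"
        assert predict_branch_points(seq) == []
        calls = predict_branch_points(seq, min_score=0.0)
        assert [c.score for c in calls] == [1]

    def test_count_and_multiplicity(self):
        calls = [BranchPointCall(-10, 2.0, "AACTAACAA", 5),
                 BranchPointCall(-30, 2.0, "CTCTGACTC", 5)]
        assert has_multiple_bps([], k=2) is False
        assert has_multiple_bps(calls, k=2) is True
        assert has_multiple_bps(calls, k=3) is False
        assert has_multiple_bps(calls * 2, k=3) is True

    def test_best_call_prefers_score_then_proximity(self):
        near = BranchPointCall(-10, 1.0, "x", 5)
        far_high = BranchPointCall(-80, 2.0, "y", 5)
        assert best_branch_point([near, far_high]) is far_high
        tie = BranchPointCall(-40, 2.0, "z", 5)
        assert best_branch_point([tie, far_high]) is tie

    def test_matches_bruteforce_scan(self):
        for seq in random_seqs(300, 100, seed=5, alphabet="ACGTN"):
            calls = predict_branch_points(seq)
            assert [(c.offset, c.score) for c in calls] == branch_point_scan(seq)


class TestU2Duplex:
    @pytest.mark.parametrize("target,expected", [
        ("TACTACAC", 19),   # reverse complement of the U2 BBS: full duplex
        ("AAAAAAAA", 6),    # three U:A pairs
        ("CCCCCCCC", 9),    # three G:C pairs
    ])
    def test_reference_targets(self, target, expected):
        call = BranchPointCall(-20, 2.0, target[:5] + "A" + target[5:], 5)
        assert u2_binding_bonds(call) == expected
        assert duplex_enumerate(target, "GUGUAGUA") == expected

    def test_short_context_scored_over_available_bases(self):
        call = BranchPointCall(-2, 2.0, "CCA", 2)  # BP near the sequence edge
        assert u2_binding_bonds(call) == duplex_enumerate("CC", "GUGUAGUA")

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        for length in range(1, 9):
            for _ in range(40):
                target = "".join(rng.choice(list("ACGT"), size=length))
                assert duplex_max_bonds(target, "GUGUAGUA") == \
                    duplex_enumerate(target, "GUGUAGUA"), target


class TestDecoyCounters:
    @pytest.mark.parametrize("seq,expected", [
        ("TCA", 1),
        ("TAATGATTAC", 3),
        ("GGGG", 0),
        ("TNA", 0),          # N breaks the motif
        ("TTAA", 2),         # overlapping motifs both count
    ])
    def test_tna_examples(self, seq, expected):
        assert count_tna(seq) == expected

    @pytest.mark.parametrize("seq,expected", [
        ("T" * 41, 38),
        ("TTTT" + "G" * 37, 2),
        ("A" * 41, 0),
        ("TTT", 0),          # shorter than the window
    ])
    def test_t_rich_examples(self, seq, expected):
        assert count_t_rich(seq) == expected

    def test_counters_match_bruteforce(self):
        for seq in random_seqs(500, 50, seed=13, alphabet="ACGTN"):
            assert count_tna(seq) == tna_scan(seq)
            assert count_t_rich(seq) == t_rich_scan(seq)


class TestJunctionFolding:
    def test_unpairable_sequence_scores_zero(self):
        assert junction_mfe("A" * 50) == 0.0

    def test_gc_hairpin(self):
        seq = "GGGGAAACCCC" + "A" * 39
        assert junction_mfe(seq) == -12.0  # four G:C pairs

    def test_rich_hairpin_lower_bound(self):
        seq = "GCGCAAAGCGC" + "A" * 39
        assert junction_mfe(seq) <= -8.0

    def test_engine_is_nonpositive(self):
        for seq in random_seqs(20, 50, seed=3):
            assert maxpair_engine(seq) <= 0.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for length in range(5, 15):
            for _ in range(15):
                seq = "".join(rng.choice(list("ACGT"), size=length))
                assert maxpair_engine(seq) == -fold_enumerate(seq), seq

    def test_thermodynamic_engine_contract(self):
        """The pluggable RNAfold engine obeys the engine contract: <= 0 and
        lower for a stable hairpin than for an unstructured sequence."""
        loose = junction_mfe("A" * 50, engine=rnafold_engine)
        hairpin = junction_mfe("GCGCGCGCGC" + "AAAA" + "GCGCGCGCGC", engine=rnafold_engine)
        assert loose <= 0.0
        assert hairpin < -5.0


class TestDirectionalContrasts:
    def test_at_class_has_more_decoys_gc_class_folds_stronger(self, bundle):
        exons = bundle.exons
        feats = {}
        for label in ("GC", "AT"):
            group = [exons[e] for e, t in bundle.truth.items() if t == label]
            feats[label] = exon_signal_features(group, bundle.genome)
        gc, at = feats["GC"], feats["AT"]
        assert at["has_2bp"].mean() > gc["has_2bp"].mean()
        assert at["n_tna"].mean() > gc["n_tna"].mean()
        assert at["n_trich"].mean() > gc["n_trich"].mean()
        assert gc["mfe_5ss"].mean() < at["mfe_5ss"].mean()
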