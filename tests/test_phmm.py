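"""Profile-HMM construction, forward bit-scores and Viterbi decoding,
checked against an exhaustive path-enumeration oracle on tiny instances."""

import numpy as np
import pytest

import ehmmalign as ea
from ehmmalign._kernels import MD, DD, DI
from ehmmalign.phmm import (HmmError, background_frequencies, encode,
                            forward_logprob, viterbi_logprob)
from conftest import (oracle_forward_viterbi, random_query,
                      random_subalignment)


class TestMatchColumns:
    @pytest.mark.parametrize("rows,expected", [
        (["AC", "AC", "AC", "AC"], [0, 1]),          # no gaps: all match
        (["A-", "A-", "A-", "AC"], [0]),             # 3/4 gaps >= 0.5: insert
        (["A-", "A-", "A-", "A-"], [0]),             # all-gap col never match
        (["AC", "A-", "AC", "AC"], [0, 1]),          # 1/4 gaps < 0.5: match
    ])
    def test_gap_fraction_threshold(self, rows, expected):
        aln = ea.MultipleAlignment([f"r{i}" for i in range(len(rows))], rows)
        assert ea.determine_match_columns(aln, 0.5) == expected

    def test_no_match_column_is_an_error(self):
        aln = ea.MultipleAlignment(["a", "b"], ["A-", "-C"])
        with pytest.raises(HmmError):
            ea.determine_match_columns(aln, 0.5)


class TestBuildProfile:
    def test_single_column_emission_pseudocounts(self):
        aln = ea.MultipleAlignment(["a", "b", "c", "d"], ["A", "A", "A", "A"])
        hmm = ea.build_profile_hmm(aln, [0], pseudocount=1.0)
        assert hmm.L == 1
        assert hmm.match_emissions[0, encode("A", "dna")[0]] == \
            pytest.approx((4 + 1) / (4 + 4))

    def test_no_deletions_observed_gives_pseudocount_floor(self):
        aln = ea.MultipleAlignment(["a", "b"], ["ACG", "ACG"])
        hmm = ea.build_profile_hmm(aln, [0, 1, 2], pseudocount=1.0)
        # two rows, both M->M at internal nodes: delete prob = 1/(2+3)
        assert hmm.transitions[MD, :hmm.L - 1] == pytest.approx(
            np.full(hmm.L - 1, 1.0 / 5.0))

    def test_single_row_profile_peaks_on_observed_residues(self):
        aln = ea.MultipleAlignment(["a"], ["ACG"])
        hmm = ea.build_profile_hmm(aln, [0, 1, 2], pseudocount=1.0)
        assert hmm.L == 3
        for j, c in enumerate("ACG"):
            code = encode(c, "dna")[0]
            assert hmm.match_emissions[j, code] == pytest.approx(2 / 5)
            assert hmm.match_emissions[j].argmax() == code

    def test_global_column_map_restricted_to_match_columns(self):
        aln = ea.MultipleAlignment(["a", "b", "c", "d"],
                                   ["AC-G", "AC-G", "ACAG", "A--G"])
        hmm = ea.build_profile_hmm(aln, [2, 5, 7, 9])
        assert hmm.columns.tolist() == [2, 5, 9]  # gappy local column 2 dropped

    @pytest.mark.parametrize("seed", range(8))
    def test_distributions_normalized_on_random_subalignments(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_subalignment(rng, int(rng.integers(2, 7)),
                                  int(rng.integers(1, 9)))
        hmm = ea.build_profile_hmm(aln, list(range(aln.n_columns)))
        assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert hmm.insert_emissions.sum() == pytest.approx(1.0)
        t = hmm.transitions
        for rows, j0 in (((0, 1, 2), 0), ((3, 4, 5), 0), ((6, 7, 8), 1)):
            assert np.allclose(t[list(rows), j0:].sum(axis=0), 1.0, atol=1e-9)

    def test_background_is_addone_smoothed_frequency(self):
        aln = ea.MultipleAlignment(["a", "b"], ["AA", "AC"])
        bg = background_frequencies(aln)
        assert bg[encode("A", "dna")[0]] == pytest.approx((3 + 1) / (4 + 4))
        assert bg[encode("G", "dna")[0]] == pytest.approx(1 / 8)


class TestForwardScore:
    def test_forward_matches_enumeration_on_tiny_profiles(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            aln = random_subalignment(rng, int(rng.integers(1, 5)),
                                      int(rng.integers(1, 4)))
            hmm = ea.build_profile_hmm(aln, list(range(aln.n_columns)))
            query = random_query(rng, int(rng.integers(1, 4)))
            expected, _ = oracle_forward_viterbi(hmm, encode(query.residues,
                                                             "dna"))
            assert forward_logprob(hmm, query) == pytest.approx(expected,
                                                                abs=1e-9)

    def test_uninformative_profile_scores_near_zero_bits(self):
        # match emissions equal background; transitions overwhelmingly M->M
        L, A = 3, 4
        bg = np.full(A, 0.25)
        eps = 1e-9
        t = np.zeros((9, L + 1))
        t[0] = 1 - 2 * eps  # MM
        t[1] = eps          # MI
        t[2, :L] = eps      # MD
        t[0, L] = 1 - eps
        t[3], t[4] = 1 - eps, eps  # IM, II
        t[5, :L] = 0.0
        t[3, L] = 1 - eps
        t[6, 1:], t[7, 1:] = 1 - 2 * eps, eps  # DM, DI
        t[8, 1:L] = eps
        t[6, L], t[7, L] = 1 - eps, eps
        hmm = ea.ProfileHmm("dna", np.tile(bg, (L, 1)), bg.copy(), t, bg,
                            np.arange(L))
        score = ea.forward_bitscore(hmm, ea.Sequence("q", "ACG"))
        # emission odds cancel; only transition/length-model terms remain
        # (the geometric length model alone contributes ~3.2 bits at m=3)
        assert abs(score.bitscore) < 4.0

    def test_consensus_scores_above_its_reversal(self):
        rng = np.random.default_rng(42)
        wins = ties = 0
        letters = ea.ALPHABETS["dna"]
        for _ in range(100):
            aln = random_subalignment(rng, 4, 8, gap_prob=0.1)
            hmm = ea.build_profile_hmm(aln, list(range(aln.n_columns)))
            consensus = "".join(letters[int(hmm.match_emissions[j].argmax())]
                                for j in range(hmm.L))
            fwd = ea.forward_bitscore(hmm, ea.Sequence("c", consensus))
            rev = ea.forward_bitscore(hmm, ea.Sequence("r", consensus[::-1]))
            if fwd.bitscore > rev.bitscore:
                wins += 1
            elif fwd.bitscore == rev.bitscore:
                ties += 1
        assert wins + ties / 2 > 50

    def test_residue_outside_alphabet_rejected(self):
        aln = ea.MultipleAlignment(["a"], ["ACG"], alphabet="dna")
        hmm = ea.build_profile_hmm(aln, [0, 1, 2])
        with pytest.raises(HmmError):
            ea.forward_bitscore(hmm, ea.Sequence("q", "ACU", alphabet="rna"))


class TestViterbi:
    def test_viterbi_bounded_by_forward(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            aln = random_subalignment(rng, int(rng.integers(2, 6)),
                                      int(rng.integers(2, 10)))
            hmm = ea.build_profile_hmm(aln, list(range(aln.n_columns)))
            query = random_query(rng, int(rng.integers(1, 12)))
            assert viterbi_logprob(hmm, query) <= \
                forward_logprob(hmm, query) + 1e-9

    def test_viterbi_matches_enumeration_on_tiny_profiles(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            aln = random_subalignment(rng, int(rng.integers(1, 5)),
                                      int(rng.integers(1, 4)))
            hmm = ea.build_profile_hmm(aln, list(range(aln.n_columns)))
            query = random_query(rng, int(rng.integers(1, 4)))
            _, best = oracle_forward_viterbi(hmm, encode(query.residues, "dna"))
            assert viterbi_logprob(hmm, query) == pytest.approx(best, abs=1e-9)

    def test_consensus_query_maps_to_consecutive_columns(self):
        aln = ea.MultipleAlignment(["a", "b", "c", "d"],
                                   ["ACGT", "ACGT", "ACGT", "ACGA"])
        hmm = ea.build_profile_hmm(aln, [3, 5, 8, 9])
        emap = ea.viterbi_extended_alignment(hmm, ea.Sequence("q", "ACGT"))
        assert emap.matched_col.tolist() == [3, 5, 8, 9]
        assert (emap.slot == -1).all()

    def test_extra_letter_uses_one_insertion_slot(self):
        aln = ea.MultipleAlignment(["a", "b", "c", "d"],
                                   ["ACGT", "ACGT", "ACGT", "ACGT"])
        hmm = ea.build_profile_hmm(aln, [0, 1, 2, 3])
        emap = ea.viterbi_extended_alignment(hmm, ea.Sequence("q", "ACGTT"))
        assert int((emap.slot >= 0).sum()) == 1
        assert int((emap.matched_col >= 0).sum()) == 4

    def test_map_total_and_strictly_increasing_for_random_queries(self):
        rng = np.random.default_rng(9)
        for _ in range(40):
            aln = random_subalignment(rng, int(rng.integers(2, 6)),
                                      int(rng.integers(2, 8)))
            hmm = ea.build_profile_hmm(aln, list(range(aln.n_columns)))
            query = random_query(rng, int(rng.integers(1, 10)))
            emap = ea.viterbi_extended_alignment(hmm, query)
            assert len(emap) == len(query)  # map is total
            matched = emap.matched_col[emap.matched_col >= 0]
            assert (np.diff(matched) > 0).all()
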