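"""Sequence primitives: FULLMAT, the ends-free aligner, translation, conservation."""

import io
import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_ends_free_score, score_alignment
from phytodesk.seqcore import (
    AMINO_ACID,
    NUCLEOTIDE,
    AlphabetError,
    BioSequence,
    CODON_TABLE,
    HYDROPHOBIC,
    NEGATIVE,
    POLAR,
    POSITIVE,
    PairwiseAlignment,
    SubstitutionMatrix,
    build_fullmat,
    classify_substitution,
    conservation_scores,
    ends_free_align,
    read_fasta,
    residue_class,
    translate,
    write_fasta,
)

nt = lambda s, name="q": BioSequence(name, s, NUCLEOTIDE)


class TestBioSequence:
    def test_rejects_characters_outside_alphabet(self):
        with pytest.raises(ValueError, match="not in nucleotide"):
            BioSequence("x", "ACGU", NUCLEOTIDE)
        with pytest.raises(AlphabetError):
            BioSequence("x", "ACGT", "rna")

    def test_one_based_indexing(self):
        s = nt("ACGT")
        assert s[1] == "A" and s[4] == "T"
        with pytest.raises(IndexError):
            s[0]

    def test_reverse_complement(self):
        assert nt("ACGTN").reverse_complement().residues == "NACGT"


class TestFullmat:
    def test_printed_match_and_mismatch_scores(self, nt_matrix):
        assert nt_matrix.score("A", "A") == 5
        assert nt_matrix.score("A", "G") == -4

    @pytest.mark.parametrize("alphabet", [NUCLEOTIDE, AMINO_ACID])
    def test_symmetry_over_all_pairs(self, alphabet):
        m = build_fullmat(alphabet)
        for a in m.symbols:
            for b in m.symbols:
                assert m.score(a, b) == m.score(b, a)
                assert m.score(a, b) == (5 if a == b else -4)

    def test_gap_penalty_inequality(self, nt_matrix):
        # gap open < mismatch < gap extend < match
        assert nt_matrix.gap_open < -4 < nt_matrix.gap_extend < 5

    def test_rejects_unknown_alphabet_and_bad_penalties(self):
        with pytest.raises(AlphabetError):
            build_fullmat("codon")
        with pytest.raises(ValueError, match="gap_open < mismatch"):
            build_fullmat(NUCLEOTIDE, gap_open=-2)

    def test_emboss_text_round_trip(self, nt_matrix):
        again = SubstitutionMatrix.from_text(nt_matrix.to_text())
        assert again.scores == nt_matrix.scores
        assert again.gap_open == nt_matrix.gap_open
        assert again.gap_extend == nt_matrix.gap_extend


class TestEndsFreeAlign:
    def test_single_match_scores_five(self, nt_matrix):
        assert ends_free_align(nt("A"), nt("A", "s"), nt_matrix).score == 5

    def test_empty_query_rides_on_free_end_gaps(self, nt_matrix):
        aln = ends_free_align(nt(""), nt("ACGT", "s"), nt_matrix)
        assert aln.score == 0
        assert aln.query_aligned == "----"
        assert aln.subject_aligned == "ACGT"
        aln.validate()

    def test_three_mers_match_enumeration_oracle(self, nt_matrix):
        aln = ends_free_align(nt("CAC"), nt("CGC", "s"), nt_matrix)
        assert aln.score == brute_force_ends_free_score("CAC", "CGC")

    def test_matches_oracle_on_all_short_binary_pairs(self, nt_matrix):
        seqs = [
            "".join(p)
            for k in range(0, 5)
            for p in itertools.product("AC", repeat=k)
        ]
        for q, s in itertools.product(seqs, repeat=2):
            aln = ends_free_align(nt(q), nt(s, "s"), nt_matrix)
            expected = brute_force_ends_free_score(q, s)
            assert aln.score == expected, (q, s)
            # the reported alignment itself scores what the aligner claims
            assert (
                score_alignment(aln.query_aligned, aln.subject_aligned)
                == aln.score
            )

    @given(st.text(alphabet="ACGT", min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_self_alignment_is_gap_free_perfect(self, residues):
        matrix = build_fullmat(NUCLEOTIDE)
        aln = ends_free_align(nt(residues), nt(residues, "s"), matrix)
        assert aln.score == 5 * len(residues)

    @given(
        st.text(alphabet="ACGT", min_size=0, max_size=12),
        st.text(alphabet="ACGT", min_size=0, max_size=12),
    )
    @settings(max_examples=60, deadline=None)
    def test_score_symmetric_under_sequence_swap(self, a, b):
        matrix = build_fullmat(NUCLEOTIDE)
        fwd = ends_free_align(nt(a), nt(b, "s"), matrix)
        rev = ends_free_align(nt(b), nt(a, "s"), matrix)
        assert fwd.score == rev.score

    def test_agrees_with_biopython_semiglobal(self, nt_matrix, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 5
        aligner.mismatch_score = -4
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -0.5
        aligner.open_end_insertion_score = 0
        aligner.extend_end_insertion_score = 0
        aligner.open_end_deletion_score = 0
        aligner.extend_end_deletion_score = 0
        for _ in range(40):
            q = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 25))))
            s = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 25))))
            ours = ends_free_align(nt(q), nt(s, "s"), nt_matrix).score
            assert ours == aligner.score(s, q)

    def test_deterministic_output(self, nt_matrix):
        a1 = ends_free_align(nt("ACGTACG"), nt("ACGCACG", "s"), nt_matrix)
        a2 = ends_free_align(nt("ACGTACG"), nt("ACGCACG", "s"), nt_matrix)
        assert a1.query_aligned == a2.query_aligned
        assert a1.subject_aligned == a2.subject_aligned

    def test_alphabet_mismatch_rejected(self, aa_matrix):
        with pytest.raises(AlphabetError):
            ends_free_align(nt("ACGT"), nt("ACGT", "s"), aa_matrix)


class TestTranslate:
    def test_all_64_codons_agree_with_standard_code(self):
        for codon in map("".join, itertools.product("ACGT", repeat=3)):
            ours = translate(nt(codon)).residues
            reference = str(Seq(codon).translate())
            assert ours == reference, codon
        assert len(CODON_TABLE) == 64

    def test_start_and_stop_codons(self):
        assert translate(nt("ATG")).residues == "M"
        assert translate(nt("TAA")).residues == "*"

    def test_ambiguous_codon_is_x(self):
        assert translate(nt("GCN")).residues == "X"

    def test_partial_codon_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            translate(nt("ATGG"))


class TestClassifySubstitution:
    def test_degenerate_third_position_is_synonymous(self):
        call = classify_substitution(nt("ATGGCT"), 6, "C")
        assert call.verdict == "synonymous"
        assert call.ref_aa == call.alt_aa == "A"
        assert call.codon_index == 2

    def test_first_position_change_is_nonsynonymous(self):
        call = classify_substitution(nt("ATGGCT"), 4, "A")
        assert call.verdict == "nonsynonymous"
        assert (call.ref_aa, call.alt_aa) == ("A", "T")

    def test_all_nine_mutations_of_a_codon_match_codon_translation(self):
        cds = nt("GCT")
        for pos in (1, 2, 3):
            for alt in "ACGT":
                if alt == cds[pos]:
                    continue
                call = classify_substitution(cds, pos, alt)
                mutant = list("GCT")
                mutant[pos - 1] = alt
                expected = str(Seq("".join(mutant)).translate())
                assert call.alt_aa == expected
                assert (call.verdict == "synonymous") == (
                    call.alt_aa == call.ref_aa
                )

    def test_agrees_with_full_sequence_retranslation(self, rng):
        residues = "".join(rng.choice(list("ACGT"), size=30))
        cds = nt(residues)
        protein = translate(cds).residues
        for _ in range(20):
            pos = int(rng.integers(1, 31))
            alt = str(rng.choice([b for b in "ACGT" if b != cds[pos]]))
            call = classify_substitution(cds, pos, alt)
            mutated = residues[: pos - 1] + alt + residues[pos:]
            new_protein = translate(nt(mutated)).residues
            assert new_protein[call.codon_index - 1] == call.alt_aa
            assert protein[call.codon_index - 1] == call.ref_aa
            assert (call.verdict == "synonymous") == (protein == new_protein)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            classify_substitution(nt("ATG"), 4, "A")
        with pytest.raises(ValueError, match="equals the reference"):
            classify_substitution(nt("ATG"), 1, "A")


class TestConservation:
    def test_fully_conserved_and_fully_diverse_columns(self):
        assert conservation_scores(["A", "A", "A"]) == [1.0]
        assert conservation_scores(["A", "C", "G", "T"]) == [0.25]

    def test_all_gap_column_scores_zero(self):
        assert conservation_scores(["-A", "-A"]) == [0.0, 1.0]

    def test_matches_direct_column_tally(self, rng):
        alphabet = list("ACDEFG-")
        msa = [
            "".join(rng.choice(alphabet, size=20)) for _ in range(5)
        ]
        scores = conservation_scores(msa)
        for col, score in enumerate(scores):
            symbols = [row[col] for row in msa if row[col] != "-"]
            if not symbols:
                assert score == 0.0
            else:
                top = max(symbols.count(c) for c in set(symbols))
                assert score == pytest.approx(top / len(symbols))
        assert all(0 <= s <= 1 for s in scores)

    def test_row_permutation_invariance(self, rng):
        msa = ["ACD-F", "AC-EF", "GCDEF", "ACDE-"]
        scores = conservation_scores(msa)
        perm = [msa[i] for i in rng.permutation(len(msa))]
        assert conservation_scores(perm) == scores

    def test_entropy_variant_bounds(self):
        scores = conservation_scores(["AAAA", "AAAC", "AACG"], method="entropy")
        assert all(0 <= s <= 1 for s in scores)
        assert scores[0] == 1.0

    def test_ragged_msa_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            conservation_scores(["AC", "ACG"])
        with pytest.raises(ValueError, match="at least 2"):
            conservation_scores(["AC"])


class TestResidueClass:
    @pytest.mark.parametrize(
        "aa,expected",
        [("L", "hydrophobic"), ("D", "negatively-charged"),
         ("K", "positively-charged"), ("S", "polar"), ("H", "polar"),
         ("X", "special")],
    )
    def test_canonical_assignments(self, aa, expected):
        assert residue_class(aa) == expected

    def test_classes_partition_the_twenty_residues(self):
        union = HYDROPHOBIC | POLAR | POSITIVE | NEGATIVE
        assert len(union) == 20
        assert sum(map(len, (HYDROPHOBIC, POLAR, POSITIVE, NEGATIVE))) == 20

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            residue_class("B")


class TestAlignmentInvariants:
    def test_validate_flags_structural_errors(self):
        with pytest.raises(ValueError, match="length"):
            PairwiseAlignment("AC", "A", 1, 2, 1, 1).validate()
        with pytest.raises(ValueError, match="gap-vs-gap"):
            PairwiseAlignment("A-", "A-", 1, 1, 1, 1).validate()
        with pytest.raises(ValueError, match="span"):
            PairwiseAlignment("AC", "AC", 1, 3, 1, 2).validate()

    def test_midline_reconstruction(self):
        aln = PairwiseAlignment("AC-G", "ACTG", 1, 3, 1, 4)
        assert aln.midline == "|| |"


def test_fasta_round_trip(tmp_path):
    seqs = [nt("ACGT", "s1"), nt("GGNTA", "s2")]
    path = tmp_path / "seqs.fasta"
    write_fasta(seqs, str(path))
    again = read_fasta(str(path), NUCLEOTIDE)
    assert [(s.id, s.residues) for s in again] == [
        (s.id, s.residues) for s in seqs
    ]


def test_gapped_fasta_preserves_gap_columns():
    text = ">a\nAC-GT\n>b\nACCGT\n"
    rows = read_fasta(io.StringIO(text), AMINO_ACID, gapped=True)
    assert rows == [("a", "AC-GT"), ("b", "ACCGT")]
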