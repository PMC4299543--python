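"""Sequence handling, global alignment and mutation application."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import biotite.sequence as bseq
import biotite.sequence.align as balign

from zymocharge.sequences import (
    AlignmentError,
    Mutation,
    ProteinSequence,
    apply_mutations,
    charge_diff_sites,
    format_mutations,
    global_align,
    parse_mutations,
    percent_identity,
    read_fasta,
    reverse_mutations,
    write_fasta,
)
from oracles import brute_force_global_alignment_score

AA = "ACDEFGHIKLMNPQRSTVWY"

seq_strategy = st.text(alphabet=AA, min_size=1, max_size=6)


def _blosum62_fn():
    alph = bseq.ProteinSequence.alphabet
    mat = balign.SubstitutionMatrix(alph, alph, "BLOSUM62").score_matrix()
    return lambda x, y: float(mat[alph.encode(x), alph.encode(y)])


class TestProteinSequence:
    def test_canonical_numbering(self):
        s = ProteinSequence("s", "IVGGY", first_residue_number=24)
        assert s.residue_at(24) == "I"
        assert s.residue_at(28) == "Y"
        assert s.last_residue_number == 28
        with pytest.raises(IndexError):
            s.residue_at(23)

    def test_rejects_invalid_residues(self):
        with pytest.raises(ValueError):
            ProteinSequence("s", "ACDX1")
        with pytest.raises(ValueError):
            ProteinSequence("s", "")

    def test_subsequence_keeps_numbering(self):
        s = ProteinSequence("s", "MNPLLAPF", 1)
        sub = s.subsequence(3, 5)
        assert sub.residues == "PLL"
        assert sub.first_residue_number == 3


class TestGlobalAlign:
    def test_identical_sequences(self):
        a = ProteinSequence("a", "ACD")
        aln = global_align(a, ProteinSequence("b", "ACD"))
        assert aln.columns == ((0, 0), (1, 1), (2, 2))
        assert percent_identity(aln) == 1.0

    def test_known_ungapped_score(self):
        # K-K scores 5 and R-D scores -2 in BLOSUM62
        aln = global_align(ProteinSequence("a", "KR"), ProteinSequence("b", "KD"))
        assert aln.score == 3.0
        assert aln.columns == ((0, 0), (1, 1))

    def test_gap_cost_convention(self):
        # single gap of length 2: open + 1 * extend
        aln = global_align(
            ProteinSequence("a", "AAA"), ProteinSequence("b", "A"),
            gap_open=10.0, gap_extend=0.5,
        )
        assert aln.score == pytest.approx(4.0 - 10.5)

    def test_unknown_matrix_raises(self):
        with pytest.raises(AlignmentError):
            global_align(ProteinSequence("a", "AA"), ProteinSequence("b", "AA"),
                         matrix="NOSUCHMATRIX")

    def test_score_matches_brute_force_enumeration(self):
        """Optimal affine-gap score equals exhaustive path enumeration on
        random short pairs."""
        rng = np.random.default_rng(12345)
        score_fn = _blosum62_fn()
        for _ in range(60):
            a = "".join(rng.choice(list(AA), rng.integers(1, 7)))
            b = "".join(rng.choice(list(AA), rng.integers(1, 7)))
            go, ge = rng.choice([(10.0, 0.5), (5.0, 1.0), (2.0, 2.0)])
            aln = global_align(ProteinSequence("a", a), ProteinSequence("b", b),
                               gap_open=go, gap_extend=ge)
            expected = brute_force_global_alignment_score(a, b, score_fn, go, ge)
            assert aln.score == pytest.approx(expected), (a, b, go, ge)

    def test_score_matches_biotite_with_integer_penalties(self):
        """Cross-check against biotite's aligner (integer penalties only)."""
        rng = np.random.default_rng(99)
        alph = bseq.ProteinSequence.alphabet
        mat = balign.SubstitutionMatrix(alph, alph, "BLOSUM62")
        for _ in range(20):
            a = "".join(rng.choice(list(AA), rng.integers(3, 30)))
            b = "".join(rng.choice(list(AA), rng.integers(3, 30)))
            ours = global_align(ProteinSequence("a", a), ProteinSequence("b", b),
                                gap_open=10.0, gap_extend=1.0)
            ref = balign.align_optimal(
                bseq.ProteinSequence(a), bseq.ProteinSequence(b), mat,
                gap_penalty=(-10, -1), terminal_penalty=True, max_number=1,
            )[0]
            assert ours.score == pytest.approx(ref.score)


class TestPercentIdentity:
    def test_half_identical(self):
        aln = global_align(ProteinSequence("a", "AA"), ProteinSequence("b", "AG"))
        assert percent_identity(aln) == 0.5

    @given(seq_strategy, seq_strategy)
    def test_symmetric(self, a, b):
        ab = global_align(ProteinSequence("x", a), ProteinSequence("y", b))
        ba = global_align(ProteinSequence("p", b), ProteinSequence("q", a))
        assert percent_identity(ab) == pytest.approx(percent_identity(ba))

    def test_denominator_conventions(self):
        aln = global_align(ProteinSequence("a", "AAAA"), ProteinSequence("b", "AA"))
        assert percent_identity(aln, "paired") == 1.0
        assert percent_identity(aln, "shorter") == 1.0
        assert percent_identity(aln, "columns") == 0.5


class TestChargeDiffSites:
    @given(seq_strategy)
    def test_self_alignment_has_no_sites(self, s):
        aln = global_align(ProteinSequence("a", s), ProteinSequence("b", s))
        assert charge_diff_sites(aln) == []

    def test_single_forced_site(self):
        aln = global_align(ProteinSequence("a", "EK"), ProteinSequence("b", "KK"))
        (site,) = charge_diff_sites(aln)
        assert site.canonical_position == 1
        assert (site.target_residue, site.homolog_residue) == ("E", "K")
        assert site.delta_charge == 2

    def test_positions_use_target_numbering(self):
        a = ProteinSequence("a", "EK", first_residue_number=79)
        aln = global_align(a, ProteinSequence("b", "KK"))
        assert charge_diff_sites(aln)[0].canonical_position == 79


class TestMutations:
    def test_parse_and_format_roundtrip(self):
        muts = parse_mutations("E79K, R122K D153K")
        assert [str(m) for m in muts] == ["E79K", "R122K", "D153K"]
        assert format_mutations(muts) == "E79K, R122K, D153K"

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError):
            parse_mutations("E79K E79A")

    def test_apply_respects_canonical_offset(self):
        s = ProteinSequence("s", "AEA", first_residue_number=78)
        out = apply_mutations(s, parse_mutations("E79K"))
        assert out.residues == "AKA"

    def test_empty_set_is_identity(self):
        s = ProteinSequence("s", "ACD")
        assert apply_mutations(s, []).residues == "ACD"

    def test_from_residue_mismatch_raises(self):
        s = ProteinSequence("s", "ACD")
        with pytest.raises(ValueError, match="numbering offset"):
            apply_mutations(s, [Mutation(2, "G", "K")])

    @given(st.data())
    def test_reverse_set_restores_sequence(self, data):
        s = data.draw(st.text(alphabet=AA, min_size=3, max_size=20))
        seq = ProteinSequence("s", s)
        n_mut = data.draw(st.integers(1, min(5, len(s))))
        positions = data.draw(
            st.lists(st.integers(1, len(s)), min_size=n_mut, max_size=n_mut,
                     unique=True)
        )
        muts = []
        for p in positions:
            old = seq.residue_at(p)
            new = data.draw(st.sampled_from([x for x in AA if x != old]))
            muts.append(Mutation(p, old, new))
        mutated = apply_mutations(seq, muts)
        assert apply_mutations(mutated, reverse_mutations(muts)).residues == s


class TestFasta:
    def test_roundtrip_with_numbering(self, tmp_path):
        path = tmp_path / "seqs.fasta"
        seqs = [
            ProteinSequence("zymogen", "APFDDDDK" + "IVGGY" * 20, 16),
            ProteinSequence("plain", "ACDEFGH"),
        ]
        write_fasta(seqs, path)
        back = read_fasta(path)
        assert [s.id for s in back] == ["zymogen", "plain"]
        assert back[0].residues == seqs[0].residues
        assert back[0].first_residue_number == 16
        assert back[1].first_residue_number == 1
        # 60-column wrapping
        body = path.read_text().splitlines()
        assert max(len(line) for line in body if not line.startswith(">")) == 60
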