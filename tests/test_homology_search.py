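import math
import random

import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from thiocomp.homology_search import (
    ScoringScheme,
    evalue,
    seed_extend_align,
    smith_waterman,
    translated_search,
)
from thiocomp.io_formats import SeqRecord
from thiocomp.seq_core import reverse_complement


def _rand(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutate(rng, s, d):
    return "".join(
        rng.choice([x for x in "ACGT" if x != c]) if rng.random() < d else c for c in s
    )


def _nt_oracle(scheme: ScoringScheme) -> PairwiseAligner:
    return PairwiseAligner(
        mode="local",
        match_score=scheme.match,
        mismatch_score=scheme.mismatch,
        open_gap_score=-(scheme.gap_open + scheme.gap_extend),
        extend_gap_score=-scheme.gap_extend,
    )


def _raw_from_bits(bits: float, scheme: ScoringScheme) -> float:
    return (bits * math.log(2) + math.log(scheme.K)) / scheme.lam


class TestEvalue:
    def test_unit_expectation(self):
        # 2^-S * mn == 1 exactly when S = log2(mn)
        mn = 1 << 20
        assert evalue(20.0, mn) == pytest.approx(1.0)

    def test_ten_bits_divide_by_1024(self):
        assert evalue(60.0, 1e6) == pytest.approx(evalue(50.0, 1e6) / 1024)

    def test_closed_form_value(self):
        assert evalue(50.0, 1e6) == pytest.approx(8.9e-10, rel=1e-2)

    def test_monotone_in_score_and_space(self):
        assert evalue(51.0, 1e6) < evalue(50.0, 1e6)
        assert evalue(50.0, 2e6) == pytest.approx(2 * evalue(50.0, 1e6))

    def test_nonfinite_score_rejected(self):
        with pytest.raises(ValueError):
            evalue(float("nan"), 1e6)


class TestSmithWaterman:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_oracle_nucleotide(self, seed):
        rng = random.Random(seed)
        scheme = ScoringScheme.nucleotide()
        a = _rand(rng, rng.randint(50, 600))
        core = _rand(rng, 200)
        b = _rand(rng, 100) + _mutate(rng, core, 0.2) + _rand(rng, 100)
        if seed % 2 == 0:
            a = _rand(rng, 80) + core + _rand(rng, 80)
        aln = smith_waterman(a, b, scheme)
        oracle = _nt_oracle(scheme).score(a, b)
        assert (aln.score if aln else 0) == oracle

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_independent_oracle_protein(self, seed):
        rng = random.Random(100 + seed)
        scheme = ScoringScheme.protein()
        aa = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(aa) for _ in range(rng.randint(40, 200)))
        b = "".join(rng.choice(aa) for _ in range(rng.randint(40, 200)))
        pa = PairwiseAligner(
            mode="local",
            substitution_matrix=substitution_matrices.load("BLOSUM62"),
            open_gap_score=-12,
            extend_gap_score=-1,
        )
        aln = smith_waterman(a, b, scheme)
        assert (aln.score if aln else 0) == pa.score(a, b)

    def test_score_symmetry(self):
        rng = random.Random(42)
        scheme = ScoringScheme.nucleotide()
        for _ in range(5):
            a, b = _rand(rng, 300), _rand(rng, 300)
            sa = smith_waterman(a, b, scheme)
            sb = smith_waterman(b, a, scheme)
            assert (sa.score if sa else 0) == (sb.score if sb else 0)

    def test_empty_sequences(self):
        assert smith_waterman("", "ACGT", ScoringScheme.nucleotide()) is None


class TestSeedExtend:
    def test_self_alignment_full_span_full_identity(self):
        rng = random.Random(1)
        s = _rand(rng, 1000)
        hits = seed_extend_align(SeqRecord("q", s), SeqRecord("s", s))
        top = max(hits, key=lambda h: h.bit_score)
        assert top.percent_identity == 100.0
        assert (top.q_start, top.q_end) == (1, 1000)
        assert (top.s_start, top.s_end) == (1, 1000)
        # bit score is the maximum the scheme allows for this length
        scheme = ScoringScheme.nucleotide()
        assert _raw_from_bits(top.bit_score, scheme) == pytest.approx(
            1000 * scheme.match, abs=0.5
        )

    def test_planted_segment_score_equals_full_smith_waterman(self):
        rng = random.Random(2)
        scheme = ScoringScheme.nucleotide()
        planted = _rand(rng, 600)
        subject = _rand(rng, 5000) + _mutate(rng, planted, 0.30) + _rand(rng, 4400)
        hits = seed_extend_align(SeqRecord("q", planted), SeqRecord("s", subject))
        top = max(hits, key=lambda h: h.bit_score)
        oracle = _nt_oracle(scheme).score(planted, subject)
        assert _raw_from_bits(top.bit_score, scheme) == pytest.approx(oracle, abs=0.5)
        # the hit covers at least 90% of the planted segment
        assert (top.q_end - top.q_start + 1) >= 0.9 * 600

    def test_reverse_complement_reported_on_minus_strand(self):
        rng = random.Random(3)
        planted = _rand(rng, 600)
        subject = _rand(rng, 2000) + planted + _rand(rng, 2000)
        hits = seed_extend_align(
            SeqRecord("q", reverse_complement(planted)), SeqRecord("s", subject)
        )
        top = max(hits, key=lambda h: h.bit_score)
        assert top.s_start > top.s_end
        assert top.subject_span() == (2001, 2600)

    def test_empty_query_yields_no_hits(self):
        assert seed_extend_align(SeqRecord("q", "A"), SeqRecord("s", "")) == []


_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_SYN = {
    "GCT": "GCC", "TGT": "TGC", "GAT": "GAC", "GAA": "GAG", "TTT": "TTC",
    "GGT": "GGC", "CAT": "CAC", "ATT": "ATC", "AAA": "AAG", "TTA": "TTG",
    "AAT": "AAC", "CCT": "CCC", "CAA": "CAG", "CGT": "CGC", "TCT": "TCC",
    "ACT": "ACC", "GTT": "GTC", "TAT": "TAC",
}


class TestTranslatedSearch:
    def _protein(self, rng, n):
        return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n))

    def test_exact_back_translation_hits_frame_one(self):
        rng = random.Random(4)
        prot = self._protein(rng, 120)
        nt = "".join(_CODON[a] for a in prot)
        hits = translated_search(SeqRecord("p", prot), SeqRecord("n", nt))
        top = max(hits, key=lambda h: h.bit_score)
        assert top.frame == 1
        assert top.percent_identity == 100.0
        assert (top.s_start, top.s_end) == (1, len(nt))

    def test_synonymous_codon_changes_are_invisible(self):
        rng = random.Random(5)
        prot = self._protein(rng, 120)
        codons = [_CODON[a] for a in prot]
        swapped = [
            _SYN.get(c, c) if rng.random() < 0.3 else c for c in codons
        ]
        hits = translated_search(SeqRecord("p", prot), SeqRecord("n", "".join(swapped)))
        top = max(hits, key=lambda h: h.bit_score)
        assert top.percent_identity == 100.0

    def test_minus_frame_coordinates(self):
        rng = random.Random(6)
        prot = self._protein(rng, 100)
        nt = "".join(_CODON[a] for a in prot)
        subject = _rand(rng, 333) + reverse_complement(nt) + _rand(rng, 200)
        hits = translated_search(SeqRecord("p", prot), SeqRecord("n", subject))
        top = max(hits, key=lambda h: h.bit_score)
        assert top.frame < 0
        assert top.s_start > top.s_end
        assert top.subject_span() == (334, 333 + len(nt))

    def test_evalue_scales_with_subject_length(self):
        rng = random.Random(7)
        prot = self._protein(rng, 100)
        nt = "".join(_CODON[a] for a in prot)
        pad = _rand(rng, len(nt))
        h1 = max(
            translated_search(SeqRecord("p", prot), SeqRecord("n", nt)),
            key=lambda h: h.bit_score,
        )
        h2 = max(
            translated_search(SeqRecord("p", prot), SeqRecord("n", nt + pad)),
            key=lambda h: h.bit_score,
        )
        # same alignment, doubled raw search space m x n
        assert h2.bit_score == h1.bit_score
        assert h2.e_value == pytest.approx(2 * h1.e_value)


def test_unknown_scoring_parameters_need_explicit_constants():
    with pytest.raises(ValueError, match="Karlin-Altschul"):
        ScoringScheme.nucleotide(match=7, mismatch=-5)
    scheme = ScoringScheme.nucleotide(match=7, mismatch=-5, lam=0.3, K=0.1)
    assert scheme.lam == 0.3
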