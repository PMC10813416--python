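import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbminer import seqcore as sc

from ._oracles import global_score_enumerate, local_score_enumerate

dna = st.text(alphabet="ACGT", min_size=1, max_size=6)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("TTAA", "TTAA"), ("CACTA", "TAGTG"), ("N", "N"), ("ACGT", "ACGT")],
    )
    def test_known_values(self, seq, expected):
        assert sc.reverse_complement(seq) == expected

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=50))
    def test_involution(self, seq):
        assert sc.reverse_complement(sc.reverse_complement(seq)) == seq

    def test_rejects_non_iupac(self):
        with pytest.raises(sc.InvalidSequenceError):
            sc.reverse_complement("ACGU")


class TestSixFrameTranslate:
    def test_codon_table(self):
        frames = sc.six_frame_translate(sc.NucSequence("x", "ATGAAATAA"))
        plus1 = next(f for f in frames if f.frame == 1)
        assert plus1.protein.residues == "MK*"

    def test_minus_frames_equal_revcomp_plus(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        nuc = sc.NucSequence("x", seq)
        rc = sc.reverse_complement(nuc)
        fwd = {f.frame: f.protein.residues for f in sc.six_frame_translate(nuc)}
        rev = {f.frame: f.protein.residues for f in sc.six_frame_translate(rc)}
        for k in (1, 2, 3):
            assert fwd[-k] == rev[k]

    def test_coordinate_backmap_is_three_per_residue(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=47))
        for f in sc.six_frame_translate(sc.NucSequence("x", seq)):
            for p0, p1 in [(0, 1), (2, 5), (0, len(f.protein))]:
                if p1 > len(f.protein):
                    continue
                s, e = f.nuc_span(p0, p1)
                assert e - s == 3 * (p1 - p0)
                assert 0 <= s <= e <= len(seq)

    def test_too_short_rejected(self):
        with pytest.raises(sc.InvalidSequenceError):
            sc.six_frame_translate(sc.NucSequence("x", "AT"))


class TestAligners:
    def test_blosum_self_alignment(self):
        res = sc.smith_waterman("AAAA", "AAAA", protein=True)
        assert res.score == 16.0 and res.identity == 1.0

    def test_disjoint_alphabet_empty_local(self):
        res = sc.smith_waterman("AAAA", "TTTT")
        assert res.is_empty and res.score == 0.0

    def test_global_identity_extremes(self):
        assert sc.needleman_wunsch("ACGTACGT", "ACGTACGT").identity == 1.0
        assert sc.needleman_wunsch("AAAA", "TTTT").identity == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(sc.InvalidSequenceError):
            sc.smith_waterman("", "ACGT")

    def test_local_score_symmetric(self, rng):
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=8))
            b = "".join(rng.choice(list("ACGT"), size=8))
            assert sc.smith_waterman(a, b).score == sc.smith_waterman(b, a).score

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(dna, dna)
    def test_local_matches_exhaustive_enumeration(self, a, b):
        assert sc.smith_waterman(a, b).score == local_score_enumerate(a, b)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(dna, dna)
    def test_global_matches_exhaustive_enumeration(self, a, b):
        assert sc.needleman_wunsch(a, b).score == global_score_enumerate(a, b)

    def test_identity_and_coverage_bounds(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=30))
            b = "".join(rng.choice(list("ACGT"), size=25))
            for res in (sc.smith_waterman(a, b), sc.needleman_wunsch(a, b)):
                assert 0.0 <= res.identity <= 1.0
                assert 0.0 <= res.coverage_query <= 1.0

    def test_gap_column_consistency(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=40))
        b = "".join(rng.choice(list("ACGT"), size=40))
        res = sc.needleman_wunsch(a, b)
        stripped = [
            (x, y)
            for x, y in zip(res.aligned_query, res.aligned_subject)
            if x != "-" and y != "-"
        ]
        matches = sum(1 for x, y in stripped if x == y)
        total_matches = sum(
            1 for x, y in zip(res.aligned_query, res.aligned_subject) if x == y and x != "-"
        )
        assert matches == total_matches  # matches only occur in gap-free columns


class TestEvalue:
    def test_closed_form(self):
        e = sc.karlin_altschul_evalue(100, 500, 10**6, K=0.041, lam=0.267)
        assert e == pytest.approx(0.041 * 500 * 1e6 * math.exp(-0.267 * 100), rel=1e-12)
        assert e == pytest.approx(5.1e-5, rel=0.05)

    def test_linear_in_database_size(self):
        assert sc.karlin_altschul_evalue(50, 100, 2_000_000) == pytest.approx(
            2 * sc.karlin_altschul_evalue(50, 100, 1_000_000)
        )

    def test_vanishes_at_high_score(self):
        assert sc.karlin_altschul_evalue(10_000, 100, 10**9) < 1e-300

    def test_monotone_decreasing_in_score(self):
        es = [sc.karlin_altschul_evalue(s, 100, 10**6) for s in (10, 20, 40, 80)]
        assert es == sorted(es, reverse=True)

    def test_invalid_search_space(self):
        with pytest.raises(ValueError):
            sc.karlin_altschul_evalue(10, 0, 100)


class TestFasta:
    def test_round_trip_with_wrapping(self, tmp_path, rng):
        seqs = [
            sc.NucSequence("a", "".join(rng.choice(list("ACGT"), size=150)), "descr one"),
            sc.NucSequence("b", "acgt" * 5),  # lowercase tolerated, normalized
        ]
        p = tmp_path / "x.fasta"
        sc.write_fasta(p, seqs)
        text = p.read_text()
        assert max(len(l) for l in text.splitlines()) <= 61
        back = sc.read_fasta(p)
        assert [s.id for s in back] == ["a", "b"]
        assert back[0].residues == seqs[0].residues
        assert back[1].residues == "ACGT" * 5


class TestCenterStar:
    def test_identical_members_no_gaps(self):
        rows = sc.center_star_msa("ACGTACGT", ["ACGTACGT", "ACGTACGT"])
        assert all(r == "ACGTACGT" for r in rows)

    def test_center_row_preserves_center(self, rng):
        center = "".join(rng.choice(list("ACGT"), size=50))
        others = [center[:20] + center[25:], center[5:], "ACGT" + center]
        rows = sc.center_star_msa(center, others)
        assert rows[0].replace("-", "") == center
        assert len({len(r) for r in rows}) == 1
        assert len(rows[0]) >= len(center)

    def test_majority_consensus_recovers_center(self, rng):
        center = "".join(rng.choice(list("ACGT"), size=200))
        mutated = []
        for _ in range(4):
            m = list(center)
            for i in rng.choice(len(m), size=6, replace=False):
                m[i] = "ACGT"[(("ACGT".index(m[i])) + 1) % 4]
            mutated.append("".join(m))
        rows = sc.center_star_msa(center, mutated)
        cons = sc.majority_consensus(rows)
        mismatches = sum(1 for x, y in zip(cons, center) if x != y)
        assert len(cons) == len(center) and mismatches <= 2
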