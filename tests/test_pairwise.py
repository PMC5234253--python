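import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, strategies as st

from oracles import gotoh_score
from ohnotrace.genome_db import GenomeDB, GenomeRecord, OrfRecord
from ohnotrace.pairwise import (
    AlignmentParams,
    align_global,
    align_local,
    all_vs_all,
    evalue_from_score,
    group_identity_summary,
    read_hits,
    write_hits,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
B62 = substitution_matrices.load("BLOSUM62")
PAPER_PARAMS = AlignmentParams()  # BLOSUM62, gap open -1, extend -1


def b62(x, y):
    return float(B62[x, y])


def random_peptides(seed, n_pairs, max_len=12):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_pairs):
        la, lb = rng.integers(1, max_len + 1, size=2)
        out.append((
            "".join(rng.choice(list(AA), la)),
            "".join(rng.choice(list(AA), lb)),
        ))
    return out


class TestAlignLocal:
    def test_identity_quad(self):
        score, ident, length = align_local("AAAA", "AAAA", PAPER_PARAMS)
        assert score == 4 * b62("A", "A") == 16
        assert ident == 100.0 and length == 4

    @pytest.mark.parametrize("pair", random_peptides(11, 50))
    def test_matches_reference_dp(self, pair):
        a, b = pair
        score, _, _ = align_local(a, b, PAPER_PARAMS)
        assert score == gotoh_score(a, b, b62, -1, -1, "local")

    def test_symmetric(self):
        for a, b in random_peptides(3, 10):
            sa, *_ = align_local(a, b, PAPER_PARAMS)
            sb, *_ = align_local(b, a, PAPER_PARAMS)
            assert sa == sb

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_local("", "MKV", PAPER_PARAMS)


class TestAlignGlobal:
    def test_identical_sequences(self):
        st_ = align_global("MKVLA", "MKVLA")
        assert st_.identity_pct == 100.0 and st_.gap_pct == 0.0

    def test_hand_example_acde_ace(self):
        # optimal alignment ACDE / AC-E: 3 matches over 4 columns
        st_ = align_global("ACDE", "ACE", matrix=None, match=1, mismatch=-1,
                           gap_open=-2, gap_extend=-2)
        assert st_.identity_pct == 75.0
        assert st_.gap_pct == 25.0
        assert st_.aln_length == 4

    @pytest.mark.parametrize("pair", random_peptides(12, 25))
    def test_score_matches_reference_dp(self, pair):
        # identity/gap percentages derive from the optimal-score alignment;
        # cross-check the optimum itself against the reference DP
        from Bio import Align

        a, b = pair
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.substitution_matrix = B62
        al.open_gap_score = -5
        al.extend_gap_score = -2
        assert al.score(a, b) == gotoh_score(a, b, b62, -5, -2, "global")

    def test_swap_invariance(self):
        for a, b in random_peptides(4, 10):
            s1 = align_global(a, b)
            s2 = align_global(b, a)
            assert (s1.identity_pct, s1.gap_pct, s1.aln_length) == (
                s2.identity_pct, s2.gap_pct, s2.aln_length
            )

    def test_column_accounting_sums_to_100(self):
        for a, b in random_peptides(5, 10):
            st_ = align_global(a, b)
            assert 0.0 <= st_.identity_pct <= 100.0
            assert 0.0 <= st_.gap_pct <= 100.0
            assert st_.identity_pct + st_.gap_pct <= 100.0 + 1e-9


class TestEvalue:
    def test_closed_form_value(self):
        expected = 0.041 * 500 * 500 * math.exp(-0.267 * 100)  # ~2.6e-8
        got = evalue_from_score(100, 500, 500, PAPER_PARAMS)
        assert got == pytest.approx(expected, rel=1e-6)
        assert got == pytest.approx(2.6e-8, rel=0.01)

    def test_zero_score_limit(self):
        assert evalue_from_score(0, 30, 40, PAPER_PARAMS) == pytest.approx(
            0.041 * 30 * 40, rel=1e-9
        )

    @given(
        s1=st.floats(-50, 400), ds=st.floats(1e-3, 100),
        m=st.integers(1, 10**6), n=st.integers(1, 10**6),
    )
    def test_monotone_in_score_and_sizes(self, s1, ds, m, n):
        e1 = evalue_from_score(s1, m, n, PAPER_PARAMS)
        e2 = evalue_from_score(s1 + ds, m, n, PAPER_PARAMS)
        assert e2 < e1
        assert evalue_from_score(s1, m + 1, n, PAPER_PARAMS) > e1
        assert evalue_from_score(s1, m, n + 1, PAPER_PARAMS) > e1

    def test_bad_constants_rejected(self):
        with pytest.raises(ValueError):
            AlignmentParams(ka_lambda=-1.0)


def _db_of(seqs):
    orfs = [OrfRecord(f"aaaa_1_g{i}", "aaaa", 1, "s1", i, "+", s) for i, s in enumerate(seqs)]
    return GenomeDB([GenomeRecord("aaaa", 1, "pre", orfs)])


class TestAllVsAll:
    def test_identical_triplet_gives_all_ordered_pairs(self):
        db = _db_of(["MKVLAWWCE"] * 3)
        hits = all_vs_all(db, PAPER_PARAMS)
        assert len(hits) == 6
        assert all(h.identity_pct == 100.0 for h in hits)
        assert all(h.query_id != h.subject_id for h in hits)

    def test_single_orf_empty(self):
        assert all_vs_all(_db_of(["MKVLA"]), PAPER_PARAMS) == []

    def test_report_ceiling_filters(self):
        # two unrelated short peptides: e-value above ceiling, no hit kept
        db = _db_of(["MKMKMKMK", "WCWCWCWC"])
        params = AlignmentParams(evalue_ceiling=1e-3)
        assert all_vs_all(db, params) == []

    def test_hit_table_round_trip(self, tmp_path):
        db = _db_of(["MKVLAWWCE", "MKVLAWWCE", "MKVLACHCE"])
        hits = all_vs_all(db, PAPER_PARAMS)
        write_hits(hits, tmp_path / "h.tsv")
        back = read_hits(tmp_path / "h.tsv")
        assert {(h.query_id, h.subject_id) for h in back} == {
            (h.query_id, h.subject_id) for h in hits
        }
        for h1, h2 in zip(sorted(hits, key=lambda h: (h.query_id, h.subject_id)),
                          sorted(back, key=lambda h: (h.query_id, h.subject_id))):
            assert h2.evalue == pytest.approx(h1.evalue, rel=1e-3)
            assert h2.identity_pct == pytest.approx(h1.identity_pct, abs=0.01)


class TestGroupIdentitySummary:
    def test_identical_singletons(self):
        db = _db_of(["MKVLAWWCE", "MKVLAWWCE"])
        mi, mg, n = group_identity_summary(["aaaa_1_g0"], ["aaaa_1_g1"], db)
        assert (mi, mg, n) == (100.0, 0.0, 1)

    def test_mean_over_cross_pairs(self):
        seqs = ["MKVLAW", "MKVLAC", "MKVQAW", "WWWWWW"]
        db = _db_of(seqs)
        ga, gb = ["aaaa_1_g0", "aaaa_1_g1"], ["aaaa_1_g2", "aaaa_1_g3"]
        vals = [align_global(db[x].protein_seq, db[y].protein_seq).identity_pct
                for x in ga for y in gb]
        mi, _, n = group_identity_summary(ga, gb, db)
        assert n == 4
        assert mi == pytest.approx(sum(vals) / 4)

    def test_same_group_uses_unordered_pairs(self):
        db = _db_of(["MKVLAW", "MKVLAC", "MKVQAW"])
        ids = list(db.orf_index)
        _, _, n = group_identity_summary(ids, ids, db)
        assert n == 3  # C(3,2)

    def test_empty_group_rejected(self):
        db = _db_of(["MKVLAW"])
        with pytest.raises(ValueError):
            group_identity_summary([], ["aaaa_1_g0"], db)
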