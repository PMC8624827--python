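"""Homology index, BLAST tabular I/O and the internal aligner."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from homolineage.errors import DomainError, ParseError, ValidationError
from homolineage.pairscore import (
    AA_ALPHABET,
    PairHit,
    ProteinRecord,
    align_pair,
    all_vs_all_hits,
    build_hi_graph,
    compute_hi,
    make_aligner,
    per_query_hit_counts,
    read_blast_tabular,
    write_blast_tabular,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _tab_line(q="g1", s="g2", pident="50.0", length="100", qlen="100", slen="100"):
    return "\t".join(
        [q, s, pident, length, "50", "0", "1", length, "1", length, "1e-30", "200",
         qlen, slen]
    )


class TestComputeHI:
    @pytest.mark.parametrize(
        "pident,aln_len,qlen,slen,expected",
        [
            (100.0, 120, 120, 120, 1.0),   # perfect full-length match
            (50.0, 100, 100, 100, 0.5),    # half the residues identical
            (100.0, 50, 100, 100, 0.5),    # half-length perfect match
            (100.0, 200, 100, 100, 1.0),   # clamp: gappy overlong alignment
            (25.0, 80, 100, 60, 2 * 0.25 * 80 / 160),
        ],
    )
    def test_formula(self, pident, aln_len, qlen, slen, expected):
        assert compute_hi(pident, aln_len, qlen, slen) == pytest.approx(expected, abs=1e-15)

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(DomainError):
            compute_hi(50.0, 0, 100, 100)
        with pytest.raises(DomainError):
            compute_hi(50.0, 10, 0, 100)

    def test_out_of_range_identity_rejected(self):
        with pytest.raises(ValidationError):
            compute_hi(120.0, 10, 10, 10)

    @given(
        pident=st.floats(0, 100),
        aln_len=st.integers(1, 5000),
        qlen=st.integers(1, 5000),
        slen=st.integers(1, 5000),
    )
    def test_bounds(self, pident, aln_len, qlen, slen):
        assert 0.0 <= compute_hi(pident, aln_len, qlen, slen) <= 1.0


class TestBlastTabular:
    def test_reads_hits_and_self_hits(self, tmp_path):
        path = tmp_path / "hits.tab"
        path.write_text(
            "# comment\n"
            + _tab_line() + "\n"
            + _tab_line(q="g1", s="g1", pident="100.0", length="120",
                        qlen="120", slen="120") + "\n"
        )
        hits = read_blast_tabular(path)
        assert len(hits) == 2
        assert hits[0].hi == pytest.approx(0.5)
        assert not hits[0].is_self
        assert hits[1].is_self and hits[1].hi == 1.0
        assert per_query_hit_counts(hits) == {"g1": 2}

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "bad.tab"
        path.write_text(_tab_line() + "\textra\n")
        with pytest.raises(ParseError, match=":1"):
            read_blast_tabular(path)

    def test_non_numeric_field(self, tmp_path):
        path = tmp_path / "bad.tab"
        path.write_text(_tab_line(pident="high") + "\n")
        with pytest.raises(ParseError, match=":1"):
            read_blast_tabular(path)

    def test_identity_out_of_range(self, tmp_path):
        path = tmp_path / "bad.tab"
        path.write_text(_tab_line(pident="101.0") + "\n")
        with pytest.raises(ValidationError):
            read_blast_tabular(path)

    def test_roundtrip_preserves_hi_exactly(self, tmp_path, rng):
        hits = []
        for i in range(50):
            qlen = int(rng.integers(60, 400))
            slen = int(rng.integers(60, 400))
            aln = int(rng.integers(30, min(qlen, slen) + 1))
            pident = float(rng.uniform(5, 100))
            hits.append(
                PairHit(f"q{i}", f"s{i}", pident, aln, qlen, slen,
                        compute_hi(pident, aln, qlen, slen))
            )
        path = tmp_path / "rt.tab"
        write_blast_tabular(hits, path, header_lines=["provenance"])
        back = read_blast_tabular(path)
        assert [h.hi for h in back] == [h.hi for h in hits]


class TestAlignPair:
    def test_identical_sequences_score_one(self, toy_records):
        a = toy_records[0]
        b = ProteinRecord("other", "spZ", a.sequence)
        assert align_pair(a, b).hi == 1.0

    def test_disjoint_alphabets_score_zero_locally(self):
        a = ProteinRecord("w", "s1", "WWWWWWWWWW")
        b = ProteinRecord("g", "s2", "GGGGGGGGGG")
        hit = align_pair(a, b, mode="local")
        assert hit.hi == 0.0 and hit.aln_len == 0

    def test_symmetric_under_argument_order(self, toy_records):
        for x in toy_records:
            for y in toy_records:
                assert align_pair(x, y).hi == align_pair(y, x).hi

    def test_empty_sequence_rejected(self, toy_records):
        with pytest.raises(ValidationError):
            ProteinRecord("e", "s", "")

    def test_scores_match_gotoh_oracle(self, rng):
        """The aligner's optimal local score equals an independently
        written Gotoh dynamic program on random short peptides."""
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")

        def gotoh(s1, s2, gap_first=12, gap_ext=1):
            n, m = len(s1), len(s2)
            NEG = float("-inf")
            M = [[0.0] * (m + 1) for _ in range(n + 1)]
            X = [[NEG] * (m + 1) for _ in range(n + 1)]
            Y = [[NEG] * (m + 1) for _ in range(n + 1)]
            best = 0.0
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    X[i][j] = max(M[i - 1][j] - gap_first, X[i - 1][j] - gap_ext)
                    Y[i][j] = max(M[i][j - 1] - gap_first, Y[i][j - 1] - gap_ext)
                    sub = blosum[s1[i - 1], s2[j - 1]]
                    M[i][j] = max(
                        0.0,
                        sub + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]),
                    )
                    best = max(best, M[i][j])
            return best

        aligner = make_aligner(mode="local")
        for _ in range(15):
            s1 = "".join(rng.choice(list(AA20), size=int(rng.integers(10, 30))))
            s2 = "".join(rng.choice(list(AA20), size=int(rng.integers(10, 30))))
            assert aligner.score(s1, s2) == pytest.approx(gotoh(s1, s2))

    def test_hand_computed_hi_on_unambiguous_alignment(self):
        """An identical block in mismatching flanks: the local optimum
        is the block itself, so pident/aln_len/hi follow by hand."""
        core = "MKTAYIAKQRQISFVKSHFSRQ"
        a = ProteinRecord("a", "s1", "WWW" + core + "WWW")
        b = ProteinRecord("b", "s2", "GGG" + core + "GGG")
        hit = align_pair(a, b, mode="local")
        assert hit.pident == 100.0
        assert hit.aln_len == len(core)
        assert hit.hi == pytest.approx(2 * len(core) / (len(a) + len(b)))


class TestHIGraph:
    def test_empty_hits_give_empty_graph(self):
        g = build_hi_graph([])
        assert g.n_genes == 0 and g.n_edges == 0

    def test_max_collapse_of_bidirectional_hits(self):
        hits = [
            PairHit("g1", "g2", 40.0, 100, 100, 100, 0.4),
            PairHit("g2", "g1", 60.0, 100, 100, 100, 0.6),
        ]
        g = build_hi_graph(hits)
        assert g.n_edges == 1 and g.hi("g1", "g2") == 0.6

    def test_self_hits_dropped(self):
        g = build_hi_graph([PairHit("g1", "g1", 100.0, 50, 50, 50, 1.0)])
        assert g.n_genes == 1 and g.n_edges == 0

    def test_direction_invariance_matches_dict_oracle(self, rng):
        """Edge set equals a brute-force max-per-unordered-pair dict,
        whichever direction each hit arrives in."""
        genes = [f"g{i}" for i in range(8)]
        raw = []
        oracle: dict[frozenset, float] = {}
        for _ in range(60):
            a, b = rng.choice(genes, size=2, replace=False)
            hi = float(rng.uniform(0.05, 1.0))
            raw.append(PairHit(a, b, hi * 100, 100, 100, 100, hi))
            key = frozenset((a, b))
            oracle[key] = max(oracle.get(key, 0.0), hi)
        g = build_hi_graph(raw)
        assert {frozenset((a, b)): hi for a, b, hi in g.edges()} == oracle

    def test_self_hi_is_one_for_known_gene(self):
        g = build_hi_graph([PairHit("g1", "g2", 50.0, 100, 100, 100, 0.5)])
        assert g.hi("g1", "g1") == 1.0
        assert g.hi("g1", "zz") == 0.0


def test_all_vs_all_rejects_duplicate_ids(toy_records):
    with pytest.raises(ValidationError):
        all_vs_all_hits(toy_records + [toy_records[0]])


def test_record_alphabet_validation():
    with pytest.raises(ValidationError):
        ProteinRecord("g", "s", "MKT1AY")
    assert set("MKTXAY") <= AA_ALPHABET
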