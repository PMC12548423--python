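"""Sequence I/O, consensus, and pairwise-alignment behavior."""

import logging
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypermut.seqio import (
    AlignParams,
    SeqRecordN,
    align_pairwise,
    build_consensus,
    ingest_aligned_fasta,
    project_query,
    read_fasta,
    write_fasta,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def gotoh_oracle(a, b, p: AlignParams) -> float:
    """Independent pure-python affine-gap DP (scores only).

    Same scoring scheme as the package aligner: gap of length L costs
    gap_open + L*gap_extend; N scores as a mismatch against anything.
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(p.gap_open + p.gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(p.gap_open + p.gap_extend * j)
    opn = p.gap_open + p.gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == "N" or b[j - 1] == "N":
                s = p.mismatch
            else:
                s = p.match if a[i - 1] == b[j - 1] else p.mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - opn, Y[i - 1][j] - opn,
                          X[i - 1][j] - p.gap_extend)
            Y[i][j] = max(M[i][j - 1] - opn, X[i][j - 1] - opn,
                          Y[i][j - 1] - p.gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


class TestReadFasta:
    @pytest.mark.parametrize(
        "content,expected_seq",
        [
            (">a\nacgt\n", "ACGT"),        # case normalization
            (">a\nACGU\n", "ACGT"),        # RNA -> DNA
            (">a\nACRT\n", "ACNT"),        # ambiguity code -> N
        ],
    )
    def test_normalization(self, tmp_path, content, expected_seq):
        f = tmp_path / "in.fa"
        f.write_text(content)
        (rec,) = read_fasta(f)
        assert rec.id == "a"
        assert rec.seq == expected_seq

    def test_ambiguity_warns(self, tmp_path, caplog):
        f = tmp_path / "in.fa"
        f.write_text(">a\nACRT\n")
        with caplog.at_level(logging.WARNING, logger="hypermut.seqio"):
            read_fasta(f)
        assert any("ambiguity" in r.message for r in caplog.records)

    def test_empty_file_errors(self, tmp_path):
        f = tmp_path / "empty.fa"
        f.write_text("")
        with pytest.raises(ValueError):
            read_fasta(f)

    def test_illegal_character_errors(self, tmp_path):
        f = tmp_path / "bad.fa"
        f.write_text(">a\nAC!T\n")
        with pytest.raises(ValueError):
            read_fasta(f)

    def test_round_trip(self, tmp_path):
        records = [SeqRecordN("x", "ACGTN"), SeqRecordN("y", "GGATCC")]
        path = tmp_path / "out.fa"
        write_fasta(records, path)
        assert read_fasta(path) == records


class TestConsensus:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["ACGT", "ACGT", "ACGT"], "ACGT"),  # unanimity
            (["ACGT", "ACGA", "ACGA"], "ACGA"),  # majority
            (["A-GT", "AC-T", "ACGT"], "ACGT"),  # gap minority loses per column
        ],
    )
    def test_majority(self, seqs, expected):
        records = [SeqRecordN(f"s{i}", s) for i, s in enumerate(seqs)]
        assert build_consensus(records, pre_aligned=True).seq == expected

    def test_tie_broken_by_first_record(self):
        records = [SeqRecordN("s0", "T"), SeqRecordN("s1", "C")]
        assert build_consensus(records, pre_aligned=True).seq == "T"
        assert build_consensus(records[::-1], pre_aligned=True).seq == "C"

    def test_n_ignored_unless_all_n(self):
        records = [SeqRecordN("s0", "NA"), SeqRecordN("s1", "NA"),
                   SeqRecordN("s2", "GA")]
        # col 1: votes G only -> G; col 2: A
        assert build_consensus(records, pre_aligned=True).seq == "GA"
        all_n = [SeqRecordN("a", "N"), SeqRecordN("b", "N")]
        assert build_consensus(all_n, pre_aligned=True).seq == "N"

    def test_majority_gap_column_dropped(self):
        records = [SeqRecordN("a", "A-G"), SeqRecordN("b", "A-G"),
                   SeqRecordN("c", "ACG")]
        assert build_consensus(records, pre_aligned=True).seq == "AG"

    @pytest.mark.parametrize("records", [[SeqRecordN("only", "ACGT")], []])
    def test_too_few_records(self, records):
        with pytest.raises(ValueError):
            build_consensus(records, pre_aligned=True)

    def test_unaligned_rejected(self):
        records = [SeqRecordN("a", "ACGT"), SeqRecordN("b", "ACG")]
        with pytest.raises(ValueError, match="upstream|equal"):
            build_consensus(records, pre_aligned=False)
        with pytest.raises(ValueError):
            build_consensus(records, pre_aligned=True)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT-", min_size=8, max_size=8),
                    min_size=3, max_size=6),
           st.randoms(use_true_random=False))
    def test_permutation_invariant_without_ties(self, seqs, rnd):
        records = [SeqRecordN(f"s{i}", s) for i, s in enumerate(seqs)]
        base = build_consensus(records, pre_aligned=True).seq
        # permutation may only change tie columns; strict-majority columns
        # must be stable, so compare against a tie-free reduction
        shuffled = records[:]
        rnd.shuffle(shuffled)
        other = build_consensus(shuffled, pre_aligned=True).seq
        if not _has_tie(seqs):
            assert other == base


def _has_tie(seqs):
    for col in zip(*seqs):
        votes = [c for c in col if c != "N"]
        if not votes:
            continue
        counts = {c: votes.count(c) for c in set(votes)}
        best = max(counts.values())
        if sum(1 for v in counts.values() if v == best) > 1:
            return True
    return False


class TestAlignPairwise:
    def test_identity(self):
        aln = align_pairwise(SeqRecordN("r", "ACGT"), SeqRecordN("q", "ACGT"))
        assert aln.ref_str == aln.qry_str == "ACGT"
        assert aln.score == 8.0

    def test_single_deletion(self):
        aln = align_pairwise(
            SeqRecordN("r", "ACGT"), SeqRecordN("q", "AGT"),
            AlignParams(1, -1, 2, 1),
        )
        assert aln.ref_str == "ACGT"
        assert aln.qry_str == "A-GT"
        assert aln.score == 0.0  # 3 matches - (open 2 + extend 1)

    def test_all_mismatch_beats_gapping(self):
        aln = align_pairwise(SeqRecordN("r", "AAAA"), SeqRecordN("q", "TTTT"))
        assert aln.ref_str == "AAAA"
        assert aln.qry_str == "TTTT"
        assert aln.score == -12.0

    def test_identity_long_sequence_gapless(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(10_000))
        aln = align_pairwise(SeqRecordN("r", seq), SeqRecordN("q", seq))
        assert "-" not in aln.ref_str and "-" not in aln.qry_str
        assert aln.ref_str == aln.qry_str == seq

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(dna, dna)
    def test_score_matches_oracle(self, a, b):
        params = AlignParams(2, -3, 8, 2)
        aln = align_pairwise(SeqRecordN("r", a), SeqRecordN("q", b), params)
        assert aln.score == pytest.approx(gotoh_oracle(a, b, params))
        # the reported columns realize the reported score
        assert _score_columns(aln.columns, params) == pytest.approx(aln.score)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dna, dna)
    def test_score_matches_oracle_cheap_gaps(self, a, b):
        params = AlignParams(1, -2, 1, 1)
        aln = align_pairwise(SeqRecordN("r", a), SeqRecordN("q", b), params)
        assert aln.score == pytest.approx(gotoh_oracle(a, b, params))
        assert _score_columns(aln.columns, params) == pytest.approx(aln.score)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pairwise(SeqRecordN("r", "-"), SeqRecordN("q", "ACGT"))

    def test_params_validation(self):
        with pytest.raises(ValueError):
            AlignParams(gap_open=1, gap_extend=2)


def _score_columns(columns, p: AlignParams) -> float:
    """Score an explicit alignment column list (for internal consistency)."""
    score = 0.0
    in_gap = None
    for rc, qc in columns:
        if rc == "-" or qc == "-":
            side = "r" if rc == "-" else "q"
            if in_gap != side:
                score -= p.gap_open
            score -= p.gap_extend
            in_gap = side
        else:
            in_gap = None
            if "N" in (rc, qc):
                score += p.mismatch
            else:
                score += p.match if rc == qc else p.mismatch
    return score


class TestIngestAligned:
    def test_reference_gap_projection(self):
        alns = ingest_aligned_fasta(
            [SeqRecordN("r", "AC-T"), SeqRecordN("q", "ACGT")], "r"
        )
        (aln,) = alns
        assert aln.columns == [("A", "A"), ("C", "C"), ("-", "G"), ("T", "T")]
        assert aln.ref_positions == [1, 2, None, 3]
        assert project_query(aln) == "ACT"

    def test_shared_coordinate_frame(self):
        recs = [SeqRecordN("r", "ACGT"), SeqRecordN("q1", "ACGA"),
                SeqRecordN("q2", "TCGT")]
        a1, a2 = ingest_aligned_fasta(recs, "r")
        assert a1.ref_positions == a2.ref_positions == [1, 2, 3, 4]

    def test_reference_only_yields_empty(self):
        assert ingest_aligned_fasta([SeqRecordN("r", "ACGT")], "r") == []

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            ingest_aligned_fasta(
                [SeqRecordN("r", "ACGT"), SeqRecordN("q", "ACG")], "r"
            )

    def test_missing_reference_error(self):
        with pytest.raises(ValueError):
            ingest_aligned_fasta([SeqRecordN("q", "ACGT")], "r")


class TestSeqRecordValidation:
    @pytest.mark.parametrize("rec_id,seq", [("", "ACGT"), ("x", ""), ("x", "ACxT")])
    def test_invalid(self, rec_id, seq):
        with pytest.raises(ValueError):
            SeqRecordN(rec_id, seq)
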