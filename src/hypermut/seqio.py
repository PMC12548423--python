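"""Sequence I/O, consensus building, and pairwise alignment.

Hypermutation profiling needs only three substrates: clean uppercase DNA
records, a consensus reference when no single progenitor exists (as for the
*M. spretus* provirus group), and a column-wise correspondence between each
query provirus and its reference.  Multiple-sequence alignments produced by
external tools (MUSCLE, ClustalW, MAFFT) are accepted as aligned FASTA; an
internal global affine-gap aligner covers the pairwise desk-scale case.

Coordinates throughout the package are 1-based, inclusive, on the ungapped
reference plus strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN-")
# IUPAC ambiguity codes collapse to N: they never participate in mismatch
# counting, so keeping them as distinct symbols buys nothing downstream.
_AMBIGUITY = frozenset("RYSWKMBDHV")

__all__ = [
    "SeqRecordN",
    "AlignParams",
    "PairwiseAlignment",
    "read_fasta",
    "write_fasta",
    "build_consensus",
    "align_pairwise",
    "ingest_aligned_fasta",
    "project_query",
]


@dataclass(frozen=True)
class SeqRecordN:
    """A named nucleotide sequence over {A, C, G, T, N, -}, uppercase."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be nonempty")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass(frozen=True)
class AlignParams:
    """Scoring for global affine-gap alignment.

    ``match`` and ``mismatch`` are added per aligned base pair (``mismatch``
    is normally negative); a gap of length L costs ``gap_open + L *
    gap_extend``.  The defaults gap conservatively so that isolated
    substitutions are scored as substitutions rather than absorbed into
    indels — the analysis counts substitutions, not indels.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 8.0
    gap_extend: float = 2.0

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass
class PairwiseAlignment:
    """Column-wise correspondence of a query to a reference.

    ``columns`` holds ``(ref_char, qry_char)`` pairs; ``ref_positions`` gives
    the 1-based ungapped reference coordinate of each column, or ``None``
    for reference-gap (insertion) columns.
    """

    ref_id: str
    qry_id: str
    columns: list[tuple[str, str]]
    ref_positions: list[Optional[int]] = field(default_factory=list)
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.ref_positions:
            self.ref_positions = _number_reference(self.ref_str)

    @property
    def ref_str(self) -> str:
        return "".join(c[0] for c in self.columns)

    @property
    def qry_str(self) -> str:
        return "".join(c[1] for c in self.columns)

    @property
    def ref_length(self) -> int:
        """Ungapped reference length covered by the alignment."""
        return sum(1 for p in self.ref_positions if p is not None)

    def to_records(self) -> tuple[SeqRecordN, SeqRecordN]:
        return (
            SeqRecordN(self.ref_id, self.ref_str),
            SeqRecordN(self.qry_id, self.qry_str),
        )


def _number_reference(ref_str: str) -> list[Optional[int]]:
    out: list[Optional[int]] = []
    pos = 0
    for ch in ref_str:
        if ch == "-":
            out.append(None)
        else:
            pos += 1
            out.append(pos)
    return out


def _normalize(raw: str, rec_id: str) -> str:
    s = raw.upper().replace("U", "T")
    if set(s) <= ALPHABET:
        return s
    cleaned = []
    n_amb = 0
    for ch in s:
        if ch in ALPHABET:
            cleaned.append(ch)
        elif ch in _AMBIGUITY:
            cleaned.append("N")
            n_amb += 1
        else:
            raise ValueError(f"record {rec_id!r}: illegal character {ch!r}")
    if n_amb:
        log.warning(
            "record %r: %d IUPAC ambiguity base(s) mapped to N", rec_id, n_amb
        )
    return "".join(cleaned)


def read_fasta(path: str | Path) -> list[SeqRecordN]:
    """Read FASTA into uppercase DNA records; RNA U is mapped to T.

    IUPAC ambiguity codes other than N are normalized to N with a logged
    warning; any other character raises.  An empty file raises.
    """
    records = [
        SeqRecordN(rec.id, _normalize(str(rec.seq), rec.id))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecordN], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def build_consensus(
    records: Sequence[SeqRecordN],
    pre_aligned: bool = False,
    id: str = "consensus",
) -> SeqRecordN:
    """Per-column majority consensus of pre-aligned records.

    Columns whose majority character is a gap are dropped.  N never votes
    unless a column is all-N.  Ties are broken by the character of the
    earliest record carrying one of the tied characters, so the result is
    deterministic and order-dependent only at ties.
    """
    if len(records) < 2:
        raise ValueError("consensus requires at least 2 records")
    if not pre_aligned:
        raise ValueError(
            "unaligned input: alignment must be done upstream "
            "(pass pre_aligned=True once records are aligned)"
        )
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise ValueError("pre_aligned records must have equal lengths")
    (ncol,) = lengths
    out = []
    for j in range(ncol):
        column = [r.seq[j] for r in records]
        votes = [c for c in column if c != "N"]
        if not votes:
            out.append("N")
            continue
        counts: dict[str, int] = {}
        for c in votes:
            counts[c] = counts.get(c, 0) + 1
        best = max(counts.values())
        tied = {c for c, n in counts.items() if n == best}
        winner = tied.pop() if len(tied) == 1 else next(
            c for c in column if c in tied
        )
        if winner != "-":
            out.append(winner)
    return SeqRecordN(id, "".join(out))


# ---------------------------------------------------------------------------
# Global affine-gap alignment (Gotoh, three states).
#
# State M consumes one base of each sequence (diagonal); state X consumes a
# reference base against a query gap ("up"); state Y consumes a query base
# against a reference gap ("left").  The fill is row-vectorized with numpy
# (Y's within-row recurrence becomes a running maximum); all three score
# matrices are kept in float32 so the traceback can re-derive each step from
# the stored values.  Traceback ties prefer diagonal, then up, then left,
# and prefer closing a gap over extending it.

_NEG = np.float32(-1e30)


def align_pairwise(
    ref: SeqRecordN, qry: SeqRecordN, params: AlignParams | None = None
) -> PairwiseAlignment:
    """Optimal global alignment of ``qry`` against ``ref``.

    Deterministic: traceback ties are resolved diagonal-first, then up
    (reference-consuming gap), then left.  N aligned against anything scores
    as a mismatch.
    """
    params = params or AlignParams()
    a, b = ref.ungapped(), qry.ungapped()
    if not a or not b:
        raise ValueError("both sequences must be nonempty")
    n, m = len(a), len(b)

    opn = np.float32(params.gap_open + params.gap_extend)  # cost of a 1-gap
    ext = np.float32(params.gap_extend)
    sc_match = np.float32(params.match)
    sc_mis = np.float32(params.mismatch)

    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    n_code = ord("N")

    M = np.full((n + 1, m + 1), _NEG, dtype=np.float32)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.float32)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.float32)
    M[0, 0] = 0.0
    X[1:, 0] = -params.gap_open - ext * np.arange(1, n + 1, dtype=np.float32)
    Y[0, 1:] = -params.gap_open - ext * np.arange(1, m + 1, dtype=np.float32)

    j_idx = np.arange(m + 1, dtype=np.float32)
    for i in range(1, n + 1):
        sub = np.where(b_arr == a_arr[i - 1], sc_match, sc_mis)
        if a_arr[i - 1] == n_code:
            sub[:] = sc_mis
        sub[b_arr == n_code] = sc_mis

        prev_best = np.maximum(M[i - 1], np.maximum(X[i - 1], Y[i - 1]))
        M[i, 1:] = prev_best[:-1] + sub
        X[i] = np.maximum(np.maximum(M[i - 1], Y[i - 1]) - opn, X[i - 1] - ext)
        X[i, 0] = -params.gap_open - ext * i
        # Y[i, j] = max_{k<j}( max(M[i,k], X[i,k]) - gap_open - ext*(j-k) )
        cand = np.maximum(M[i], X[i]) - np.float32(params.gap_open) + ext * j_idx
        runmax = np.maximum.accumulate(cand)
        Y[i, 1:] = runmax[:-1] - ext * j_idx[1:]
        Y[i, 0] = _NEG

    # traceback (state order encodes the tie preference M > X > Y)
    i, j = n, m
    end = (M[n, m], X[n, m], Y[n, m])
    state = int(max(range(3), key=lambda s: (end[s], -s)))
    score = float(end[state])
    cols: list[tuple[str, str]] = []
    while i > 0 or j > 0:
        if state == 0:
            cols.append((a[i - 1], b[j - 1]))
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            state = int(max(range(3), key=lambda s: (prev[s], -s)))
            i -= 1
            j -= 1
        elif state == 1:
            cols.append((a[i - 1], "-"))
            here = X[i, j]
            if M[i - 1, j] - opn >= here:
                state = 0
            elif X[i - 1, j] - ext >= here:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            cols.append(("-", b[j - 1]))
            here = Y[i, j]
            if M[i, j - 1] - opn >= here:
                state = 0
            elif X[i, j - 1] - opn >= here:
                state = 1
            else:
                state = 2
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    cols.reverse()
    return PairwiseAlignment(ref.id, qry.id, cols, score=score)


def ingest_aligned_fasta(
    records: Sequence[SeqRecordN], ref_id: str
) -> list[PairwiseAlignment]:
    """Split an aligned FASTA into per-query pairwise alignments.

    All records must be equal length (aligned).  One :class:`PairwiseAlignment`
    per non-reference record is returned, all sharing the reference
    coordinate frame.  Passing only the reference yields an empty list.
    """
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        raise ValueError("aligned FASTA records must have equal lengths")
    by_id = {r.id: r for r in records}
    if ref_id not in by_id:
        raise ValueError(f"reference id {ref_id!r} not present")
    ref = by_id[ref_id]
    ref_positions = _number_reference(ref.seq)
    out = []
    for rec in records:
        if rec.id == ref_id:
            continue
        cols = list(zip(ref.seq, rec.seq))
        out.append(
            PairwiseAlignment(ref_id, rec.id, cols, list(ref_positions))
        )
    return out


def project_query(aln: PairwiseAlignment) -> str:
    """Query characters at each ungapped reference position.

    Returns a string of length ``aln.ref_length`` whose i-th character is the
    query base aligned to reference position i+1 ('-' where the query is
    deleted).  Insertion columns (reference gaps) are invisible in this
    projection, which is exactly the coordinate frame the mismatch and
    context analyses work in.
    """
    out = []
    for (rc, qc), pos in zip(aln.columns, aln.ref_positions):
        if pos is not None:
            out.append(qc)
    return "".join(out)
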