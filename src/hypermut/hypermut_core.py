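"""Mismatch classification and hypermutation summary statistics.

APOBEC3 editing deaminates C→U on the retroviral minus strand during
reverse transcription, which is read out as G→A substitutions on the
proviral plus strand.  Hypermutation is therefore recognized as an excess
of G>A over the other substitution classes — in particular over C>T (the
plus-strand-editing mirror image) and A>G (the ADAR signature).  This
module classifies substitutions of a query provirus relative to its
reference, summarizes them into the per-provirus statistics used throughout
the package (%G>A of mismatches, G>A per 1,000 reference bases, query base
composition), and tallies runs of consecutive G>A mutations, the footprint
of sequential editing of minus-strand C tracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .seqio import PairwiseAlignment

DNA = "ACGT"

#: The 12 ordered substitution classes ("ref>qry").
SUBSTITUTION_CLASSES: tuple[str, ...] = tuple(
    f"{r}>{q}" for r in DNA for q in DNA if r != q
)

__all__ = [
    "SUBSTITUTION_CLASSES",
    "MismatchRecord",
    "MismatchProfile",
    "classify_mismatches",
    "summarize_profile",
    "base_composition",
    "find_runs",
    "count_indel_columns",
]


@dataclass(frozen=True, order=True)
class MismatchRecord:
    """A single substitution at an ungapped reference position (1-based)."""

    ref_pos: int
    ref_base: str
    qry_base: str

    def __post_init__(self) -> None:
        if self.ref_base == self.qry_base:
            raise ValueError("ref_base and qry_base must differ")
        if self.ref_base not in DNA or self.qry_base not in DNA:
            raise ValueError("mismatch bases must be in ACGT")

    @property
    def klass(self) -> str:
        return f"{self.ref_base}>{self.qry_base}"


@dataclass
class MismatchProfile:
    """Summary statistics over a set of classified mismatches.

    ``pct_GA_of_total`` is None when there are no mismatches at all.
    Percentages are carried at full precision; presentation rounding lives
    in :mod:`hypermut.report`.
    """

    counts: dict[str, int]
    total: int
    aligned_ref_length: int
    pct_GA_of_total: Optional[float]
    GA_per_kb: float
    pct_G: Optional[float]
    pct_A: Optional[float]
    run_histogram: dict[int, int] = field(default_factory=dict)


def classify_mismatches(
    aln: PairwiseAlignment,
    region: Optional[tuple[int, int]] = None,
) -> list[MismatchRecord]:
    """One record per alignment column where both bases are in ACGT and differ.

    Columns containing '-' or N on either side contribute nothing.  ``region``
    is a 1-based inclusive interval of reference coordinates; an empty overlap
    yields an empty list.
    """
    out: list[MismatchRecord] = []
    for (rc, qc), pos in zip(aln.columns, aln.ref_positions):
        if pos is None:
            continue
        if region is not None and not (region[0] <= pos <= region[1]):
            continue
        if rc in DNA and qc in DNA and rc != qc:
            out.append(MismatchRecord(pos, rc, qc))
    out.sort(key=lambda r: r.ref_pos)
    return out


def base_composition(seq: str) -> tuple[float, float]:
    """(%G, %A) of a sequence, over non-N (and non-gap) characters."""
    if not seq:
        raise ValueError("empty sequence")
    counted = [c for c in seq if c in DNA]
    if not counted:
        raise ValueError("no unambiguous bases in sequence")
    n = len(counted)
    return (
        100.0 * counted.count("G") / n,
        100.0 * counted.count("A") / n,
    )


def find_runs(records: Sequence[MismatchRecord]) -> dict[int, int]:
    """Histogram of maximal runs of G>A at adjacent reference coordinates.

    A run of k >= 2 consecutive reference positions each carrying a G>A
    record counts once under key k.  Non-G>A records at an intervening
    position do not extend a run, and a coordinate gap of any size breaks
    one.  Lengths above 5 keep their own key rather than being truncated.
    """
    ga_positions = sorted(r.ref_pos for r in records if r.klass == "G>A")
    hist: dict[int, int] = {}
    run_len = 0
    prev = None
    for pos in ga_positions:
        if prev is not None and pos == prev + 1:
            run_len += 1
        else:
            if run_len >= 2:
                hist[run_len] = hist.get(run_len, 0) + 1
            run_len = 1
        prev = pos
    if run_len >= 2:
        hist[run_len] = hist.get(run_len, 0) + 1
    return hist


def count_indel_columns(aln: PairwiseAlignment) -> int:
    """Number of gap-containing alignment columns (reported, never counted
    among substitutions)."""
    return sum(1 for rc, qc in aln.columns if rc == "-" or qc == "-")


def summarize_profile(
    records: Sequence[MismatchRecord],
    aligned_ref_length: int,
    qry_composition_span: Optional[str] = None,
) -> MismatchProfile:
    """Assemble a :class:`MismatchProfile` from classified mismatches.

    ``aligned_ref_length`` is the number of reference bases in the compared
    span (the per-1,000-bp denominator).  ``qry_composition_span`` is the
    query sequence over the compared span, used for %G/%A; when omitted the
    composition fields are None.
    """
    if aligned_ref_length <= 0:
        raise ValueError("aligned_ref_length must be positive")
    counts = {k: 0 for k in SUBSTITUTION_CLASSES}
    for r in records:
        counts[r.klass] += 1
    total = sum(counts.values())
    pct_ga = 100.0 * counts["G>A"] / total if total > 0 else None
    ga_per_kb = 1000.0 * counts["G>A"] / aligned_ref_length
    if qry_composition_span is not None:
        pct_g, pct_a = base_composition(qry_composition_span)
    else:
        pct_g = pct_a = None
    return MismatchProfile(
        counts=counts,
        total=total,
        aligned_ref_length=aligned_ref_length,
        pct_GA_of_total=pct_ga,
        GA_per_kb=ga_per_kb,
        pct_G=pct_g,
        pct_A=pct_a,
        run_histogram=find_runs(records),
    )
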