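"""5' vs 3' LTR comparison against a reference LTR.

The two LTRs of a provirus are identical at integration and diverge only
afterwards, so substitutions present in one LTR but not the other are
informative about when and where they arose.  APOBEC3 editing during
reverse transcription can hit the nascent 3' LTR a second time while its
minus strand is transiently displaced and single-stranded, producing G>A
substitutions unique to the 3' LTR.  This module aligns both LTRs to a
reference LTR on a common coordinate frame and classifies each substitution
as shared (same base change at the same reference position in both LTRs)
or LTR-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .hypermut_core import MismatchRecord, classify_mismatches
from .seqio import AlignParams, PairwiseAlignment, SeqRecordN, align_pairwise

__all__ = ["LTRComparison", "compare_ltrs"]

#: minimum fraction of identical columns for two LTRs to count as homologous
IDENTITY_FLOOR = 0.5


@dataclass
class LTRComparison:
    """Classified substitutions of a 5'/3' LTR pair versus a reference LTR.

    Entries are ``(ref_pos, klass)`` pairs; "shared" requires the same
    substituted base at the same reference position in both LTRs.  Positions
    where the two LTRs differ from the reference with *different* bases
    appear as two specific entries.  Indels are reported by position but
    never counted among substitutions.
    """

    shared: list[tuple[int, str]]
    five_specific: list[tuple[int, str]]
    three_specific: list[tuple[int, str]]
    indel_positions: list[int] = field(default_factory=list)

    @property
    def three_specific_GA_count(self) -> int:
        return sum(1 for _, k in self.three_specific if k == "G>A")

    @property
    def five_specific_GA_count(self) -> int:
        return sum(1 for _, k in self.five_specific if k == "G>A")


def _identity(aln: PairwiseAlignment) -> float:
    ident = sum(1 for rc, qc in aln.columns if rc == qc and rc != "-")
    return ident / len(aln.columns)


def _indel_ref_positions(aln: PairwiseAlignment) -> set[int]:
    out = set()
    last_pos = 0
    for (rc, qc), pos in zip(aln.columns, aln.ref_positions):
        if pos is not None:
            last_pos = pos
        if rc == "-" or qc == "-":
            out.add(last_pos)
    return out


def compare_ltrs(
    five: SeqRecordN,
    three: SeqRecordN,
    ref_ltr: SeqRecordN,
    params: Optional[AlignParams] = None,
    mask: Optional[tuple[int, int]] = None,
) -> LTRComparison:
    """Align both LTRs to ``ref_ltr`` and classify their substitutions.

    ``mask`` is a reference interval (1-based, inclusive) excluded from
    classification — e.g. a hypervariable segment where mismatches against
    the reference cannot be called reliably.  Raises if either LTR aligns
    with identity below ``IDENTITY_FLOOR`` ("not homologous").
    """
    aln5 = align_pairwise(ref_ltr, five, params)
    aln3 = align_pairwise(ref_ltr, three, params)
    for name, aln in (("5' LTR", aln5), ("3' LTR", aln3)):
        if _identity(aln) < IDENTITY_FLOOR:
            raise ValueError(
                f"{name} not homologous to reference "
                f"(identity {_identity(aln):.2f} < {IDENTITY_FLOOR})"
            )

    def keyed(aln: PairwiseAlignment) -> dict[tuple[int, str], MismatchRecord]:
        recs = classify_mismatches(aln)
        if mask is not None:
            recs = [r for r in recs if not (mask[0] <= r.ref_pos <= mask[1])]
        return {(r.ref_pos, r.klass): r for r in recs}

    m5, m3 = keyed(aln5), keyed(aln3)
    shared = sorted(set(m5) & set(m3))
    five_specific = sorted(set(m5) - set(m3))
    three_specific = sorted(set(m3) - set(m5))
    indels = sorted(_indel_ref_positions(aln5) | _indel_ref_positions(aln3))
    return LTRComparison(shared, five_specific, three_specific, indels)
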