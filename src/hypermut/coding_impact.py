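"""Coding consequences of G>A hypermutation within annotated CDS intervals.

G>A editing has a characteristic proteomic footprint: premature stop codons
arising almost exclusively from tryptophan codons (TGG is provably the only
non-stop codon that G>A-only changes can convert to a stop), disabled ATG
start codons, and a high nonsynonymous fraction.  This module scans CDS
annotations on the reference coordinate frame for all three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .hypermut_core import DNA, MismatchRecord
from .seqio import PairwiseAlignment, project_query

log = logging.getLogger(__name__)

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

__all__ = [
    "CdsAnnotation",
    "StopGainEvent",
    "scan_stop_gains",
    "scan_start_loss",
    "nonsyn_fraction",
    "ga_only_stop_sources",
]


def _translate(codon: str) -> Optional[str]:
    """Amino acid for a codon, '*' for stops, None if ambiguous/gapped."""
    if any(b not in DNA for b in codon):
        return None
    if codon in STOP_CODONS:
        return "*"
    return standard_dna_table.forward_table[codon]


@dataclass(frozen=True)
class CdsAnnotation:
    """A coding interval on reference coordinates (1-based, inclusive).

    ``frame_offset`` shifts the first complete codon; codon indices are
    1-based from the (frame-adjusted) start.  ``numbering_anchor`` is a
    free-text note on what codon 1 means (e.g. a gene's own ATG vs a
    ribosomal frameshift site).
    """

    gene: str
    start: int
    end: int
    frame_offset: int = 0
    numbering_anchor: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < 3:
            raise ValueError(f"CDS {self.gene}: interval shorter than a codon")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1, or 2")

    def codon_positions(self):
        """Yield (codon_index, (p1, p2, p3)) reference positions."""
        first = self.start + self.frame_offset
        idx = 0
        for p in range(first, self.end - 1, 3):
            idx += 1
            yield idx, (p, p + 1, p + 2)


@dataclass(frozen=True)
class StopGainEvent:
    gene: str
    codon_index: int
    ref_codon: str
    qry_codon: str
    caused_by_GA_only: bool

    def __post_init__(self) -> None:
        if self.qry_codon not in STOP_CODONS:
            raise ValueError("qry_codon must be a stop codon")
        if self.ref_codon in STOP_CODONS:
            raise ValueError("ref_codon must not already be a stop")


def _codon_pair(aln_ref: str, aln_qry: str, positions) -> tuple[str, str]:
    p1, p2, p3 = positions
    ref_codon = aln_ref[p1 - 1] + aln_ref[p2 - 1] + aln_ref[p3 - 1]
    qry_codon = aln_qry[p1 - 1] + aln_qry[p2 - 1] + aln_qry[p3 - 1]
    return ref_codon, qry_codon


def _check_cds_in_alignment(aln: PairwiseAlignment, cds: CdsAnnotation) -> None:
    if cds.start < 1 or cds.end > aln.ref_length:
        raise ValueError(
            f"CDS {cds.gene} [{cds.start},{cds.end}] outside aligned reference "
            f"span of length {aln.ref_length}"
        )


def scan_stop_gains(
    aln: PairwiseAlignment, cds: CdsAnnotation
) -> list[StopGainEvent]:
    """Premature stop codons in the query relative to the reference.

    Codons whose query bases include a deletion or N are skipped with a
    warning (stop/start calls need the full realized codon).
    ``caused_by_GA_only`` is true iff every differing base within the codon
    is a plus-strand G>A change.
    """
    _check_cds_in_alignment(aln, cds)
    ref_seq = aln.ref_str.replace("-", "")
    qry_proj = project_query(aln)
    events = []
    skipped = 0
    for idx, positions in cds.codon_positions():
        ref_codon, qry_codon = _codon_pair(ref_seq, qry_proj, positions)
        ref_aa, qry_aa = _translate(ref_codon), _translate(qry_codon)
        if ref_aa is None or qry_aa is None:
            skipped += 1
            continue
        if qry_aa == "*" and ref_aa != "*":
            ga_only = all(
                r == q or (r == "G" and q == "A")
                for r, q in zip(ref_codon, qry_codon)
            )
            events.append(StopGainEvent(cds.gene, idx, ref_codon, qry_codon, ga_only))
    if skipped:
        log.warning("scan_stop_gains(%s): skipped %d gapped/ambiguous codon(s)",
                    cds.gene, skipped)
    return events


def scan_start_loss(
    aln: PairwiseAlignment, cds: CdsAnnotation
) -> tuple[bool, str]:
    """(start_lost, query codon 1) for a CDS whose reference codon 1 is ATG."""
    _check_cds_in_alignment(aln, cds)
    ref_seq = aln.ref_str.replace("-", "")
    qry_proj = project_query(aln)
    _, positions = next(iter(cds.codon_positions()))
    ref_codon, qry_codon = _codon_pair(ref_seq, qry_proj, positions)
    if ref_codon != "ATG":
        raise ValueError(
            f"CDS {cds.gene}: no annotated ATG start (reference codon 1 is "
            f"{ref_codon})"
        )
    return qry_codon != "ATG", qry_codon


def nonsyn_fraction(
    records: Sequence[MismatchRecord],
    cds: CdsAnnotation,
    ref_seq: str,
) -> Optional[float]:
    """Fraction of in-CDS G>A records that change the encoded amino acid.

    Each record is evaluated independently against the reference codon (no
    compounding of multiple edits within one codon).  Returns None when no
    G>A record falls inside the CDS.
    """
    pos_to_codon: dict[int, tuple[int, tuple[int, int, int]]] = {}
    for idx, positions in cds.codon_positions():
        for offset, p in enumerate(positions):
            pos_to_codon[p] = (offset, positions)
    n = nonsyn = 0
    for rec in records:
        if rec.klass != "G>A" or rec.ref_pos not in pos_to_codon:
            continue
        offset, positions = pos_to_codon[rec.ref_pos]
        ref_codon = "".join(ref_seq[p - 1] for p in positions)
        mut = list(ref_codon)
        mut[offset] = "A"
        ref_aa, mut_aa = _translate(ref_codon), _translate("".join(mut))
        if ref_aa is None or mut_aa is None:
            continue
        n += 1
        if ref_aa != mut_aa:
            nonsyn += 1
    return nonsyn / n if n else None


def ga_only_stop_sources() -> set[str]:
    """Non-stop codons convertible to a stop codon by G>A changes alone.

    Exhaustive over the 64-codon table.  The result is {'TGG'}: the
    observation that every editing-induced premature stop is a mutated
    tryptophan codon is a theorem of the genetic code, not a coincidence.
    """
    out = set()
    codons = [a + b + c for a in DNA for b in DNA for c in DNA]
    for codon in codons:
        if codon in STOP_CODONS:
            continue
        # enumerate all non-empty subsets of G positions mutated to A
        g_pos = [i for i, b in enumerate(codon) if b == "G"]
        for mask in range(1, 1 << len(g_pos)):
            mut = list(codon)
            for k, i in enumerate(g_pos):
                if mask & (1 << k):
                    mut[i] = "A"
            if "".join(mut) in STOP_CODONS:
                out.add(codon)
                break
    return out
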