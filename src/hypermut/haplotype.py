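"""Haplotype enumeration at diagnostic sites of aligned coding sequences.

The two laboratory-mouse APOBEC3 alleles (mA3-B6 and mA3-BALB) differ at a
small set of replacement sites; wild-mouse sequences recombine those
polymorphisms into further haplotypes.  This module genotypes aligned
sequences (nucleotide or translated) at an arbitrary, user-supplied set of
diagnostic alignment columns and enumerates the distinct haplotypes
relative to the two named reference alleles.  A provisional example site
file ships with the package; the engine is generic over any
:class:`DiagnosticSiteSet`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = ["DiagnosticSiteSet", "HaplotypeCall", "AlignedRecord",
           "call_haplotypes", "read_sites_tsv", "read_alignment_fasta"]

_MISSING = {"-", "N", "X"}


@dataclass(frozen=True)
class AlignedRecord:
    """A row of a (nucleotide or translated) alignment; no alphabet check,
    since diagnostic sites are routinely amino-acid residues."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def read_alignment_fasta(path: str | Path) -> list[AlignedRecord]:
    """Read an aligned FASTA without nucleotide-alphabet restrictions."""
    records = [
        AlignedRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


@dataclass(frozen=True)
class DiagnosticSiteSet:
    """Ordered diagnostic columns with the residues of two reference alleles.

    ``sites`` holds ``(column, residue_A, residue_B)`` with 1-based alignment
    columns; the two residues must differ at every site.
    """

    sites: tuple[tuple[int, str, str], ...]
    allele_A_name: str = "alleleA"
    allele_B_name: str = "alleleB"

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("at least one diagnostic site required")
        for col, a, b in self.sites:
            if a == b:
                raise ValueError(f"column {col}: allele residues must differ")

    @property
    def columns(self) -> tuple[int, ...]:
        return tuple(s[0] for s in self.sites)

    def vector_A(self) -> str:
        return "".join(s[1] for s in self.sites)

    def vector_B(self) -> str:
        return "".join(s[2] for s in self.sites)

    def subset(self, columns: Sequence[int]) -> "DiagnosticSiteSet":
        """Restrict to the given alignment columns (for samples covering
        only part of the gene); labels then denote compatibility classes."""
        keep = tuple(s for s in self.sites if s[0] in set(columns))
        return DiagnosticSiteSet(keep, self.allele_A_name, self.allele_B_name)


@dataclass
class HaplotypeCall:
    sample_id: str
    vector: str
    label: str
    incomplete: bool = False
    novel_residues: tuple[int, ...] = ()  # site indices with off-allele residues


def call_haplotypes(
    alignment: Sequence,
    sites: DiagnosticSiteSet,
    restrict_columns: Optional[Sequence[int]] = None,
) -> tuple[list[HaplotypeCall], int]:
    """Genotype every sample at the diagnostic sites.

    Identical residue vectors share a haplotype id; vectors equal to allele
    A or B get those allele names, others get ids H1, H2, ... in order of
    first appearance.  Samples with a gap or N at any diagnostic site are
    flagged incomplete and excluded from the distinct-haplotype count
    (their partial vectors are still reported).  Returns the calls and the
    number of distinct non-reference haplotypes.

    With ``restrict_columns`` the site set is subset first (samples
    sequenced over only part of the gene); labels are then compatibility
    classes over the covered sites, marked with a ``*`` suffix.
    """
    if restrict_columns is not None:
        sites = sites.subset(restrict_columns)
        suffix = "*"
    else:
        suffix = ""
    lengths = {len(r) for r in alignment}
    if len(lengths) > 1:
        raise ValueError("alignment records must have equal lengths")
    if lengths and max(sites.columns) > max(lengths):
        raise ValueError("diagnostic column outside alignment length")

    vec_a, vec_b = sites.vector_A(), sites.vector_B()
    seen: dict[str, str] = {vec_a: sites.allele_A_name + suffix,
                            vec_b: sites.allele_B_name + suffix}
    novel_ids = 0
    calls = []
    for rec in alignment:
        vector = "".join(rec.seq[c - 1] for c in sites.columns)
        incomplete = any(ch in _MISSING for ch in vector)
        novel = tuple(
            i for i, (ch, (col, a, b)) in enumerate(zip(vector, sites.sites))
            if ch not in _MISSING and ch not in (a, b)
        )
        if incomplete:
            calls.append(HaplotypeCall(rec.id, vector, "incomplete", True, novel))
            continue
        if vector not in seen:
            novel_ids += 1
            seen[vector] = f"H{novel_ids}{suffix}"
        calls.append(HaplotypeCall(rec.id, vector, seen[vector], False, novel))
    return calls, novel_ids


def read_sites_tsv(path: str | Path) -> DiagnosticSiteSet:
    """Read a diagnostic-site TSV (columns: column, residue_A, residue_B).

    Optional header lines starting with '#' may carry
    ``allele_A_name=...`` / ``allele_B_name=...`` annotations.
    """
    name_a, name_b = "alleleA", "alleleB"
    with open(path) as fh:
        header_lines = []
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
            else:
                break
    for line in header_lines:
        for token in line.lstrip("#").split():
            if token.startswith("allele_A_name="):
                name_a = token.split("=", 1)[1]
            elif token.startswith("allele_B_name="):
                name_b = token.split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    sites = tuple(
        (int(row["column"]), str(row["residue_A"]), str(row["residue_B"]))
        for _, row in df.iterrows()
    )
    return DiagnosticSiteSet(sites, name_a, name_b)
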