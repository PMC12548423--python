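"""Minus-strand target-site context analysis of G>A mutations.

APOBEC3 deaminates cytidines on the minus strand, and its site selection is
governed by the two bases 5' of the target C on that strand (the -2/-1
positions).  A plus-strand G>A at position i therefore reports a
minus-strand C whose -1 and -2 neighbors sit at plus-strand positions i+1
and i+2 (complemented).  Contexts are written minus-strand 5'→3' as
(-2, -1, C): the canonical mouse APOBEC3 preferences are T(T/C)C for the
B6 allele and XTC (any base at -2, T at -1) for the BALB allele, which on
the plus strand read G(G/A)A and GAX.

Two context sources are supported.  ``reference`` reads the neighbors from
the unedited reference — the classical assumption that every mutation is
independent.  ``contemporaneous`` reads them from the edited query, which
models neighbors that were themselves already edited: sequential editing of
minus-strand C tracts converts CCC into TTC/CTC/TCC, creating preferred
target sites on the fly.  The "standalone" filter keeps only sites whose
-1/-2 neighbors are unmutated, for which the two sources coincide.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

from .hypermut_core import DNA, MismatchRecord

log = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

__all__ = [
    "ContextSite",
    "LogoMatrix",
    "PreferenceCall",
    "extract_contexts",
    "standalone_filter",
    "shared_sites",
    "build_logo",
    "classify_preference",
    "preference_from_sites",
]


@dataclass(frozen=True)
class ContextSite:
    """Minus-strand trinucleotide context of one G>A site.

    ``minus_context`` is written 5'→3' on the minus strand: (-2, -1, C).
    """

    ref_pos: int
    minus_context: str
    source: str  # "reference" | "contemporaneous"


@dataclass
class LogoMatrix:
    """Position frequency matrix over (-2, -1, 0) with information content.

    ``info_bits[p] = 2 - H(freqs[p])`` in bits, without small-sample
    correction (default Weblogo behavior at these sample sizes).
    """

    positions: tuple[str, ...]  # ("-2", "-1", "0")
    freqs: list[dict[str, float]]
    info_bits: list[float]
    n_sites: int


@dataclass
class PreferenceCall:
    """Allele-style target-site preference call for a logo."""

    label: Literal["B6-like", "BALB-like", "indeterminate"]
    score: float
    components: dict


def extract_contexts(
    records: Sequence[MismatchRecord],
    ref_seq: str,
    qry_seq: Optional[str] = None,
    source: Literal["reference", "contemporaneous"] = "reference",
) -> list[ContextSite]:
    """Minus-strand (-2, -1, C) context for every G>A record.

    ``ref_seq`` is the ungapped reference; ``qry_seq`` (required for
    ``source="contemporaneous"``) is the query projected onto reference
    coordinates (see :func:`hypermut.seqio.project_query`), so both strings
    index 1-based by ``ref_pos``.  Sites within 2 nt of the reference 3' end
    or whose neighbor positions are gaps/N are dropped with a logged count.
    """
    if source not in ("reference", "contemporaneous"):
        raise ValueError(f"unknown context source {source!r}")
    if source == "contemporaneous":
        if qry_seq is None:
            raise ValueError("contemporaneous context requires the query sequence")
        if len(qry_seq) != len(ref_seq):
            raise ValueError(
                "query must be projected onto reference coordinates "
                "(equal length strings)"
            )
    neighbor_src = ref_seq if source == "reference" else qry_seq

    sites = []
    dropped = 0
    for rec in records:
        if rec.klass != "G>A":
            raise ValueError(f"non-G>A record at position {rec.ref_pos}")
        i = rec.ref_pos  # 1-based; neighbors at i+1, i+2
        if i + 2 > len(ref_seq):
            dropped += 1
            continue
        p1, p2 = neighbor_src[i], neighbor_src[i + 1]  # 0-based i, i+1
        if p1 not in DNA or p2 not in DNA:
            dropped += 1
            continue
        ctx = _COMP[p2] + _COMP[p1] + "C"
        sites.append(ContextSite(rec.ref_pos, ctx, source))
    if dropped:
        log.info("extract_contexts: dropped %d site(s) (edge or gap/N neighbor)",
                 dropped)
    return sites


def standalone_filter(
    sites: Sequence[ContextSite],
    records: Sequence[MismatchRecord],
    exclude_classes: Optional[frozenset[str]] = None,
) -> list[ContextSite]:
    """Keep only sites whose -1/-2 neighbors carry no (excluded) mutation.

    The -1/-2 minus-strand neighbors of a site at reference position i are
    plus-strand positions i+1 and i+2.  By default any mismatch class at a
    neighbor removes the site; pass ``exclude_classes=frozenset({"G>A"})``
    to restrict the exclusion to minus-strand C>T edits (plus-strand G>A),
    the narrower reading.  Idempotent; output is a subset of the input.
    """
    if exclude_classes is None:
        mutated = {r.ref_pos for r in records}
    else:
        mutated = {r.ref_pos for r in records if r.klass in exclude_classes}
    return [
        s for s in sites
        if (s.ref_pos + 1) not in mutated and (s.ref_pos + 2) not in mutated
    ]


def shared_sites(
    profiles: Mapping[str, Sequence[MismatchRecord]],
    min_share: int = 2,
) -> set[int]:
    """Reference positions carrying a G>A record in >= min_share profiles."""
    if min_share < 2:
        raise ValueError("min_share must be >= 2")
    tally: dict[int, int] = {}
    for recs in profiles.values():
        for pos in {r.ref_pos for r in recs if r.klass == "G>A"}:
            tally[pos] = tally.get(pos, 0) + 1
    return {pos for pos, n in tally.items() if n >= min_share}


def build_logo(sites: Sequence[ContextSite]) -> LogoMatrix:
    """Position frequency matrix and per-column information content."""
    if not sites:
        raise ValueError("cannot build a logo from zero sites")
    n = len(sites)
    freqs = []
    info = []
    for col in range(3):
        counts = {b: 0 for b in DNA}
        for s in sites:
            counts[s.minus_context[col]] += 1
        f = {b: counts[b] / n for b in DNA}
        h = -sum(p * math.log2(p) for p in f.values() if p > 0)
        freqs.append(f)
        info.append(2.0 - h)
    return LogoMatrix(("-2", "-1", "0"), freqs, info, n)


def classify_preference(
    logo: LogoMatrix,
    background: Optional[Mapping[str, float]] = None,
    score_threshold: float = 0.5,
    uniform_info: float = 0.3,
    min_sites: int = 20,
) -> PreferenceCall:
    """Call a B6-like vs BALB-like target-site preference from a logo.

    The logo should be built from sites with T or C at -1 (see
    :func:`preference_from_sites`).  The discriminant is

        score = log2( f(T at -2) / bg(T) ) - log2( max_{B!=T} f(B at -2) / bg(B) )

    with frequencies floored at 0.5/n to keep the logs finite.  ``B6-like``
    when score exceeds ``score_threshold``; ``BALB-like`` when the -2 column
    is near-uniform (info < ``uniform_info`` bits) while f(T at -1) > 0.5;
    otherwise ``indeterminate``.  Logos from fewer than ``min_sites`` sites
    are always indeterminate.  The numeric thresholds are package
    conventions (the underlying biology is classically judged by eye from
    sequence logos) and are all configurable.
    """
    bg = dict(background) if background else {b: 0.25 for b in DNA}
    floor = 0.5 / max(logo.n_sites, 1)
    f2 = {b: max(logo.freqs[0][b], floor) for b in DNA}
    bgf = {b: max(bg.get(b, 0.0), floor) for b in DNA}
    score = math.log2(f2["T"] / bgf["T"]) - max(
        math.log2(f2[b] / bgf[b]) for b in DNA if b != "T"
    )
    components = {
        "f_minus2": dict(logo.freqs[0]),
        "f_minus1": dict(logo.freqs[1]),
        "info_minus2": logo.info_bits[0],
        "n_sites": logo.n_sites,
        "background": bgf,
    }
    if logo.n_sites < min_sites:
        return PreferenceCall("indeterminate", score, components)
    if score > score_threshold:
        return PreferenceCall("B6-like", score, components)
    if logo.info_bits[0] < uniform_info and logo.freqs[1]["T"] > 0.5:
        return PreferenceCall("BALB-like", score, components)
    return PreferenceCall("indeterminate", score, components)


def preference_from_sites(
    sites: Sequence[ContextSite],
    background: Optional[Mapping[str, float]] = None,
    **kwargs,
) -> PreferenceCall:
    """Restrict to sites with T or C at -1, build a logo, and classify.

    Sites with other bases at -1 carry no information about the B6/BALB
    distinction (both alleles require a pyrimidine-ish -1 in their canonical
    motifs) and only dilute the -2 column.
    """
    restricted = [s for s in sites if s.minus_context[1] in ("T", "C")]
    if not restricted:
        return PreferenceCall(
            "indeterminate", 0.0, {"n_sites": 0, "reason": "no T/C at -1"}
        )
    return classify_preference(build_logo(restricted), background, **kwargs)
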