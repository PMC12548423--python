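"""Synthetic proviruses and APOBEC3-style minus-strand deamination.

The simulator supplies ground truth for every analysis stage.  It models:

* a provirus with two identical long terminal repeats (LTRs are identical
  at integration) and an internal CDS seeded with TGG codons and an ATG
  start, on an i.i.d. background of the AT-rich composition typical of
  MMTV-like genomes;
* minus-strand C→U deamination with trinucleotide-context-dependent rates
  (read out as plus-strand G→A), applied in sequential scans of the minus
  strand; with ``cascade`` on, each scan reads the *live* edited sequence,
  so editing a C-tract member creates a preferred (-1 T) context for its
  neighbor in the next pass — the mechanism behind runs of consecutive G>A;
* extra editing passes restricted to the 3' LTR, modeling the transient
  second single-stranded exposure of the nascent 3' LTR minus strand during
  strand-displacement synthesis;
* uniform background substitutions that exclude G>A by default so class
  counts remain attributable to deamination;
* LTR-copy retrotransposition (both LTRs of the daughter derived from the
  parent's 3' LTR).

A single seeded generator drives all draws in a documented order (passes in
order; within a pass, minus-strand 3'→5', i.e. ascending plus-strand
coordinates; background last), so the truth log fully determines the
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .coding_impact import CdsAnnotation
from .seqio import SeqRecordN

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Default context weights: calibration-free package conventions chosen to
#: produce Table-1-like mismatch densities with a B6-style T(T/C)C bias.
DEFAULT_WEIGHTS: dict[str, float] = {"TTC": 8.0, "TCC": 4.0, "CTC": 4.0}

__all__ = [
    "ProvirusTemplate",
    "EditConfig",
    "EditTruth",
    "generate_provirus",
    "simulate_editing",
    "simulate_ltr_copy",
    "expected_edit_count",
    "solve_rate_for_expected",
    "minus_context_at",
]


@dataclass(frozen=True)
class ProvirusTemplate:
    """An unedited provirus with identical flanking LTRs (1-based intervals)."""

    seq: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    cds_list: tuple[CdsAnnotation, ...]
    seed: int

    def __post_init__(self) -> None:
        s5 = self.seq[self.ltr5[0] - 1 : self.ltr5[1]]
        s3 = self.seq[self.ltr3[0] - 1 : self.ltr3[1]]
        if s5 != s3:
            raise ValueError("LTRs must be identical at generation")
        if self.ltr5[1] >= self.ltr3[0]:
            raise ValueError("LTR intervals must be non-overlapping and ordered")

    def ltr_seq(self, which: str) -> str:
        lo, hi = self.ltr5 if which == "5" else self.ltr3
        return self.seq[lo - 1 : hi]


@dataclass(frozen=True)
class EditConfig:
    """Parameters of one simulated deamination exposure.

    ``base_rate`` is the per-scan deamination probability of an exposed
    minus-strand C in a neutral context; ``context_weights`` multiply it per
    minus-strand 3-mer (missing contexts default to 1; the product is capped
    at 1).  ``passes`` sequential scans are applied genome-wide, then
    ``ltr3_extra_exposure`` additional scans restricted to the 3' LTR.
    Background substitutions are uniform over positions and non-self bases
    and by default never create G>A at a G, keeping substitution classes
    attributable; ``allow_background_GA`` lifts that exclusion for stress
    tests.
    """

    base_rate: float = 0.02
    context_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )
    cascade: bool = False
    passes: int = 1
    ltr3_extra_exposure: int = 0
    background_sub_rate: float = 0.0
    allow_background_GA: bool = False
    scan: str = "3to5"  # minus-strand scan direction
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_rate <= 1.0):
            raise ValueError("base_rate must be in [0, 1]")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")
        if self.ltr3_extra_exposure < 0:
            raise ValueError("ltr3_extra_exposure must be >= 0")
        if any(w < 0 for w in self.context_weights.values()):
            raise ValueError("context weights must be nonnegative")
        if self.scan not in ("3to5", "5to3"):
            raise ValueError("scan must be '3to5' or '5to3'")

    def site_prob(self, context: str) -> float:
        return min(1.0, self.base_rate * self.context_weights.get(context, 1.0))


@dataclass
class EditTruth:
    """Ordered record of simulated events.

    ``events``: (plus-strand position 1-based, pass index 0-based, the
    minus-strand 3-mer context the deaminase saw at edit time).
    """

    events: list[tuple[int, int, str]]
    background_events: list[tuple[int, str, str]]

    @property
    def positions(self) -> list[int]:
        return [e[0] for e in self.events]


def minus_context_at(seq: str, pos: int) -> str:
    """Minus-strand (-2, -1, C) 3-mer for the minus-strand C paired with the
    plus-strand G at 1-based ``pos``; 'N's pad past the 3' end."""
    p1 = seq[pos] if pos < len(seq) else "N"
    p2 = seq[pos + 1] if pos + 1 < len(seq) else "N"
    return _COMP.get(p2, "N") + _COMP.get(p1, "N") + _COMP.get(seq[pos - 1], "N")


def generate_provirus(
    total_len: int = 8000,
    ltr_len: int = 1300,
    gc_fraction: float = 0.42,
    n_tgg_codons: int = 10,
    seed: int = 0,
) -> ProvirusTemplate:
    """Generate a provirus template with identical LTRs and one seeded CDS.

    Defaults emulate an MMTV-like provirus: ~8 kb total, unusually large
    (>1.3 kb) LTRs, and an AT-rich composition (GC ~0.42, matching the
    ~21% G / ~29% A of an unedited MMTV genome).  The CDS starts with ATG,
    contains at least ``n_tgg_codons`` TGG codons, no internal stops, and a
    terminal TAA.  Deterministic under ``seed``.
    """
    if not (0.0 < gc_fraction < 1.0):
        raise ValueError("gc_fraction must be in (0, 1)")
    if 2 * ltr_len >= total_len:
        raise ValueError("2*ltr_len must be smaller than total_len")
    body_len = total_len - 2 * ltr_len
    n_codons = max(3 * n_tgg_codons, 200)
    cds_len = 3 * n_codons
    if cds_len + 60 > body_len:
        raise ValueError(
            f"body of {body_len} nt cannot host a CDS of {cds_len} nt; "
            "increase total_len or decrease n_tgg_codons"
        )
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2,
         (1 - gc_fraction) / 2]
    )

    def random_dna(n: int) -> str:
        return "".join(rng.choice(bases, size=n, p=p))

    ltr = random_dna(ltr_len)
    body = list(random_dna(body_len))

    # CDS: ATG + random sense codons with TGG seeded at distinct indices + TAA
    non_stop = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    codons = ["ATG"]
    codons += [non_stop[rng.integers(len(non_stop))] for _ in range(n_codons - 2)]
    codons.append("TAA")
    tgg_slots = rng.choice(
        np.arange(1, n_codons - 1), size=n_tgg_codons, replace=False
    )
    for slot in tgg_slots:
        codons[int(slot)] = "TGG"
    cds_seq = "".join(codons)
    cds_offset = 30  # fixed margin inside the body
    body[cds_offset : cds_offset + cds_len] = list(cds_seq)
    seq = ltr + "".join(body) + ltr

    cds_start = ltr_len + cds_offset + 1  # 1-based
    cds = CdsAnnotation(
        gene="gag",
        start=cds_start,
        end=cds_start + cds_len - 1,
        numbering_anchor="codon 1 = annotated ATG",
    )
    return ProvirusTemplate(
        seq=seq,
        ltr5=(1, ltr_len),
        ltr3=(total_len - ltr_len + 1, total_len),
        cds_list=(cds,),
        seed=seed,
    )


def _scan_once(
    seq: list[str],
    template_seq: str,
    config: EditConfig,
    rng: np.random.Generator,
    pass_index: int,
    interval: Optional[tuple[int, int]],
    events: list[tuple[int, int, str]],
) -> None:
    lo, hi = interval if interval else (1, len(seq))
    positions = range(lo, hi + 1)
    if config.scan == "5to3":  # minus-strand 5'->3' = descending plus strand
        positions = reversed(positions)
    current = "".join(seq)
    for pos in positions:
        if seq[pos - 1] != "G":
            continue
        src = current if config.cascade else template_seq
        ctx = minus_context_at(src, pos)
        if rng.random() < config.site_prob(ctx):
            events.append((pos, pass_index, ctx))
            seq[pos - 1] = "A"
            if config.cascade and config.scan == "5to3":
                # a 5'->3' minus-strand scan sees its own edits within a pass
                current = current[: pos - 1] + "A" + current[pos:]


def simulate_editing(
    template: ProvirusTemplate, config: EditConfig
) -> tuple[SeqRecordN, EditTruth]:
    """Apply context-dependent minus-strand deamination to a template.

    Every deamination is realized as plus-strand G→A.  Each global pass
    scans all minus-strand Cs once; the 3' LTR then receives
    ``ltr3_extra_exposure`` further restricted passes; background
    substitutions are applied last (never to already-deaminated positions,
    so truth events stay readable from the output).
    """
    rng = np.random.default_rng(config.seed)
    seq = list(template.seq)
    events: list[tuple[int, int, str]] = []
    for pass_index in range(config.passes):
        _scan_once(seq, template.seq, config, rng, pass_index, None, events)
    for k in range(config.ltr3_extra_exposure):
        _scan_once(
            seq, template.seq, config, rng, config.passes + k,
            template.ltr3, events,
        )

    background: list[tuple[int, str, str]] = []
    if config.background_sub_rate > 0:
        edited_positions = {e[0] for e in events}
        hits = np.nonzero(
            rng.random(len(seq)) < config.background_sub_rate
        )[0]
        for i in hits:
            pos = int(i) + 1
            if pos in edited_positions:
                continue
            from_base = seq[i]
            if from_base not in "ACGT":
                continue
            choices = [b for b in "ACGT" if b != from_base]
            if from_base == "G" and not config.allow_background_GA:
                choices.remove("A")
            to_base = choices[rng.integers(len(choices))]
            seq[i] = to_base
            background.append((pos, from_base, to_base))

    edited = SeqRecordN(f"sim_edited_seed{config.seed}", "".join(seq))
    return edited, EditTruth(events, background)


def simulate_ltr_copy(
    provirus: SeqRecordN | str, template: ProvirusTemplate
) -> SeqRecordN:
    """Retrotransposition signature: both LTRs become copies of the 3' LTR.

    Models a daughter provirus generated from a parent transcript — the
    transcript spans U3 of the 3' LTR through U5 of the 5' LTR, so both
    daughter LTRs derive from (mostly) the parent's 3' LTR.  Idempotent.
    """
    seq = provirus.seq if isinstance(provirus, SeqRecordN) else provirus
    lo5, hi5 = template.ltr5
    lo3, hi3 = template.ltr3
    ltr3_seq = seq[lo3 - 1 : hi3]
    if hi5 - lo5 != hi3 - lo3:
        raise ValueError("LTR intervals have unequal lengths")
    new_seq = seq[: lo5 - 1] + ltr3_seq + seq[hi5:]
    name = provirus.id + "_ltrcopy" if isinstance(provirus, SeqRecordN) else "ltrcopy"
    return SeqRecordN(name, new_seq)


def expected_edit_count(
    template: ProvirusTemplate, config: EditConfig
) -> float:
    """Closed-form expected number of deamination events (cascade off).

    Each minus-strand C (plus-strand G) at position i sees t_i independent
    Bernoulli trials at its reference-context probability p_i, where t_i is
    ``passes`` plus the extra 3' LTR passes for sites inside that interval;
    the site is edited with probability 1-(1-p_i)^t_i.  Only valid with
    ``cascade`` off (contexts then never change).
    """
    if config.cascade:
        raise ValueError("closed form requires cascade off")
    lo3, hi3 = template.ltr3
    total = 0.0
    for i, base in enumerate(template.seq, start=1):
        if base != "G":
            continue
        p = config.site_prob(minus_context_at(template.seq, i))
        t = config.passes + (
            config.ltr3_extra_exposure if lo3 <= i <= hi3 else 0
        )
        total += 1.0 - (1.0 - p) ** t
    return total


def solve_rate_for_expected(
    template: ProvirusTemplate,
    config: EditConfig,
    target_edits: float,
) -> float:
    """Base rate at which the cascade-off expectation equals ``target_edits``.

    Used to match expected edit counts between regimes (e.g. cascade on vs
    off) without post-hoc tuning: the cascade-off rate is solved from the
    closed form against a target measured or specified elsewhere.
    """
    cfg = replace(config, cascade=False)

    def f(rate: float) -> float:
        return expected_edit_count(template, replace(cfg, base_rate=rate)) - target_edits

    if f(1.0) < 0:
        raise ValueError("target_edits unattainable even at rate 1")
    return float(brentq(f, 0.0, 1.0, xtol=1e-10))
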