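# Methods

## Coordinate and context conventions

All coordinates are 1-based, inclusive, on the ungapped reference plus
strand.  For a plus-strand G at position *i*, the paired minus-strand C has
its −1 and −2 neighbors at plus-strand positions *i*+1 and *i*+2; contexts
are reported as minus-strand 5′→3′ trinucleotides (−2, −1, C), i.e. the
reverse complement of the plus-strand triplet (*i*, *i*+1, *i*+2).  This
makes the canonical allele motifs read T(T/C)C and XTC on the minus strand
and G(G/A)A / GAX on the plus strand, the two notations used
interchangeably in the hypermutation literature.

## Mismatch profiling

A substitution is counted only where both aligned characters are in
{A,C,G,T}: columns containing a gap or N contribute nothing to the counts
and N is likewise excluded from the base-composition denominator.  Indels
are never counted as substitutions (they are reported separately), because
the analysis counts point edits.  Derived statistics:

- `%G>A of total = 100 · n(G>A) / Σ n(all 12 classes)` (undefined when
  there are no mismatches; rendered as "–"),
- `G>A per kb = 1000 · n(G>A) / aligned reference length`.

Runs of consecutive G>A are maximal blocks of adjacent *reference*
coordinates each carrying a G>A record; a non-G>A record does not extend a
run and a coordinate gap of any size (including an alignment indel) breaks
one.  This is the literal readout of a sequentially edited minus-strand C
tract.  Run lengths above 5 keep their own histogram key.

Presentation rounding is half-up (spreadsheet-style) at 1 decimal (2 or 0
where a comparison table prints those), applied only at display time; full
precision is carried everywhere else.

## Pairwise alignment

The internal aligner is a global three-state affine-gap (Gotoh) dynamic
program: match/mismatch scores are added per aligned pair and a gap of
length L costs `gap_open + L·gap_extend`.  Defaults (match 2, mismatch −3,
gap_open 8, gap_extend 2) gap conservatively so isolated substitutions are
scored as substitutions rather than absorbed into indels.  The fill is
row-vectorized (the within-row insertion recurrence becomes a running
maximum); all three score matrices are retained in float32 so the traceback
re-derives each step from stored values.  Traceback ties prefer diagonal,
then the reference-consuming gap, then the query-consuming gap, and prefer
closing a gap over extending it, making output deterministic.  N scores as
a mismatch against anything.  Score-level correctness is cross-checked in
the test suite against an independently coded pure-Python dynamic program
on randomized instances.

External multiple alignments (MUSCLE/ClustalW/MAFFT output) are accepted as
aligned FASTA and split into per-query pairwise alignments sharing the
reference coordinate frame; consensus building is per-column majority with
N abstaining, majority-gap columns dropped, and ties broken by the earliest
record carrying a tied character (deterministic, documented, and the only
order-dependent behavior).

## Target-site analysis

Context extraction drops sites within 2 nt of the reference 3′ end and
sites whose neighbor positions carry a gap or N (count logged).  Insertions
relative to the reference are invisible in the reference-coordinate
projection and therefore cannot contribute neighbors.

The "standalone" filter keeps sites whose −1/−2 neighbors (plus-strand
*i*+1, *i*+2) carry no mismatch record.  By default *any* mismatch class
excludes a site — the stricter of the two readings in circulation — with an
option to narrow the exclusion to minus-strand C>T (plus-strand G>A) only.

Logo columns report base frequencies and information content
`I = 2 − H` bits without small-sample correction, matching default Weblogo
behavior at the relevant site counts.

The preference call is a package construction: the classical B6/BALB
distinction is made by visual logo inspection, so any numeric discriminant
is a convention.  Restricted to sites with T or C at −1, the score is

    score = log2( f(T at −2) / bg(T) ) − max_{B≠T} log2( f(B at −2) / bg(B) )

with frequencies floored at 0.5/n.  `B6-like` requires score > 0.5 log2
units; `BALB-like` requires a near-uniform −2 column (information < 0.3
bits) with f(T at −1) > 0.5; logos from fewer than 20 sites are always
`indeterminate`.  All thresholds are arguments.  The classifier is
validated only on synthetic data (see below).

## Coding impact

Stop/start scanning translates the full realized query codon (standard
nuclear code); codons whose query bases include a deletion or N are skipped
with a warning, and codons interrupted by query insertions are evaluated on
the query bases aligned to the reference codon positions.  The
nonsynonymous fraction evaluates each G>A record independently against the
reference codon (no compounding within a codon), mirroring how per-site
substitutions are reported versus realized stops.  `ga_only_stop_sources`
proves by exhaustive scan that TGG is the unique non-stop codon reachable
to a stop by G>A-only changes — so "every editing-induced premature stop is
a mutated tryptophan codon" is a theorem of the code, and the module's
tests assert it as such.

## LTR comparison

Both LTRs are aligned to the reference LTR; a substitution is "shared" only
if the same substituted base occurs at the same reference position in both
LTRs (stricter than co-occurrence of any change), and positions where the
two LTRs differ from the reference with different bases yield two specific
entries.  Alignments below 50% column identity are rejected as
non-homologous.  Single-base indels are reported by position but never
counted among substitutions.  No mask is applied by default; hypervariable
intervals (known only from figure-level annotations) must be supplied by
the user.

## Simulator

`generate_provirus` defaults: 8,000 bp total, 1,300 bp identical LTRs
(MMTV-like proviruses have unusually large >1.3 kb LTRs), i.i.d.
composition at GC = 0.42 (matching the ~21% G / ~29% A of an unedited
MMTV-like genome), and one body CDS opened by ATG, closed by TAA, free of
internal stops, and seeded with ≥10 TGG codons.

`simulate_editing` scans the minus strand once per pass in the 3′→5′
direction (the direction reverse transcription exposes single-stranded
DNA; configurable, and consequential only when cascade is on).  Each
minus-strand C is edited with probability `min(1, base_rate ·
weight(context))`; the context is read from the unedited template when
`cascade` is off and from the live sequence when on, so cascade editing
lets a C-tract edit create a preferred −1 T context for its neighbor in
the next pass — the mechanism that converts CCC into TTC/CTC/TCC targets
and produces runs.  After the global passes, `ltr3_extra_exposure`
additional passes are applied to the 3′-LTR interval only, the simplest
mechanism consistent with the strand-displacement account of 3′-LTR
re-exposure (no PPT-anchored gradient is modeled, deliberately).
Background substitutions are uniform over positions and non-self bases,
never hit already-deaminated positions, and by default never create G>A at
a G, keeping the substitution classes attributable; a flag lifts the
exclusion for stress tests.  A single seeded generator drives all draws in
a documented order, so the truth log fully determines the output.

Default editing parameters (`base_rate` 0.02; weights TTC:8, TCC:4, CTC:4,
else 1) are calibration-free conventions chosen to produce mismatch
densities in the range observed for heavily edited proviruses; absolute
per-pass rates are not identifiable from endpoint sequence data and no
claim is attached to them.

For rate matching between regimes the cascade-off expectation has the
closed form `Σ_sites 1 − (1 − p_site)^t_site`, and
`solve_rate_for_expected` inverts it by bisection; cascade-on regimes are
matched by piloting their mean edit count and solving the off-regime rate
against it, rather than by tuning either regime toward a desired outcome.

### What the synthetic tests do and do not establish

The simulator emulates context-weighted, strand-specific deamination on an
i.i.d. background.  Real proviral sequence is not i.i.d. (codon structure,
CpG suppression, repeats), real editing exposure varies along the genome
with replication intermediates, and real comparisons involve reference
choice and alignment uncertainty.  A green synthetic test therefore
establishes that the estimators recover the generating mechanism under the
stated model — exact truth recovery, correct preference-regime
classification, cascade-driven run enrichment, 3′-LTR asymmetry — not that
any particular biological sequence was edited by a particular allele.
Published-sequence results that require the original database accessions
(raw per-provirus counts, window curves, site lists, wild-mouse haplotypes)
are out of the desk-scale test surface by design.

## Numerical and degenerate-input choices

- Alignment scores use float32; with integer-valued parameters all values
  are exactly representable, so tie comparisons are exact.
- Zero mismatches: %G>A is undefined (None / "–"), G>A per kb is 0.
- All-N composition spans raise; N-containing columns abstain everywhere.
- IUPAC ambiguity codes other than N are normalized to N with a logged
  warning rather than rejected.
- Haplotype vectors containing a gap/N/X at a diagnostic site are reported
  but excluded from the distinct-haplotype count.
- The packaged diagnostic-site file for the APOBEC3 alleles is a
  **provisional synthetic stand-in** (the true residues are not available
  in machine-readable form) and is marked as such in its header.

## Known limitations

- The internal aligner is quadratic in memory (three float32 matrices);
  practical to ~10 kb pairs, which covers proviral work. Larger jobs
  should use an external aligner and the aligned-FASTA ingestion path.
- Exact reproduction of column-level alignments from specific external
  tools is not guaranteed (their parameters are not part of this package).
- The preference discriminant's thresholds are conventions validated on
  synthetic data; borderline logos should be inspected directly.
- Two published-table rows (one %G>A cell each) are internally
  inconsistent in their source and are flagged `known_inconsistent` in the
  packaged fixtures; they are detected by the verification machinery and
  excluded from hard assertions.
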