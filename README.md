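# hypermut

Profiling of APOBEC3-driven G>A hypermutation in endogenous retroviruses
(ERVs), built around the endogenous mouse mammary tumor virus (*Mtv*)
provirus system, with a ground-truth simulator of minus-strand cytidine
deamination.

## The problem

APOBEC3 cytidine deaminases restrict retroviruses by editing C→U on the
viral minus-strand DNA while it is transiently single-stranded during
reverse transcription.  Each edit is fixed as a **G→A substitution on the
proviral plus strand**, so a provirus edited before germline integration
carries a permanent, strand-asymmetric mutational record: far more G>A than
C>T (the opposite-strand mirror) or A>G (the ADAR signature).  This package
is for researchers who want to quantify that record in proviral sequences
and to test mechanistic hypotheses about how it arose:

- **Mismatch profiling** against a reference provirus (or a group
  consensus): per-class substitution counts, %G>A of all mismatches, G>A
  per 1,000 reference bp, query base composition, and runs of consecutive
  G>A mutations (the footprint of sequentially edited minus-strand C
  tracts).
- **Sliding-window tracks** (default 400 bp window, 100 bp step) exposing
  genome-wide editing versus localized gradients.
- **Target-site context analysis**: the deaminase's site choice is
  controlled by the two bases 5′ of the target C on the minus strand.
  Writing contexts minus-strand 5′→3′ as (−2, −1, C), the mouse APOBEC3
  allele mA3-B6 prefers T(T/C)C while mA3-BALB prefers XTC — on the plus
  strand, G(G/A)A and GAX.  The package extracts contexts under the
  *reference* assumption (neighbors read from the unedited reference) or
  *contemporaneously* (neighbors read from the edited query, modeling
  target sites created by earlier edits), builds position frequency
  matrices with information content `I_p = 2 − H_p` bits, intersects
  shared sites across proviruses, applies the "standalone" filter (sites
  whose −1/−2 neighbors are unmutated), and calls a B6-like vs BALB-like
  preference with a log-odds discriminant.
- **Coding impact**: premature stop codons (provably all from TGG when
  caused by G>A alone), ATG start losses, and the nonsynonymous fraction of
  G>A changes.
- **5′/3′ LTR comparison**: the two long terminal repeats are identical at
  integration, so substitutions specific to one LTR are datable.  Extra
  editing of the nascent 3′ LTR during strand-displacement synthesis
  predicts an excess of 3′-LTR-specific G>A, which the comparison
  quantifies.
- **Haplotype enumeration** of aligned APOBEC3 coding sequences at
  user-supplied diagnostic sites.
- **A simulator** (`hypermut.a3sim`) generating proviruses with identical
  LTRs and seeded TGG-rich CDSs, then editing them with context-weighted
  per-site Bernoulli deamination, optional cascade (live-context) editing,
  extra 3′-LTR exposure, background noise, and LTR-copy retrotransposition
  — every stochastic run is reproducible from its seed, and a truth log
  records each event with the context the deaminase saw at edit time.

## Worked example

```python
from hypermut.a3sim import EditConfig, generate_provirus, simulate_editing
from hypermut.context import extract_contexts, preference_from_sites
from hypermut.hypermut_core import classify_mismatches, summarize_profile
from hypermut.report import make_row, render_markdown
from hypermut.seqio import SeqRecordN, ingest_aligned_fasta, project_query

template = generate_provirus(seed=42)              # 8 kb, 1.3 kb LTRs
edited, truth = simulate_editing(
    template, EditConfig(base_rate=0.02, passes=2, ltr3_extra_exposure=3, seed=42)
)
(aln,) = ingest_aligned_fasta(
    [SeqRecordN("ref", template.seq), edited], "ref"
)
records = classify_mismatches(aln)
profile = summarize_profile(records, aln.ref_length, project_query(aln))
print(render_markdown([make_row(profile, "sim")]))
print("runs of consecutive G>A:", profile.run_histogram)

sites = extract_contexts([r for r in records if r.klass == "G>A"], template.seq)
call = preference_from_sites(sites)
print(f"target-site preference: {call.label} (score {call.score:.2f})")
```

prints

```
| name | length | G>A | C>T | A>G | total | %G>A | G>A/kb |
|---|---|---|---|---|---|---|---|
| sim | 8000 | 134 | 0 | 0 | 134 | 100.0 | 16.8 |
runs of consecutive G>A: {2: 4}
target-site preference: B6-like (score 1.14)
```

All 134 mismatches are G>A because only deamination was simulated (no
background noise): every substitution is a logged truth event.  The 16.8
G>A per kb and the four 2-long runs come from two genome-wide editing
passes plus three extra 3′-LTR passes at the default T(T/C)C-biased context
weights, which is also why the preference call is B6-like.

The same stages are available from the shell via the `hypermut` CLI
(`simulate`, `align`, `consensus`, `profile`, `windows`, `context`, `ltr`,
`orf`, `haplotype`, `report`); every command writes a JSON manifest so runs
can be reproduced exactly.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline results from scratch: it verifies the
derived cells of the two packaged published comparison tables from their
raw counts (flagging the rows known to be internally inconsistent in the
source), proves the TGG stop-codon theorem by exhaustive codon-table scan,
then simulates a provirus at the given seed and runs mismatch profiling,
sliding windows, target-site preference calling, coding-impact scanning,
5′/3′ LTR comparison, and the LTR-copy signature end-to-end, printing a
summary of each stage.

`docs/methods.md` documents the models, parameter choices, and the limits
of what the synthetic-data tests establish.
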