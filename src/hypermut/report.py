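"""Summary-row assembly and verification against published tables.

Derived statistics (%G>A of mismatches, G>A per 1,000 bp) are always
recomputed from raw counts — never trusted from the input — and rounded
half-up at the precision of the table being compared to.  Published
comparison tables ship with the package as TSV fixtures; cells known to be
internally inconsistent in their source (the printed derived value does not
follow from the printed counts) are annotated ``known_inconsistent`` and
are flagged rather than asserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .hypermut_core import MismatchProfile

__all__ = [
    "SummaryRow",
    "make_row",
    "check_against_expected",
    "round_half_up",
    "load_expected_table",
    "recompute_expected_table",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (spreadsheet-style,
    not banker's rounding)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SummaryRow:
    """One provirus row of a hypermutation summary table.

    Display fields are rounded half-up; the full-precision values are kept
    alongside (``pct_GA_full``, ``GA_per_kb_full``).
    """

    name: str
    length: int
    ga: int
    ct: int
    ag: int
    total: int
    pct_G: Optional[float]
    pct_A: Optional[float]
    pct_GA_of_total: Optional[float]
    GA_per_kb: float
    pct_GA_full: Optional[float]
    GA_per_kb_full: float
    runs: dict[int, int]


def make_row(
    profile: MismatchProfile, name: str, pct_decimals: int = 1
) -> SummaryRow:
    """Assemble a display row from a profile, recomputing derived fields."""
    ga = profile.counts["G>A"]
    total = profile.total
    length = profile.aligned_ref_length
    pct_full = 100.0 * ga / total if total else None
    per_kb_full = 1000.0 * ga / length
    return SummaryRow(
        name=name,
        length=length,
        ga=ga,
        ct=profile.counts["C>T"],
        ag=profile.counts["A>G"],
        total=total,
        pct_G=round_half_up(profile.pct_G, 1) if profile.pct_G is not None else None,
        pct_A=round_half_up(profile.pct_A, 1) if profile.pct_A is not None else None,
        pct_GA_of_total=(
            round_half_up(pct_full, pct_decimals) if pct_full is not None else None
        ),
        GA_per_kb=round_half_up(per_kb_full, 1),
        pct_GA_full=pct_full,
        GA_per_kb_full=per_kb_full,
        runs=dict(profile.run_histogram),
    )


def load_expected_table(name_or_path: str | Path) -> pd.DataFrame:
    """Load a published comparison table.

    ``name_or_path`` is either a path to a TSV or the name of a packaged
    fixture (``"mtv_mismatches"`` or ``"ultraedited"``).  Columns: name,
    length, GA, total, pct_GA_printed, GA_per_kb_printed (optional),
    pct_decimals, known_inconsistent.
    """
    packaged = {
        "mtv_mismatches": "table_mtv_mismatches.tsv",
        "ultraedited": "table_ultraedited.tsv",
    }
    if str(name_or_path) in packaged:
        ref = resources.files("hypermut.data") / packaged[str(name_or_path)]
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(name_or_path, sep="\t", comment="#")


def recompute_expected_table(expected: pd.DataFrame) -> pd.DataFrame:
    """Recompute the derived cells of a published table from its raw counts.

    Adds ``pct_GA_recomputed`` / ``GA_per_kb_recomputed`` (rounded at each
    row's printed precision) and boolean ``pct_GA_agrees`` /
    ``GA_per_kb_agrees`` columns, comparing at tolerance 0.05 (0.005 for
    2-decimal cells).  ``known_inconsistent`` rows are compared too — the
    point is that the discrepancy is *detected*, not absorbed.
    """
    df = expected.copy()
    pct_rec, perkb_rec, pct_ok, perkb_ok = [], [], [], []
    for _, row in df.iterrows():
        nd = int(row.get("pct_decimals", 1))
        tol = 0.5 * 10.0 ** -nd  # half an ulp of the printed precision
        pct = round_half_up(100.0 * row["GA"] / row["total"], nd)
        pct_rec.append(pct)
        pct_ok.append(
            pd.notna(row.get("pct_GA_printed"))
            and abs(pct - float(row["pct_GA_printed"])) <= tol
        )
        if pd.notna(row.get("GA_per_kb_printed")) and pd.notna(row.get("length")):
            perkb = round_half_up(1000.0 * row["GA"] / row["length"], 1)
            perkb_rec.append(perkb)
            perkb_ok.append(abs(perkb - float(row["GA_per_kb_printed"])) <= 0.05)
        else:
            perkb_rec.append(float("nan"))
            perkb_ok.append(None)
    df["pct_GA_recomputed"] = pct_rec
    df["GA_per_kb_recomputed"] = perkb_rec
    df["pct_GA_agrees"] = pct_ok
    df["GA_per_kb_agrees"] = perkb_ok
    return df


@dataclass
class CellDiff:
    row: str
    cell: str
    expected: float
    got: float


@dataclass
class CheckReport:
    passed: bool
    diffs: list[CellDiff]
    missing_rows: list[str]


def check_against_expected(
    rows: Sequence[SummaryRow],
    expected: pd.DataFrame,
    tolerance: float = 0.05,
) -> CheckReport:
    """Per-cell comparison of recomputed rows against a published table.

    Compares the derived cells (%G>A, G>A/kb where present) at the printed
    precision.  Missing rows are listed, not fatal.  Rows marked
    ``known_inconsistent`` in the expected table are skipped from the
    pass/fail verdict but still diffed.
    """
    by_name = {r.name: r for r in rows}
    diffs: list[CellDiff] = []
    hard_fail = False
    missing = []
    for _, exp in expected.iterrows():
        name = exp["name"]
        if name not in by_name:
            missing.append(name)
            continue
        got = by_name[name]
        inconsistent = bool(exp.get("known_inconsistent", False))
        nd = int(exp.get("pct_decimals", 1))
        tol = tolerance * 10.0 ** (1 - nd)
        checks = []
        if pd.notna(exp.get("pct_GA_printed")) and got.pct_GA_full is not None:
            checks.append(
                ("pct_GA", float(exp["pct_GA_printed"]),
                 round_half_up(got.pct_GA_full, nd), tol)
            )
        if pd.notna(exp.get("GA_per_kb_printed")):
            checks.append(
                ("GA_per_kb", float(exp["GA_per_kb_printed"]),
                 round_half_up(got.GA_per_kb_full, 1), tolerance)
            )
        for cell, want, have, t in checks:
            if abs(want - have) > t:
                diffs.append(CellDiff(name, cell, want, have))
                if not inconsistent:
                    hard_fail = True
    return CheckReport(not hard_fail, diffs, missing)


def render_markdown(rows: Sequence[SummaryRow]) -> str:
    """Simple Markdown rendering of summary rows ('-' for undefined cells)."""
    header = ("| name | length | G>A | C>T | A>G | total | %G>A | G>A/kb |\n"
              "|---|---|---|---|---|---|---|---|")
    lines = [header]
    for r in rows:
        pct = "-" if r.pct_GA_of_total is None else f"{r.pct_GA_of_total}"
        lines.append(
            f"| {r.name} | {r.length} | {r.ga} | {r.ct} | {r.ag} "
            f"| {r.total} | {pct} | {r.GA_per_kb} |"
        )
    return "\n".join(lines)
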