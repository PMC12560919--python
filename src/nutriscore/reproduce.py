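"""One-shot recomputation of every derivable fixture-table cell.

``reproduce_paper`` recomputes the class sums, ratios and health
indices of the fatty-acid fixture table from its printed acid rows, and
the protein-basis values, chemical scores, EAAI, BV and NI of the
protein-quality fixture from the printed amino-acid and proximate rows,
then compares each recomputed cell against its printed value.

Default tolerances reflect two-decimal input rounding propagated
through the formulas: ±0.05 absolute for lipid quantities, ±0.5%
relative for protein-quality quantities.

Three printed quantities are *documented discrepancies* — cells the
fixture's own arithmetic cannot yield:

* the trans-fatty-acid sum rows (the printed ∑TFA is irreconcilable
  with trans-vaccenic + C18:2 trans in every column);
* the female thrombogenic index (prints 1.74, recomputes to 1.78);
* the Overall-column stearic value (9.86, inconsistent with the sex
  means 22.15/13.45), which drags the Overall ∑SFA and UFA/SFA with it.

These are reported as ``known_discrepancy`` — visible, never silently
passed — and do not fail the run.  Any other out-of-tolerance cell does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import lipid, protein
from .io import fixture_amino_acid_profile, fixture_fatty_acid_profile, fixture_protein_pct, load_fixture
from .types import ESSENTIAL_GROUPS

__all__ = ["ReproCell", "ReproductionReport", "reproduce_paper"]

#: (row, column) cells whose printed values are documented as non-derivable;
#: always reported as known_discrepancy, even if a recomputation happens to
#: land inside tolerance (the female TI recomputes to 1.78 against a printed
#: 1.74 — close, but a documented mismatch, never a silent pass)
KNOWN_DISCREPANCIES: frozenset[tuple[str, str]] = frozenset(
    {
        ("tfa", "male"),
        ("tfa", "female"),
        ("tfa", "overall"),
        ("ti", "female"),
        ("input:C18:0", "overall"),  # overall stearic outside the sex-mean hull
        ("sfa", "overall"),  # downstream of the overall stearic anomaly
        ("ufa_sfa_ratio", "overall"),  # likewise
    }
)

#: rows whose printed values depend on the as-published dialect
DIALECT_SENSITIVE_ROWS = frozenset(
    {"n6", "n6_n3_ratio", "ai", "ti", "h_fa", "h_over_H"}
)

#: printed per-sample-mean ratios, not derivable from column means
INFORMATIONAL_ROWS = frozenset({"n6_n3_ratio"})


@dataclass(frozen=True)
class ReproCell:
    """One printed-vs-recomputed comparison."""

    table: str
    row: str
    column: str
    printed: float
    recomputed: float
    tolerance: float
    relative: bool
    status: str  # pass | fail | known_discrepancy | expected_mismatch | informational

    @property
    def deviation(self) -> float:
        if self.relative:
            return abs(self.recomputed - self.printed) / abs(self.printed)
        return abs(self.recomputed - self.printed)


@dataclass
class ReproductionReport:
    dialect: str
    lipid_tol: float
    protein_rel_tol: float
    cells: list[ReproCell] = field(default_factory=list)

    @property
    def failures(self) -> list[ReproCell]:
        return [c for c in self.cells if c.status == "fail"]

    @property
    def known(self) -> list[ReproCell]:
        return [c for c in self.cells if c.status == "known_discrepancy"]

    @property
    def ok(self) -> bool:
        return not self.failures

    def summary(self) -> str:
        counts: dict[str, int] = {}
        for c in self.cells:
            counts[c.status] = counts.get(c.status, 0) + 1
        parts = [f"{v} {k}" for k, v in sorted(counts.items())]
        return f"{len(self.cells)} cells: " + ", ".join(parts)


def _status(
    row: str, column: str, within: bool, dialect: str
) -> str:
    if (row, column) in KNOWN_DISCREPANCIES:
        return "known_discrepancy"
    if row in INFORMATIONAL_ROWS:
        return "informational"
    if within:
        return "pass"
    if dialect != "as_published" and row in DIALECT_SENSITIVE_ROWS:
        return "expected_mismatch"
    return "fail"


def reproduce_paper(
    dialect: str = "as_published",
    lipid_tol: float = 0.05,
    protein_rel_tol: float = 0.005,
) -> ReproductionReport:
    """Recompute every derivable fixture cell and compare to print."""
    report = ReproductionReport(
        dialect=dialect, lipid_tol=lipid_tol, protein_rel_tol=protein_rel_tol
    )

    # -- fatty-acid table ---------------------------------------------------
    t4 = load_fixture("aubrac_table4")
    printed = {
        (r["analyte"], col): float(r[f"{col}_mean"])
        for _, r in t4[t4["kind"].isin(["derived", "index"])].iterrows()
        for col in ("male", "female", "overall")
    }
    for col in ("male", "female", "overall"):
        prof = fixture_fatty_acid_profile(col)
        s = lipid.sum_fatty_acid_classes(prof, dialect)
        hfa, h_fa, h_over_H = lipid.hypo_hyper_ratio(prof, dialect)
        recomputed = {
            "n3": s.n3,
            "n6": s.n6,
            "tfa": s.tfa,
            "sfa": s.sfa,
            "mufa": s.mufa,
            "pufa": s.pufa,
            "ufa": s.ufa,
            "ufa_sfa_ratio": s.ufa_sfa_ratio,
            "n6_n3_ratio": s.n6_n3_ratio,
            "ai": lipid.atherogenic_index(prof, dialect),
            "ti": lipid.thrombogenic_index(prof, dialect),
            "hfa": hfa,
            "h_fa": h_fa,
            "h_over_H": h_over_H,
        }
        for row, value in recomputed.items():
            p = printed[(row, col)]
            within = abs(value - p) <= lipid_tol
            report.cells.append(
                ReproCell(
                    table="fatty_acids",
                    row=row,
                    column=col,
                    printed=p,
                    recomputed=value,
                    tolerance=lipid_tol,
                    relative=False,
                    status=_status(row, col, within, dialect),
                )
            )

    # -- overall-column input consistency ------------------------------------
    # a column average must lie between the group averages; the printed
    # Overall stearic (9.86 vs sex means 22.15/13.45) cannot, under any
    # male/female weighting
    acids = t4[t4["kind"] == "acid"]
    for _, r in acids.iterrows():
        lo = min(float(r["male_mean"]), float(r["female_mean"]))
        hi = max(float(r["male_mean"]), float(r["female_mean"]))
        ov = float(r["overall_mean"])
        within = lo - lipid_tol <= ov <= hi + lipid_tol
        report.cells.append(
            ReproCell(
                table="fatty_acids",
                row=f"input:{r['analyte']}",
                column="overall",
                printed=ov,
                recomputed=float(min(max(ov, lo), hi)),  # nearest hull point
                tolerance=lipid_tol,
                relative=False,
                status=_status(f"input:{r['analyte']}", "overall", within, dialect),
            )
        )

    # -- protein-quality table ----------------------------------------------
    t6 = load_fixture("aubrac_table6")
    protein_pct = fixture_protein_pct("sex_mean")
    result = protein.evaluate_protein_quality(
        fixture_amino_acid_profile("overall"), protein_pct
    )
    groups = protein.essential_groups(result.basis)

    def add_protein_cell(row: str, column: str, p: float, value: float) -> None:
        within = abs(value - p) <= protein_rel_tol * abs(p)
        report.cells.append(
            ReproCell(
                table="protein_quality",
                row=row,
                column=column,
                printed=p,
                recomputed=value,
                tolerance=protein_rel_tol,
                relative=True,
                status="pass" if within else "fail",
            )
        )

    basis_rows = t6[t6["row_type"] == "basis"].set_index("group")
    for g in ESSENTIAL_GROUPS:
        add_protein_cell(f"basis:{g}", "meat", float(basis_rows.at[g, "meat"]), groups[g])
    add_protein_cell(
        "basis:eaa_total", "meat", float(basis_rows.at["eaa_total", "meat"]), result.total_eaa
    )
    cs_rows = t6[t6["row_type"] == "chemical_score"].set_index("group")
    idx_rows = t6[t6["row_type"] == "index"].set_index("group")
    for std in ("children", "youth", "adults"):
        for g in ESSENTIAL_GROUPS:
            add_protein_cell(
                f"cs:{g}", std, float(cs_rows.at[g, std]), result.chemical_scores[std][g]
            )
        add_protein_cell("eaai", std, float(idx_rows.at["eaai", std]), result.eaai[std])
        add_protein_cell("bv", std, float(idx_rows.at["bv", std]), result.bv[std])
        add_protein_cell("ni", std, float(idx_rows.at["ni", std]), result.ni[std])

    return report
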