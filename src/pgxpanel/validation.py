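"""Built-in self-validation.

Re-derives, from the packaged reference data and nothing else:

* the 10 HapMap validation samples — genotypes implied by the reference
  diplotypes plus the measured copy numbers must reproduce every reference
  call, for CYP2D6 both with and without copy-number data;
* the phenotype classification of every diplotype in the built-in cohort
  count table (one documented disputed CYP2D6 diplotype excepted);
* the cohort's published population statistics: per-allele Fst values and
  Hardy-Weinberg non-significance for the non-CNV genes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from ._util import UND
from .panel import Panel
from .phenotype import assign_phenotype
from .popstats import fst_table, hwe_table
from .simulate import cohort_from_counts, load_cohort_counts
from .starcall import Cyp2d6CopyState, call_gene

__all__ = ["load_hapmap_reference", "run_validation", "ValidationReport"]

#: published fixation indices reproduced from the cohort counts
#: (gene, allele) -> Fst to three decimals
REFERENCE_FST = {
    ("VKORC1", "*2"): 0.382,
    ("CYP2C19", "*17"): 0.070,
    ("CYP2C9", "*2"): 0.026,
    ("CYP2C9", "*3"): 0.027,
    ("CYP2C19", "*2"): 0.010,
    ("CYP2C19", "*3"): 0.005,
    ("CYP3A5", "*3"): 0.016,
}

_DISPUTED = {("CYP2D6", "*4X2/*36")}


def load_hapmap_reference() -> pd.DataFrame:
    ref = importlib.resources.files("pgxpanel.data") / "hapmap10_reference.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class ValidationReport:
    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, ok: bool, detail: str = "") -> None:
        self.checks.append((name, ok, detail))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def render(self) -> str:
        lines = []
        for name, ok, detail in self.checks:
            status = "PASS" if ok else "FAIL"
            lines.append(f"[{status}] {name}" + (f" — {detail}" if detail else ""))
        lines.append(
            f"{sum(ok for _, ok, _ in self.checks)}/{len(self.checks)} checks passed"
        )
        return "\n".join(lines)


def _check_hapmap(panel: Panel, report: ValidationReport) -> None:
    reference = load_hapmap_reference()
    gene_cols = {"CYP2C19": "CYP2C19", "CYP2C9": "CYP2C9",
                 "VKORC1": "VKORC1", "CYP3A5": "CYP3A5"}
    n_ok = 0
    failures: list[str] = []
    for _, row in reference.iterrows():
        state = Cyp2d6CopyState(int(row["exon9_cn"]), int(row["intron2_cn"]))
        genotypes = panel.implied_genotypes("CYP2D6", row["CYP2D6_cn"])
        ok = True
        with_cn = call_gene(genotypes, "CYP2D6", panel, state).text
        no_cn = call_gene(genotypes, "CYP2D6", panel, None).text
        if with_cn != row["CYP2D6_cn"] or no_cn != row["CYP2D6_no_cn"]:
            ok = False
            failures.append(f"{row['sample_id']} CYP2D6 {with_cn}/{no_cn}")
        for gene, col in gene_cols.items():
            called = call_gene(
                panel.implied_genotypes(gene, row[col]), gene, panel
            ).text
            if called != row[col]:
                ok = False
                failures.append(f"{row['sample_id']} {gene} {called}")
        n_ok += ok
    report.add(
        "reference samples reproduced", n_ok == len(reference),
        f"{n_ok}/{len(reference)}" + (f"; {failures[:3]}" if failures else ""),
    )


def _check_phenotypes(panel: Panel, report: ValidationReport) -> None:
    counts = load_cohort_counts()
    mismatches = []
    for _, row in counts.iterrows():
        if row["diplotype"] == UND or (row["gene"], row["diplotype"]) in _DISPUTED:
            continue
        expected = row["phenotype"] if isinstance(row["phenotype"], str) else ""
        got = assign_phenotype(row["gene"], row["diplotype"], panel).phenotype or ""
        if got != expected:
            mismatches.append(f"{row['gene']} {row['diplotype']}: {got}!={expected}")
    report.add("phenotype classification", not mismatches, "; ".join(mismatches[:5]))
    disputed = assign_phenotype("CYP2D6", "*4X2/*36", panel)
    report.add(
        "disputed *4X2/*36 flagged",
        disputed.phenotype == "PM" and any(
            "disputed" in w for w in disputed.warnings
        ),
        f"score-model class {disputed.phenotype}",
    )


def _check_popstats(panel: Panel, report: ValidationReport) -> None:
    cohort = cohort_from_counts()
    bad = []
    for (gene, allele), expected in REFERENCE_FST.items():
        got = fst_table(cohort, gene).loc[allele, "fst"]
        if abs(got - expected) > 5e-4:
            bad.append(f"{gene}{allele}: {got:.3f}!={expected:.3f}")
    report.add("fixation indices", not bad, "; ".join(bad))
    hwe = hwe_table(cohort)
    applicable = hwe[hwe["applicable"]]
    n_sig = int((applicable["pvalue"] < 0.05).sum())
    report.add(
        "Hardy-Weinberg equilibrium", n_sig == 0,
        f"{len(applicable)} variant/group tests, {n_sig} significant at 0.05",
    )


def run_validation(panel: Panel) -> ValidationReport:
    report = ValidationReport()
    _check_hapmap(panel, report)
    _check_phenotypes(panel, report)
    _check_popstats(panel, report)
    return report
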