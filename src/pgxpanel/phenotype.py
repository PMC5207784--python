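"""Diplotype-to-phenotype translation and CPIC actionability rules.

Metabolizer classes follow the CPIC-derived scheme with boundary classes:
PM, PM-IM, IM, IM-EM, EM, EM-UM, UM (and UND for undetermined diplotypes).

CYP2D6 uses an additive activity score over all gene copies (0 for
non-functional alleles, 0.5 for decreased, 1.0 for normal, 1.5 for the
promoter-variant allele *2A), mapped in half-point steps:
0 -> PM, 0.5 -> PM-IM, 1.0 -> IM, 1.5 -> IM-EM, 2.0 -> EM, 2.5 -> EM-UM,
>= 3.0 -> UM. The other genes are rule-based: CYP2C9 counts
reduced-function alleles (0/1/2 -> EM/IM/PM); CYP2C19 counts
loss-of-function alleles, with *17 carriers and homozygotes called UM when
no LOF allele is present; CYP3A5 counts *3 (0/1/2 -> EM/IM/PM); VKORC1
carries no metabolizer phenotype and is reported as a genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from ._util import UND
from .nomenclature import Diplotype, parse_diplotype
from .panel import Panel

__all__ = [
    "PhenotypeCall",
    "PhenotypeOptions",
    "assign_phenotype",
    "actionable_flags",
    "gene_actionable_variant",
    "add_phenotypes",
    "PhenotypeError",
]

PHENOTYPE_ORDER = ("PM", "PM-IM", "IM", "IM-EM", "EM", "EM-UM", "UM")
DRUGS = ("warfarin", "clopidogrel", "codeine", "tacrolimus")

_SCORE_MAP = {0.0: "PM", 0.5: "PM-IM", 1.0: "IM", 1.5: "IM-EM", 2.0: "EM", 2.5: "EM-UM"}

#: CYP2D6 diplotype whose additive score (0) disagrees with the IM label
#: circulating in legacy translation tables; see PhenotypeOptions.
_DISPUTED_CYP2D6 = "*4X2/*36"


class PhenotypeError(ValueError):
    pass


@dataclass
class PhenotypeOptions:
    #: report the legacy IM label for the disputed *4X2/*36 diplotype
    #: instead of the score-model PM
    legacy_labels: bool = False
    #: CYP2D6 classes considered actionable for codeine
    codeine_actionable: tuple[str, ...] = ("PM", "PM-IM", "IM")
    #: copies assumed for an unresolved "XN" multiplicity
    n_for_unresolved: int = 4


@dataclass
class PhenotypeCall:
    gene: str
    diplotype: str
    phenotype: str | None  # None for VKORC1 (genotype reported as-is)
    activity_score: float | None = None
    warnings: list[str] = field(default_factory=list)


def _coerce(gene: str, diplotype: Diplotype | str) -> Diplotype | None:
    if isinstance(diplotype, Diplotype):
        return diplotype
    if diplotype == UND:
        return None
    return parse_diplotype(diplotype, gene)


def _score_cyp2d6(d: Diplotype, panel: Panel, opts: PhenotypeOptions) -> tuple[float, list[str]]:
    warnings = []
    score = 0.0
    for slot in d.slots:
        for name in slot.alleles:
            per_copy = panel.activity_score("CYP2D6", name)
            if per_copy is None:
                raise PhenotypeError(f"no activity score for CYP2D6 {name}")
            mult = slot.multiplicity
            if mult is None:
                mult = opts.n_for_unresolved
                if per_copy > 0:
                    warnings.append("unresolved-multiplicity")
            score += per_copy * mult
    return score, warnings


def assign_phenotype(
    gene: str,
    diplotype: Diplotype | str,
    panel: Panel,
    options: PhenotypeOptions | None = None,
) -> PhenotypeCall:
    """Translate one gene's diplotype into a metabolizer phenotype."""
    opts = options or PhenotypeOptions()
    d = _coerce(gene, diplotype)
    text = diplotype if isinstance(diplotype, str) else diplotype.render()
    if d is None:
        return PhenotypeCall(gene, UND, UND)
    alleles = [panel.allele(gene, n) for n in d.copies(opts.n_for_unresolved)]

    if gene == "CYP2D6":
        score, warnings = _score_cyp2d6(d, panel, opts)
        rendered = d.render()
        phenotype = "UM" if score >= 3.0 else _SCORE_MAP.get(score)
        if phenotype is None:
            raise PhenotypeError(f"activity score {score} off the half-point grid")
        if rendered == _DISPUTED_CYP2D6:
            warnings.append(
                "classification-disputed: additive score 0 implies PM but "
                "legacy translation tables list IM"
            )
            if opts.legacy_labels:
                phenotype = "IM"
        return PhenotypeCall(gene, rendered, phenotype, score, warnings)

    if gene == "CYP2C9":
        reduced = sum(a.activity != "normal" for a in alleles)
        phenotype = {0: "EM", 1: "IM", 2: "PM"}[reduced]
        score = sum(a.score for a in alleles)
        return PhenotypeCall(gene, text, phenotype, score)

    if gene == "CYP2C19":
        reduced = sum(a.activity in ("none", "decreased") for a in alleles)
        increased = sum(a.activity == "increased" for a in alleles)
        if reduced >= 2:
            phenotype = "PM"
        elif reduced == 1:
            phenotype = "IM"
        elif increased >= 1:
            phenotype = "UM"
        else:
            phenotype = "EM"
        return PhenotypeCall(gene, text, phenotype)

    if gene == "CYP3A5":
        lof = sum(a.activity == "none" for a in alleles)
        phenotype = {0: "EM", 1: "IM", 2: "PM"}[lof]
        return PhenotypeCall(gene, text, phenotype)

    if gene == "VKORC1":
        return PhenotypeCall(gene, text, None)

    raise PhenotypeError(f"unknown gene {gene!r}")


# ---------------------------------------------------------------------------
# actionability

def _carries(d: Diplotype | None, names: set[str]) -> bool | None:
    if d is None:
        return None
    return bool(d.alleles() & names)


def actionable_flags(
    calls: Mapping[str, Diplotype | str],
    panel: Panel,
    options: PhenotypeOptions | None = None,
) -> dict[str, bool | None]:
    """Per-drug actionability for one sample's five-gene call set.

    Rules: warfarin — CYP2C9 *2/*3 carrier with VKORC1 GA or AA, or
    CYP2C9 *1/*1 with VKORC1 AA; clopidogrel — CYP2C19 *2, *3 or *6
    carrier; codeine — CYP2D6 poor/intermediate metabolizer classes;
    tacrolimus — CYP3A5 *1 carrier. A drug whose input gene is UND is not
    evaluable (None).
    """
    opts = options or PhenotypeOptions()
    d = {g: _coerce(g, calls[g]) for g in calls}

    flags: dict[str, bool | None] = {}
    c9 = d.get("CYP2C9")
    vk = d.get("VKORC1")
    if c9 is None or vk is None:
        flags["warfarin"] = None
    else:
        c9_carrier = _carries(c9, {"*2", "*3"})
        vk_ga_or_aa = _carries(vk, {"*2"})
        vk_aa = vk.render() == "*2/*2"
        flags["warfarin"] = bool(
            (c9_carrier and vk_ga_or_aa) or (not c9_carrier and vk_aa)
        )
    c19 = d.get("CYP2C19")
    flags["clopidogrel"] = _carries(c19, {"*2", "*3", "*6"})
    d6 = d.get("CYP2D6")
    if d6 is None:
        flags["codeine"] = None
    else:
        pheno = assign_phenotype("CYP2D6", d6, panel, opts).phenotype
        flags["codeine"] = pheno in opts.codeine_actionable
    flags["tacrolimus"] = _carries(d.get("CYP3A5"), {"*1"})
    return flags


def gene_actionable_variant(
    gene: str, diplotype: Diplotype | str, panel: Panel
) -> bool | None:
    """Whether a diplotype counts as carrying an actionable variant of its
    gene, under the conventions used for cohort actionable rates.

    CYP2C9: carrier of any reduced-function allele (*2..*6). CYP2C19:
    carrier of any non-*1 allele. CYP2D6: any departure from a plain *1/*1
    (variant allele or copy-number change). CYP3A5: the *1/*1 homozygote —
    the group for which standard tacrolimus dosing (set for the prevalent
    non-functional *3/*3) is atypical. UND diplotypes are not evaluable.
    """
    d = _coerce(gene, diplotype)
    if d is None:
        return None
    if gene == "CYP2C9":
        return bool(d.alleles() - {"*1"})
    if gene == "CYP2C19":
        return bool(d.alleles() - {"*1"})
    if gene == "CYP2D6":
        return d.alleles() != {"*1"} or len(d.copies()) != 2
    if gene == "CYP3A5":
        return d.render() == "*1/*1"
    if gene == "VKORC1":
        return bool(d.alleles() - {"*1"})
    raise PhenotypeError(f"unknown gene {gene!r}")


def add_phenotypes(
    results: pd.DataFrame, panel: Panel, options: PhenotypeOptions | None = None
) -> pd.DataFrame:
    """Append phenotype/activity-score/warning columns to a star-allele
    results frame (sample_id, gene, diplotype, ...)."""
    opts = options or PhenotypeOptions()
    cache: dict[tuple[str, str], PhenotypeCall] = {}
    phenos, scores, warns = [], [], []
    for gene, text in zip(results["gene"], results["diplotype"]):
        key = (gene, text)
        if key not in cache:
            cache[key] = assign_phenotype(gene, text, panel, opts)
        call = cache[key]
        phenos.append(call.phenotype if call.phenotype is not None else "")
        scores.append(call.activity_score)
        warns.append(";".join(call.warnings))
    out = results.copy()
    out["phenotype"] = phenos
    out["activity_score"] = scores
    out["warnings"] = warns
    return out
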