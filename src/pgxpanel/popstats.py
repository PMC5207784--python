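"""Population statistics over a cohort of per-sample gene calls.

A cohort is a long table of (sample_id, ethnicity, gene, diplotype) rows,
optionally with phenotype and CYP2D6 copy-number columns. Two kinds of
cohort occur: *joint* cohorts where each sample has calls for every gene
(simulated or assayed cohorts), and *marginal* cohorts reconstructed from
per-gene count tables, where sample identities do not correspond across
genes. Statistics that couple genes (any-gene actionable rates, the
two-gene warfarin rule) are computed empirically on joint cohorts and by
per-ethnicity independence products on marginal ones.

Conventions matching the source tables: allele frequencies divide by two
chromosomes per subject with undetermined subjects kept in the denominator;
frequencies are reported to three decimals, ties away from zero; Wright's
fixation index uses the plain (Ht - Hs)/Ht form with unweighted group
means, and the table-reproduction helpers feed it the *rounded* group
frequencies, since that is how the published values were derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import GROUPS, UND, round_half_away
from .nomenclature import parse_diplotype
from .panel import Panel
from .phenotype import (
    PhenotypeOptions,
    actionable_flags,
    assign_phenotype,
    gene_actionable_variant,
)
from .starcall import implied_copy_state

__all__ = [
    "CohortTable",
    "FstResult",
    "HweResult",
    "allele_frequencies",
    "allele_genotype_counts",
    "hwe_chisq",
    "hwe_table",
    "wright_fst",
    "fst_table",
    "pooled_maf",
    "phenotype_table",
    "cn_distribution",
    "cn_concordance",
    "actionable_rates",
    "drug_actionable_rates",
    "PopStatsError",
]

CYP_GENES = ("CYP2C9", "CYP2C19", "CYP2D6", "CYP3A5")


class PopStatsError(ValueError):
    pass


@dataclass
class CohortTable:
    """Per-sample gene results with ethnicity labels."""

    df: pd.DataFrame

    REQUIRED = ("sample_id", "ethnicity", "gene", "diplotype")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise PopStatsError(f"cohort table lacks columns {sorted(missing)}")

    @property
    def groups(self) -> list[str]:
        seen = list(dict.fromkeys(self.df["ethnicity"]))
        return [g for g in GROUPS if g in seen] + [
            g for g in seen if g not in GROUPS
        ]

    @property
    def is_joint(self) -> bool:
        """True when sample identities are shared across genes."""
        per_sample = self.df.groupby("sample_id")["gene"].nunique()
        return bool((per_sample > 1).any())

    def gene_frame(self, gene: str) -> pd.DataFrame:
        sub = self.df[self.df["gene"] == gene]
        if sub.empty:
            raise PopStatsError(f"cohort has no rows for {gene}")
        return sub

    def group_sizes(self, gene: str) -> pd.Series:
        sub = self.gene_frame(gene)
        return sub.groupby("ethnicity")["sample_id"].nunique().reindex(self.groups)


# ---------------------------------------------------------------------------
# allele frequencies

def _slot_alleles(diplotype: str, gene: str) -> list[list[str]]:
    if diplotype == UND:
        return []
    d = parse_diplotype(diplotype, gene)
    return [list(slot.alleles) for slot in d.slots]


def allele_frequencies(
    cohort: CohortTable,
    gene: str,
    by_group: bool = True,
    round_digits: int | None = None,
) -> pd.DataFrame:
    """Allele frequency table (alleles x ethnic groups).

    Each subject contributes two chromosomes to the denominator; UND
    subjects contribute no counted alleles but stay in the denominator.
    For CYP2D6 a per-chromosome *presence* convention is used (each allele
    counted once per haplotype slot carrying it, whatever its
    multiplicity); the result carries ``attrs["convention"]`` noting that
    this is not comparable to copy-weighted conventions.
    """
    sub = cohort.gene_frame(gene)
    groups = cohort.groups if by_group else ["All"]
    counts: dict[str, dict[str, int]] = {}
    denom: dict[str, int] = {g: 0 for g in groups}
    for eth, dip in zip(sub["ethnicity"], sub["diplotype"]):
        g = eth if by_group else "All"
        if g not in denom:
            continue
        denom[g] += 2
        for slot in _slot_alleles(dip, gene):
            for allele in dict.fromkeys(slot):
                counts.setdefault(allele, {}).setdefault(g, 0)
                counts[allele][g] += 1
    if any(d == 0 for d in denom.values()):
        empty = [g for g, d in denom.items() if d == 0]
        raise PopStatsError(f"empty group(s) for {gene}: {empty}")
    from .nomenclature import allele_sort_key

    alleles = sorted(counts, key=allele_sort_key)
    data = {
        g: [counts[a].get(g, 0) / denom[g] for a in alleles] for g in groups
    }
    out = pd.DataFrame(data, index=pd.Index(alleles, name="allele"))
    if round_digits is not None:
        out = out.map(lambda x: round_half_away(x, round_digits))
    out.attrs["convention"] = (
        "per-chromosome presence; not comparable to copy-weighted counts"
        if gene == "CYP2D6"
        else "haplotype counting"
    )
    return out


def allele_genotype_counts(cohort: CohortTable, gene: str) -> pd.DataFrame:
    """Per-allele genotype counts (hom carrier / het carrier / non-carrier)
    per group, over called (non-UND) subjects — the input to HWE tests."""
    sub = cohort.gene_frame(gene)
    rows = []
    for group, grp in sub.groupby("ethnicity"):
        called = grp[grp["diplotype"] != UND]
        parsed = [parse_diplotype(d, gene) for d in called["diplotype"]]
        alleles = sorted(
            {a for d in parsed for a in d.alleles()} - {"*1"}
        )
        for allele in alleles:
            n_hom = n_het = n_ref = 0
            for d in parsed:
                in_slots = sum(allele in slot.alleles for slot in d.slots)
                if in_slots == 2:
                    n_hom += 1
                elif in_slots == 1:
                    n_het += 1
                else:
                    n_ref += 1
            rows.append(
                dict(gene=gene, ethnicity=group, allele=allele,
                     n_hom=n_hom, n_het=n_het, n_ref=n_ref)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hardy-Weinberg

@dataclass
class HweResult:
    chi2: float
    pvalue: float
    df: int = 1
    applicable: bool = True


def hwe_chisq(n_hom_var: int, n_het: int, n_hom_ref: int) -> HweResult:
    """One-degree-of-freedom chi-squared test of Hardy-Weinberg
    proportions for a biallelic variant."""
    n = n_hom_var + n_het + n_hom_ref
    if n <= 0:
        raise PopStatsError("HWE test needs at least one genotype")
    p = (2 * n_hom_var + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return HweResult(float("nan"), float("nan"), applicable=False)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_var, n_het, n_hom_ref], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(chi2, float(stats.chi2.sf(chi2, 1)))


def hwe_table(cohort: CohortTable, genes: Iterable[str] = ("CYP2C9", "CYP2C19", "CYP3A5", "VKORC1")) -> pd.DataFrame:
    """HWE chi-squared per (gene, allele, group) for the non-CNV genes."""
    rows = []
    for gene in genes:
        for _, r in allele_genotype_counts(cohort, gene).iterrows():
            res = hwe_chisq(r["n_hom"], r["n_het"], r["n_ref"])
            rows.append(
                dict(gene=gene, ethnicity=r["ethnicity"], allele=r["allele"],
                     chi2=res.chi2, pvalue=res.pvalue, applicable=res.applicable)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wright's Fst and pooled MAF

@dataclass
class FstResult:
    frequencies: tuple[float, ...]
    hs: float
    ht: float
    fst: float | None
    applicable: bool = True


def wright_fst(frequencies: Sequence[float]) -> FstResult:
    """Wright's fixation index (Ht - Hs) / Ht across groups.

    Hs is the unweighted mean within-group expected heterozygosity
    2 p_i (1 - p_i); Ht uses the unweighted mean frequency. Undefined
    (not applicable) when Ht = 0, i.e. the variant is absent or fixed
    everywhere.
    """
    ps = [float(p) for p in frequencies]
    if len(ps) < 2:
        raise PopStatsError("Fst needs at least two groups")
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise PopStatsError("allele frequencies must lie in [0, 1]")
    pbar = sum(ps) / len(ps)
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = sum(2.0 * p * (1.0 - p) for p in ps) / len(ps)
    if ht == 0.0:
        return FstResult(tuple(ps), hs, ht, None, applicable=False)
    return FstResult(tuple(ps), hs, ht, (ht - hs) / ht)


def fst_table(
    cohort: CohortTable, gene: str, round_digits: int | None = 3
) -> pd.DataFrame:
    """Per-allele Fst across ethnic groups, computed — like the published
    tables — from group frequencies rounded to three decimals."""
    freqs = allele_frequencies(cohort, gene, round_digits=round_digits)
    rows = []
    for allele, row in freqs.iterrows():
        res = wright_fst(tuple(row))
        fst = res.fst
        if fst is not None and round_digits is not None:
            fst = round_half_away(fst, round_digits)
        rows.append(dict(gene=gene, allele=allele, fst=fst, **dict(row)))
    return pd.DataFrame(rows).set_index("allele")


def pooled_maf(group_frequencies: Sequence[float], round_digits: int | None = 3) -> float:
    """Cohort-level allele frequency: the unweighted mean of the group
    frequencies (no folding to <= 0.5)."""
    ps = [float(p) for p in group_frequencies]
    if not ps:
        raise PopStatsError("pooled MAF needs at least one group")
    maf = sum(ps) / len(ps)
    return round_half_away(maf, round_digits) if round_digits is not None else maf


# ---------------------------------------------------------------------------
# phenotype and copy-number tables

def _ensure_phenotypes(cohort: CohortTable, panel: Panel | None) -> pd.DataFrame:
    df = cohort.df
    if "phenotype" in df.columns:
        return df
    if panel is None:
        raise PopStatsError("cohort lacks phenotypes; pass a panel to derive them")
    cache: dict[tuple[str, str], str] = {}

    def pheno(gene: str, dip: str) -> str:
        key = (gene, dip)
        if key not in cache:
            call = assign_phenotype(gene, dip, panel)
            cache[key] = call.phenotype if call.phenotype is not None else ""
        return cache[key]

    out = df.copy()
    out["phenotype"] = [pheno(g, d) for g, d in zip(df["gene"], df["diplotype"])]
    return out


def phenotype_table(
    cohort: CohortTable, gene: str, panel: Panel | None = None
) -> pd.DataFrame:
    """Counts and frequencies of metabolizer classes per group; the
    frequency denominator is the full group size (UND rows included, as
    their own class)."""
    df = _ensure_phenotypes(cohort, panel)
    sub = df[df["gene"] == gene]
    if sub.empty:
        return pd.DataFrame()
    sizes = sub.groupby("ethnicity")["sample_id"].nunique()
    counts = (
        sub.groupby(["phenotype", "ethnicity"])["sample_id"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(columns=[g for g in cohort.groups if g in sizes.index], fill_value=0)
    )
    order = [p for p in ("PM", "PM-IM", "IM", "IM-EM", "EM", "EM-UM", "UM", UND, "") if p in counts.index]
    counts = counts.loc[order]
    freq = counts.div(sizes, axis=1)
    freq.columns = [f"{c}_freq" for c in freq.columns]
    return pd.concat([counts, freq.map(lambda x: round_half_away(x, 3))], axis=1)


def _copy_states(sub: pd.DataFrame, panel: Panel) -> pd.DataFrame:
    if {"exon9_cn", "intron2_cn"} <= set(sub.columns) and sub["exon9_cn"].notna().all():
        return sub[["ethnicity", "exon9_cn", "intron2_cn"]].astype(
            {"exon9_cn": int, "intron2_cn": int}
        )
    rows = []
    cache: dict[str, tuple[int, int]] = {}
    for eth, dip in zip(sub["ethnicity"], sub["diplotype"]):
        if dip == UND:
            continue
        if dip not in cache:
            cs = implied_copy_state(dip, panel)
            cache[dip] = (cs.exon9_cn, cs.intron2_cn)
        rows.append(dict(ethnicity=eth, exon9_cn=cache[dip][0], intron2_cn=cache[dip][1]))
    return pd.DataFrame(rows)


def cn_distribution(
    cohort: CohortTable, panel: Panel | None = None, max_cn: int = 4
) -> pd.DataFrame:
    """CYP2D6 integer copy-number frequencies per group and region
    (rows 0, 1, ..., ">= max_cn"), derived from stored CN columns when
    present, otherwise from the diplotypes' copy structure."""
    sub = cohort.gene_frame("CYP2D6")
    if panel is None and not {"exon9_cn", "intron2_cn"} <= set(sub.columns):
        raise PopStatsError("no CN columns; pass a panel to derive copy states")
    states = _copy_states(sub, panel) if panel is not None else sub
    labels = [str(i) for i in range(max_cn)] + [f"{max_cn} and above"]
    frames = {}
    for region, col in (("exon9", "exon9_cn"), ("intron2", "intron2_cn")):
        table = {}
        for group, grp in states.groupby("ethnicity"):
            cn = grp[col].clip(upper=max_cn).astype(int)
            freq = cn.value_counts(normalize=True)
            table[group] = [float(freq.get(i, 0.0)) for i in range(max_cn + 1)]
        frames[region] = pd.DataFrame(table, index=labels)
    out = pd.concat(frames, axis=1)
    return out


def cn_concordance(cohort: CohortTable, panel: Panel | None = None) -> float:
    """Fraction of subjects whose exon-9 and intron-2 integer copy numbers
    agree (they differ whenever *36 copies are present)."""
    sub = cohort.gene_frame("CYP2D6")
    states = _copy_states(sub, panel) if panel is not None else sub
    return float((states["exon9_cn"] == states["intron2_cn"]).mean())


# ---------------------------------------------------------------------------
# actionable rates

def actionable_rates(
    cohort: CohortTable, panel: Panel, genes: Iterable[str] = CYP_GENES
) -> dict[str, float]:
    """Per-gene actionable-variant carrier fractions plus the any-gene
    fraction.

    Denominators are full group sizes; not-evaluable (UND) subjects count
    in the denominator only. On marginal cohorts the any-gene fraction is
    the per-ethnicity independence product over genes, size-weighted.
    """
    genes = list(genes)
    cache: dict[tuple[str, str], bool | None] = {}

    def actionable(gene: str, dip: str) -> bool | None:
        key = (gene, dip)
        if key not in cache:
            cache[key] = gene_actionable_variant(gene, dip, panel)
        return cache[key]

    rates: dict[str, float] = {}
    not_rate: dict[tuple[str, str], float] = {}  # (gene, group) -> P(not actionable)
    for gene in genes:
        sub = cohort.gene_frame(gene)
        flags = [actionable(gene, d) for d in sub["diplotype"]]
        rates[gene] = sum(bool(f) for f in flags) / len(flags)
        for group, grp in sub.groupby("ethnicity"):
            gflags = [actionable(gene, d) for d in grp["diplotype"]]
            not_rate[(gene, group)] = 1.0 - sum(bool(f) for f in gflags) / len(gflags)
    if cohort.is_joint:
        wide = cohort.df[cohort.df["gene"].isin(genes)].pivot(
            index="sample_id", columns="gene", values="diplotype"
        )
        any_flag = wide.apply(
            lambda row: any(bool(actionable(g, row[g])) for g in genes), axis=1
        )
        rates["any_gene"] = float(any_flag.mean())
    else:
        sizes = cohort.group_sizes(genes[0]).dropna()
        total = sizes.sum()
        acc = 0.0
        for group, n in sizes.items():
            p_none = 1.0
            for gene in genes:
                p_none *= not_rate[(gene, group)]
            acc += n * (1.0 - p_none)
        rates["any_gene"] = float(acc / total)
    return rates


def plot_phenotype_frequencies(
    cohort: CohortTable,
    genes: Iterable[str] = ("CYP2C9", "CYP2C19", "CYP2D6"),
    panel: Panel | None = None,
    axes=None,
):
    """Grouped bar charts of metabolizer-class frequencies per ethnicity,
    one subplot per gene. Requires matplotlib; returns the axes."""
    import matplotlib.pyplot as plt

    genes = list(genes)
    if axes is None:
        _, axes = plt.subplots(1, len(genes), figsize=(4 * len(genes), 3.2),
                               squeeze=False)
        axes = axes[0]
    for ax, gene in zip(axes, genes):
        table = phenotype_table(cohort, gene, panel)
        freq_cols = [c for c in table.columns if str(c).endswith("_freq")]
        table[freq_cols].rename(
            columns=lambda c: str(c).removesuffix("_freq")
        ).plot.bar(ax=ax, width=0.8)
        ax.set_title(gene)
        ax.set_ylabel("frequency")
        ax.set_xlabel("")
        ax.tick_params(axis="x", rotation=45)
    return axes


def _marginal_distribution(sub: pd.DataFrame) -> dict[str, float]:
    return sub["diplotype"].value_counts(normalize=True).to_dict()


def drug_actionable_rates(
    cohort: CohortTable,
    panel: Panel,
    options: PhenotypeOptions | None = None,
) -> dict[str, float]:
    """Cohort fractions carrying actionable genotypes per drug rule.

    Joint cohorts are scored sample-by-sample; marginal cohorts use
    per-ethnicity independence for the two-gene warfarin rule and exact
    marginals for the single-gene rules.
    """
    opts = options or PhenotypeOptions()
    if cohort.is_joint:
        wide = cohort.df.pivot(index="sample_id", columns="gene", values="diplotype")
        flag_cache: dict[tuple, dict] = {}
        totals = {d: 0.0 for d in ("warfarin", "clopidogrel", "codeine", "tacrolimus")}
        for _, row in wide.iterrows():
            key = tuple(row[g] for g in wide.columns)
            if key not in flag_cache:
                flag_cache[key] = actionable_flags(row.to_dict(), panel, opts)
            for drug, val in flag_cache[key].items():
                totals[drug] += bool(val)
        n = len(wide)
        return {d: v / n for d, v in totals.items()}
    # marginal: per-group independence
    sizes = cohort.group_sizes("CYP2C9").dropna()
    total = float(sizes.sum())
    out = {d: 0.0 for d in ("warfarin", "clopidogrel", "codeine", "tacrolimus")}
    pheno_cache: dict[str, str] = {}
    for group, n in sizes.items():
        def dist(gene: str) -> dict[str, float]:
            sub = cohort.gene_frame(gene)
            return _marginal_distribution(sub[sub["ethnicity"] == group])

        c9, vk = dist("CYP2C9"), dist("VKORC1")
        p_warf = 0.0
        for d9, p9 in c9.items():
            for dv, pv in vk.items():
                if d9 == UND or dv == UND:
                    continue
                carrier = bool(
                    parse_diplotype(d9, "CYP2C9").alleles() & {"*2", "*3"}
                )
                ga_aa = "*2" in parse_diplotype(dv, "VKORC1").alleles()
                aa = dv == "*2/*2"
                if (carrier and ga_aa) or (not carrier and aa):
                    p_warf += p9 * pv
        out["warfarin"] += n * p_warf
        p_clop = sum(
            p for d, p in dist("CYP2C19").items()
            if d != UND and parse_diplotype(d, "CYP2C19").alleles() & {"*2", "*3", "*6"}
        )
        out["clopidogrel"] += n * p_clop
        p_cod = 0.0
        for d, p in dist("CYP2D6").items():
            if d == UND:
                continue
            if d not in pheno_cache:
                pheno_cache[d] = assign_phenotype("CYP2D6", d, panel, opts).phenotype
            if pheno_cache[d] in opts.codeine_actionable:
                p_cod += p
        out["codeine"] += n * p_cod
        p_tac = sum(
            p for d, p in dist("CYP3A5").items()
            if d != UND and "*1" in parse_diplotype(d, "CYP3A5").alleles()
        )
        out["tacrolimus"] += n * p_tac
    return {d: v / total for d, v in out.items()}
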