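"""Star-allele diplotype calling.

For CYP2C9, CYP2C19, CYP3A5 and VKORC1 a diploid genotype vector is matched
exactly against all unordered pairs of defined alleles: a variant must be
hom-var when both alleles of the pair carry it, het when exactly one does,
hom-ref when neither does. A unique match is the call; zero or several
matches (including those created by undetermined genotypes, which act as
wildcards) yield UND.

CYP2D6 adds structural variation. Two copy-number assays bracket the
haplotype space: the exon-9 assay counts every copy except the CYP2D6-2D7
hybrid *36, the intron-2 assay counts every copy, so their difference is
the *36 count and a total below two implies whole-gene deletion (*5)
copies. The caller enumerates all multisets of allele copies consistent
with (i) the exon-9 count, (ii) the intron-2 count, (iii) deletions only
where the copy number forces them, and (iv) the observed zygosities, then
picks a canonical representative: fewest distinct alleles, then fewest
reduced-function copies, then the lexicographically smallest rendering.
Without copy-number data the caller falls back to a two-copy model in
which *36 is excluded (it is indistinguishable from *10 by SNPs alone).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Mapping

import pandas as pd

from ._util import UND
from .nomenclature import Diplotype, HaplotypeCall, allele_sort_key
from .panel import AlleleDefinition, Panel

__all__ = [
    "Cyp2d6CopyState",
    "DiplotypeCall",
    "call_simple_gene",
    "call_cyp2d6",
    "call_gene",
    "call_cohort",
    "implied_copy_state",
    "StarCallError",
]

SIMPLE_GENES = ("CYP2C9", "CYP2C19", "CYP3A5", "VKORC1")
_REDUCED = ("decreased", "none")


class StarCallError(ValueError):
    pass


@dataclass(frozen=True)
class Cyp2d6CopyState:
    """Integer copy numbers from the two CYP2D6 assays.

    exon9_cn counts all non-*36 copies; intron2_cn counts all copies
    (deletion copies amplify in neither region).
    """

    exon9_cn: int
    intron2_cn: int

    def __post_init__(self) -> None:
        if not 0 <= self.exon9_cn <= self.intron2_cn:
            raise StarCallError(
                f"invalid copy state: intron2 >= exon9 >= 0 required, got "
                f"exon9={self.exon9_cn}, intron2={self.intron2_cn}"
            )

    @property
    def n_star36(self) -> int:
        return self.intron2_cn - self.exon9_cn


@dataclass
class DiplotypeCall:
    gene: str
    diplotype: Diplotype | None
    mode: str  # "cn" | "no_cn" | "simple"
    flags: list[str] = field(default_factory=list)

    @property
    def is_und(self) -> bool:
        return self.diplotype is None

    @property
    def text(self) -> str:
        return UND if self.diplotype is None else self.diplotype.render()


# ---------------------------------------------------------------------------
# zygosity matching

def _matches(
    copies: list[AlleleDefinition],
    genotypes: Mapping[str, str],
    assay_ids: list[str],
) -> list[str] | None:
    """Check a candidate multiset of amplifying copies against observed
    genotypes; returns match flags, or None when inconsistent.

    Undetermined genotypes are wildcards. With a single amplifying copy a
    het call is accepted as the hemizygous variant (diploid-assumption
    callers place hemizygotes ambiguously) and flagged.
    """
    k = len(copies)
    flags: list[str] = []
    for assay_id in assay_ids:
        obs = genotypes.get(assay_id, "undetermined")
        if obs == "undetermined":
            continue
        carriers = sum(assay_id in c.defining_variants for c in copies)
        if obs == "hom_ref":
            if carriers != 0:
                return None
        elif obs == "hom_var":
            if k == 0 or carriers != k:
                return None
        elif obs == "het":
            if k >= 2:
                if not 1 <= carriers <= k - 1:
                    return None
            elif k == 1:
                if carriers != 1:
                    return None
                if "hemizygous-het" not in flags:
                    flags.append("hemizygous-het")
            else:
                return None
        else:
            raise StarCallError(f"unknown genotype call {obs!r}")
    return flags


# ---------------------------------------------------------------------------
# simple (non-CNV) genes

def call_simple_gene(
    genotypes: Mapping[str, str], gene: str, panel: Panel
) -> DiplotypeCall:
    """Exact allele-pair matching for a gene without copy-number variation."""
    if gene not in SIMPLE_GENES:
        raise StarCallError(f"{gene} is not a simple (non-CNV) gene")
    assay_ids = panel.gene_assays(gene)
    alleles = sorted(
        panel.gene_alleles(gene), key=lambda a: allele_sort_key(a.name)
    )
    matches: dict[tuple[str, str], list[str]] = {}
    for a, b in combinations_with_replacement(alleles, 2):
        flags = _matches([a, b], genotypes, assay_ids)
        if flags is not None:
            matches[(a.name, b.name)] = flags
    if len(matches) != 1:
        return DiplotypeCall(gene, None, "simple", ["ambiguous" if matches else "no-match"])
    (pair, flags), = matches.items()
    n_het = sum(genotypes.get(a, "") == "het" for a in assay_ids)
    variant_bearing = {
        n for n in pair if panel.allele(gene, n).defining_variants
    }
    if n_het >= 2 and len(variant_bearing) == 2:
        # e.g. *2/*17 from two het sites: a cis arrangement matches no
        # defined allele, so trans is assumed
        flags = flags + ["phase-assumed"]
    return DiplotypeCall(
        gene, Diplotype.of(gene, pair[0], pair[1]), "simple", flags
    )


# ---------------------------------------------------------------------------
# CYP2D6

def _slot(allele: str, mult: int) -> HaplotypeCall:
    # unresolved high multiplicities render as the XN literal
    return HaplotypeCall((allele,), mult if mult <= 3 else None)


def _partition(amplifying: list[str], n_deleted: int, gene: str = "CYP2D6") -> Diplotype:
    """Arrange a multiset of copies into two haplotype slots, reproducing
    the reporting conventions of duplication notation."""
    if n_deleted >= 2:
        return Diplotype.of(gene, "*5", "*5")
    if n_deleted == 1:
        (only,) = amplifying
        return Diplotype.of(gene, "*5", only)
    counts = Counter(amplifying)
    names = sorted(counts, key=allele_sort_key)
    if len(names) == 1:
        a, k = names[0], counts[names[0]]
        return Diplotype(gene, (_slot(a, k // 2), _slot(a, k - k // 2)))
    if len(names) == 2:
        a, b = names
        if counts[a] == counts[b] == 2 and any(n == "*36" for n in names):
            # symmetric hybrid duplication: each chromosome carries the
            # same two-gene tandem, written "(…)X2"
            slot = HaplotypeCall((a, b), 1)
            return Diplotype(gene, (slot, slot))
        return Diplotype(gene, (_slot(a, counts[a]), _slot(b, counts[b])))
    # >2 distinct alleles: no standard two-slot notation; chain the minor
    # alleles as a tandem on one chromosome
    major = max(names, key=lambda n: counts[n])
    chain = tuple(
        sorted(
            (n for n in amplifying if n != major), key=allele_sort_key
        )
    )
    return Diplotype(
        gene, (_slot(major, counts[major]), HaplotypeCall(chain, 1))
    )


def _canonical_key(
    multiset: tuple[str, ...], panel: Panel, rendered: str
) -> tuple[int, int, str]:
    reduced = sum(
        panel.allele("CYP2D6", n).activity in _REDUCED for n in multiset
    )
    return (len(set(multiset)), reduced, rendered)


def call_cyp2d6(
    genotypes: Mapping[str, str],
    copy_state: Cyp2d6CopyState | None,
    panel: Panel,
    max_exon9_cn: int = 6,
) -> DiplotypeCall:
    """Resolve the CYP2D6 diplotype from SNP genotypes and, when present,
    the two-region copy state."""
    if copy_state is None:
        return _call_cyp2d6_no_cn(genotypes, panel)
    gene = "CYP2D6"
    assay_ids = panel.gene_assays(gene)
    if copy_state.exon9_cn > max_exon9_cn:
        return DiplotypeCall(gene, None, "cn", ["exon9-cn-above-enumeration-cap"])
    if copy_state.intron2_cn == 0:
        flags = _matches([], genotypes, assay_ids)
        if flags is None:
            return DiplotypeCall(gene, None, "cn", ["no-match"])
        return DiplotypeCall(gene, Diplotype.of(gene, "*5", "*5"), "cn", flags)
    n36 = copy_state.n_star36
    n_deleted = max(0, 2 - copy_state.intron2_cn)
    star36 = panel.allele(gene, "*36")
    candidates = [
        a
        for a in panel.gene_alleles(gene)
        if not a.is_deletion and not a.is_hybrid
    ]
    best: tuple[tuple, Diplotype, list[str]] | None = None
    for combo in combinations_with_replacement(candidates, copy_state.exon9_cn):
        copies = list(combo) + [star36] * n36
        flags = _matches(copies, genotypes, assay_ids)
        if flags is None:
            continue
        names = tuple(c.name for c in copies)
        dip = _partition(list(names), n_deleted, gene)
        key = _canonical_key(names, panel, dip.render())
        if best is None or key < best[0]:
            best = (key, dip, flags)
    if best is None:
        return DiplotypeCall(gene, None, "cn", ["no-match"])
    return DiplotypeCall(gene, best[1], "cn", best[2])


def _call_cyp2d6_no_cn(genotypes: Mapping[str, str], panel: Panel) -> DiplotypeCall:
    """Two-copy CYP2D6 call ignoring copy number; *36 and *5 are not
    candidates (neither is detectable from SNP data alone)."""
    gene = "CYP2D6"
    assay_ids = panel.gene_assays(gene)
    candidates = [
        a
        for a in panel.gene_alleles(gene)
        if not a.is_deletion and not a.is_hybrid
    ]
    best: tuple[tuple, Diplotype, list[str]] | None = None
    n_matches = 0
    for a, b in combinations_with_replacement(candidates, 2):
        flags = _matches([a, b], genotypes, assay_ids)
        if flags is None:
            continue
        n_matches += 1
        names = (a.name, b.name)
        dip = Diplotype.of(gene, a.name, b.name)
        key = _canonical_key(names, panel, dip.render())
        if best is None or key < best[0]:
            best = (key, dip, flags)
    if best is None:
        return DiplotypeCall(gene, None, "no_cn", ["no-match"])
    flags = best[2] if n_matches == 1 else best[2] + ["ambiguous-resolved"]
    return DiplotypeCall(gene, best[1], "no_cn", flags)


def call_gene(
    genotypes: Mapping[str, str],
    gene: str,
    panel: Panel,
    copy_state: Cyp2d6CopyState | None = None,
) -> DiplotypeCall:
    if gene == "CYP2D6":
        return call_cyp2d6(genotypes, copy_state, panel)
    return call_simple_gene(genotypes, gene, panel)


# ---------------------------------------------------------------------------
# cohort-level driver

def implied_copy_state(diplotype: Diplotype | str, panel: Panel) -> Cyp2d6CopyState:
    """Copy state a CYP2D6 diplotype would produce on the two assays."""
    from .nomenclature import parse_diplotype

    if isinstance(diplotype, str):
        diplotype = parse_diplotype(diplotype, "CYP2D6")
    exon9 = intron2 = 0
    for name in diplotype.copies():
        allele = panel.allele("CYP2D6", name)
        if allele.is_deletion:
            continue
        intron2 += 1
        if not allele.is_hybrid:
            exon9 += 1
    return Cyp2d6CopyState(exon9, intron2)


class _CallCache:
    """Memoises calls by genotype signature; cohorts contain few distinct
    signatures, so this makes cohort calling near O(distinct)."""

    def __init__(self, panel: Panel):
        self.panel = panel
        self._cache: dict = {}

    def __call__(
        self,
        gene: str,
        genotypes: Mapping[str, str],
        copy_state: Cyp2d6CopyState | None,
    ) -> DiplotypeCall:
        key = (
            gene,
            tuple(sorted(genotypes.items())),
            None if copy_state is None else (copy_state.exon9_cn, copy_state.intron2_cn),
        )
        if key not in self._cache:
            self._cache[key] = call_gene(genotypes, gene, self.panel, copy_state)
        return self._cache[key]


def call_cohort(
    genotype_calls: pd.DataFrame,
    cn_calls: pd.DataFrame | None,
    panel: Panel,
) -> pd.DataFrame:
    """Call every gene for every sample.

    genotype_calls: long frame (sample_id, assay_id, call).
    cn_calls: optional frame (sample_id, region, cn_integer); absent means
    the two-copy "without CN" mode for CYP2D6.

    Returns a results frame (sample_id, gene, diplotype, mode, flags).
    """
    assay_gene = {a.assay_id: a.gene for a in panel.assays.values()}
    unknown = set(genotype_calls["assay_id"]) - set(assay_gene)
    if unknown:
        raise StarCallError(f"genotype calls reference unknown assays: {sorted(unknown)}")
    cn_by_sample: dict[str, Cyp2d6CopyState] = {}
    if cn_calls is not None:
        wide = cn_calls.pivot_table(
            index="sample_id", columns="region", values="cn_integer",
            aggfunc="first",
        )
        for sample_id, row in wide.iterrows():
            try:
                cn_by_sample[str(sample_id)] = Cyp2d6CopyState(
                    int(row["exon9"]), int(row["intron2"])
                )
            except (StarCallError, KeyError, ValueError):
                cn_by_sample[str(sample_id)] = None  # type: ignore[assignment]
    cached = _CallCache(panel)
    rows = []
    for sample_id, sample_rows in genotype_calls.groupby("sample_id", sort=False):
        calls = dict(zip(sample_rows["assay_id"], sample_rows["call"]))
        for gene in panel.genes():
            genotypes = {
                a: calls.get(a, "undetermined") for a in panel.gene_assays(gene)
            }
            state = cn_by_sample.get(str(sample_id)) if gene == "CYP2D6" else None
            if gene == "CYP2D6" and cn_calls is not None and state is None:
                result = DiplotypeCall(gene, None, "cn", ["invalid-copy-state"])
            else:
                result = cached(gene, genotypes, state)
            rows.append(
                dict(
                    sample_id=sample_id,
                    gene=gene,
                    diplotype=result.text,
                    mode=result.mode,
                    flags=";".join(result.flags),
                )
            )
    return pd.DataFrame(rows)
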