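"""Panel model: the 32 TaqMan assays, star-allele definitions and
per-allele activity values for CYP2C9, CYP2C19, CYP2D6, CYP3A5 and VKORC1.

The panel ships as a versioned TSV (``data/panel.tsv``) with one ``variant``
row per assay and one ``allele`` row per (gene, star allele, defining
variant). Alleles are matched on assay identifiers rather than raw rsids so
that the one locus probed in two allele contexts (rs5030865, G>T defining *8
and G>A defining *14) stays distinguishable.

Besides loading/validation, the panel provides the forward map
:meth:`Panel.implied_genotypes` from a diplotype to the diploid genotype
vector its gene copies imply — the generative model used by the simulator
and by round-trip tests of the star-allele caller.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._util import GENES
from .nomenclature import Diplotype, parse_diplotype

__all__ = ["VariantAssay", "AlleleDefinition", "Panel", "load_panel", "PanelError"]

DELETION = "whole-gene-deletion"
HYBRID = "hybrid-exon9-conversion"

_PANEL_COLUMNS = [
    "record", "gene", "assay_id", "rsid", "allele", "ref_state", "alt_state",
    "change", "effect", "activity", "score", "structural",
]


class PanelError(ValueError):
    """Raised when a panel definition file fails validation."""


@dataclass(frozen=True)
class VariantAssay:
    gene: str
    assay_id: str
    rsid: str
    ref_state: str
    alt_state: str
    change: str = ""
    effect: str = ""


@dataclass(frozen=True)
class AlleleDefinition:
    gene: str
    name: str
    defining_variants: frozenset[str]  # assay ids required present
    activity: str  # increased | normal | decreased | none
    score: float | None  # per-copy activity score; None = categorical only
    structural: str = "snv-defined"

    @property
    def is_deletion(self) -> bool:
        return self.structural == DELETION

    @property
    def is_hybrid(self) -> bool:
        return self.structural == HYBRID


@dataclass
class Panel:
    assays: dict[str, VariantAssay]
    alleles: dict[tuple[str, str], AlleleDefinition]
    version: str = "1"
    _by_gene: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_gene = {}
        for a in self.assays.values():
            self._by_gene.setdefault(a.gene, []).append(a.assay_id)

    # -- lookups -----------------------------------------------------------
    def genes(self) -> list[str]:
        return [g for g in GENES if g in self._by_gene or any(k[0] == g for k in self.alleles)]

    def gene_assays(self, gene: str) -> list[str]:
        return list(self._by_gene.get(gene, []))

    def gene_alleles(self, gene: str) -> list[AlleleDefinition]:
        return [a for (g, _), a in self.alleles.items() if g == gene]

    def allele(self, gene: str, name: str) -> AlleleDefinition:
        try:
            return self.alleles[(gene, name)]
        except KeyError:
            raise PanelError(f"unknown allele {gene} {name}") from None

    def activity_score(self, gene: str, name: str) -> float | None:
        return self.allele(gene, name).score

    # -- forward model -----------------------------------------------------
    def implied_genotypes(
        self, gene: str, diplotype: Diplotype | str, n_for_unresolved: int = 4
    ) -> dict[str, str]:
        """Genotype vector implied by a diplotype's gene copies.

        For each panel assay of the gene: hom_var if every amplifying copy
        carries the variant, het if some but not all do, hom_ref if none.
        Whole-gene-deletion copies contribute no states (they carry no
        amplifiable target), so e.g. *4/*5 implies hom_var at the *4 sites.
        """
        if isinstance(diplotype, str):
            diplotype = parse_diplotype(diplotype, gene)
        copies = [
            self.allele(gene, name)
            for name in diplotype.copies(n_for_unresolved)
        ]
        amplifying = [a for a in copies if not a.is_deletion]
        n = len(amplifying)
        calls: dict[str, str] = {}
        for assay_id in self.gene_assays(gene):
            carriers = sum(assay_id in a.defining_variants for a in amplifying)
            if n == 0 or carriers == 0:
                calls[assay_id] = "hom_ref"
            elif carriers == n:
                calls[assay_id] = "hom_var"
            else:
                calls[assay_id] = "het"
        return calls

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for a in self.assays.values():
            key = (a.gene, a.rsid)
            if key in seen and seen[key] == a.alt_state:
                raise PanelError(
                    f"duplicate assay for {a.rsid} with identical alt state"
                )
            seen[key] = a.alt_state
        genes_with_alleles = {g for g, _ in self.alleles}
        for gene in genes_with_alleles:
            if (gene, "*1") not in self.alleles:
                raise PanelError(f"panel lacks reference allele *1 for {gene}")
        for (gene, name), allele in self.alleles.items():
            for assay_id in allele.defining_variants:
                if assay_id not in self.assays:
                    raise PanelError(
                        f"{gene} {name} references unknown assay {assay_id!r}"
                    )
                if self.assays[assay_id].gene != gene:
                    raise PanelError(
                        f"{gene} {name} references assay {assay_id!r} of "
                        f"another gene"
                    )
        ref = self.alleles.get(("CYP2D6", "*1"))
        if ref is not None and ref.defining_variants:
            raise PanelError("*1 must have no defining variants")


def _read_table(source: str | Path) -> pd.DataFrame:
    if source == "builtin":
        ref = importlib.resources.files("pgxpanel.data") / "panel.tsv"
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    else:
        df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    missing = set(_PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise PanelError(f"panel file lacks columns: {sorted(missing)}")
    return df.fillna("")


def load_panel(source: str | Path = "builtin") -> Panel:
    """Load and validate a panel definition (``"builtin"`` or a TSV path)."""
    df = _read_table(source)
    assays: dict[str, VariantAssay] = {}
    for _, row in df[df["record"] == "variant"].iterrows():
        assay_id = row["assay_id"]
        if assay_id in assays:
            raise PanelError(f"duplicate assay id {assay_id!r}")
        assays[assay_id] = VariantAssay(
            gene=row["gene"], assay_id=assay_id, rsid=row["rsid"],
            ref_state=row["ref_state"], alt_state=row["alt_state"],
            change=row["change"], effect=row["effect"],
        )
    alleles: dict[tuple[str, str], AlleleDefinition] = {}
    grouped = df[df["record"] == "allele"].groupby(["gene", "allele"], sort=False)
    for (gene, name), rows in grouped:
        activities = rows["activity"].unique()
        structurals = rows["structural"].unique()
        if len(activities) != 1 or len(structurals) != 1:
            raise PanelError(f"inconsistent rows for allele {gene} {name}")
        scores = rows["score"].unique()
        if len(scores) != 1:
            raise PanelError(f"inconsistent activity score for {gene} {name}")
        score = float(scores[0]) if scores[0] != "" else None
        defining = frozenset(a for a in rows["assay_id"] if a)
        alleles[(gene, name)] = AlleleDefinition(
            gene=gene, name=name, defining_variants=defining,
            activity=activities[0], score=score, structural=structurals[0],
        )
    panel = Panel(assays=assays, alleles=alleles)
    panel.validate()
    return panel


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel back to its TSV dialect (round-trippable)."""
    rows: list[dict] = []
    for a in panel.assays.values():
        rows.append(dict(
            record="variant", gene=a.gene, assay_id=a.assay_id, rsid=a.rsid,
            allele="", ref_state=a.ref_state, alt_state=a.alt_state,
            change=a.change, effect=a.effect, activity="", score="",
            structural="",
        ))
    for (gene, name), al in panel.alleles.items():
        score = "" if al.score is None else al.score
        defining = sorted(al.defining_variants) or [""]
        for assay_id in defining:
            rows.append(dict(
                record="allele", gene=gene, assay_id=assay_id, rsid="",
                allele=name, ref_state="", alt_state="", change="", effect="",
                activity=al.activity, score=score, structural=al.structural,
            ))
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def resolve_diplotypes(panel: Panel, gene: str, texts: Iterable[str]) -> list[Diplotype]:
    """Parse diplotype strings, checking every allele against the panel."""
    out = []
    for text in texts:
        d = parse_diplotype(text, gene)
        for name in d.alleles():
            panel.allele(gene, name)
        out.append(d)
    return out
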