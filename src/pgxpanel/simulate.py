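"""Synthetic-cohort generator with known truth at every pipeline level.

The generator draws per-gene diplotypes independently for each subject
from ethnicity-stratified frequency tables (the built-in default is the
observed 506-subject Singapore cohort distribution, with undetermined rows
dropped and the remainder renormalized — an unknown truth cannot be
simulated). From each diplotype it derives:

* the implied diploid genotype vector (via the panel's forward map),
* the true exon-9/intron-2 copy numbers (*36 copies count only in
  intron 2, deletion copies in neither),
* quadruplicate Ct values around the ddCt-implied means with Gaussian
  noise, plus a designated calibrator sample at CN 2/2 (CN 0 emits the
  "no-Cq" sentinel),
* two-channel endpoint fluorescence clustered at ~5/45/85 degrees with
  Gaussian angular noise, plus no-template controls.

Genes are independent within a subject (only marginal tables are
published), so joint statistics are reproduced only approximately.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import GROUPS, UND
from .panel import Panel, load_panel
from .popstats import CohortTable
from .starcall import implied_copy_state

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "cohort_from_counts",
    "load_cohort_counts",
    "default_diplotype_frequencies",
    "SimulateError",
]

_ANGLE_DEG = {"hom_ref": 5.0, "het": 45.0, "hom_var": 85.0}


class SimulateError(ValueError):
    pass


def load_cohort_counts() -> pd.DataFrame:
    """Built-in per-gene diplotype count table of the 506-subject cohort
    (columns gene, diplotype, phenotype, Malay, Indian, Chinese)."""
    ref = importlib.resources.files("pgxpanel.data") / "sg506_counts.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def default_diplotype_frequencies(
    counts: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-gene diplotype frequency tables per ethnic group, derived from
    the built-in cohort counts with UND rows removed and renormalized."""
    counts = load_cohort_counts() if counts is None else counts
    tables: dict[str, pd.DataFrame] = {}
    for gene, sub in counts.groupby("gene"):
        sub = sub[sub["diplotype"] != UND]
        table = sub.set_index("diplotype")[list(GROUPS)].astype(float)
        table = table / table.sum(axis=0)
        tables[gene] = table
    return tables


@dataclass
class SimulationConfig:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"Malay": 126, "Indian": 179, "Chinese": 201}
    )
    diplotype_freqs: dict[str, pd.DataFrame] | None = None  # default: built-in
    ct_noise_sd: float = 0.05  # cycles, per replicate and channel
    angle_sd_deg: float = 3.0
    n_replicates: int = 4
    radius_mean: float = 1.0
    radius_sd: float = 0.05
    ntc_radius: float = 0.05
    ntc_radius_sd: float = 0.01
    reference_ct: float = 25.0
    base_delta_ct: float = 0.5  # calibrator dCt (target - reference at CN 2)
    n_for_unresolved: int = 4  # copies instantiated for an "XN" multiplicity
    calibrator_id: str = "CAL01"
    seed: int = 0

    def frequencies(self) -> dict[str, pd.DataFrame]:
        tables = (
            default_diplotype_frequencies()
            if self.diplotype_freqs is None
            else self.diplotype_freqs
        )
        for gene, table in tables.items():
            sums = table.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise SimulateError(
                    f"{gene} frequency columns must sum to 1, got {dict(sums)}"
                )
        return tables


@dataclass
class SimulatedCohort:
    truth: pd.DataFrame          # sample_id, ethnicity, gene, diplotype, CNs
    genotypes: pd.DataFrame      # sample_id, assay_id, call (truth genotypes)
    fluorescence: pd.DataFrame   # sample_id, assay_id, x, y, is_ntc
    ct: pd.DataFrame             # sample_id, region, well, target_ct, reference_ct
    sample_sheet: pd.DataFrame   # sample_id, ethnicity, is_calibrator

    def truth_cohort(self) -> CohortTable:
        df = self.truth[self.truth["ethnicity"] != "calibrator"]
        return CohortTable(df.reset_index(drop=True))

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("truth", self.truth),
            ("genotypes", self.genotypes),
            ("fluorescence", self.fluorescence),
            ("ct", self.ct),
            ("sample_sheet", self.sample_sheet),
        ):
            path = outdir / f"{name}.tsv"
            out = df.copy()
            if name == "ct":
                for col in ("target_ct", "reference_ct"):
                    out[col] = out[col].map(
                        lambda v: "no-Cq" if pd.isna(v) else f"{v:.6f}"
                    )
            out.to_csv(path, sep="\t", index=False)
            paths[name] = path
        return paths


def simulate_cohort(
    config: SimulationConfig | None = None, panel: Panel | None = None
) -> SimulatedCohort:
    """Generate a full synthetic cohort; seeded and bit-for-bit
    reproducible."""
    config = config or SimulationConfig()
    panel = panel or load_panel()
    rng = np.random.default_rng(config.seed)
    tables = config.frequencies()

    sample_ids: list[str] = []
    ethnicities: list[str] = []
    for group, n in config.group_sizes.items():
        prefix = group[:2].upper()
        for i in range(n):
            sample_ids.append(f"{prefix}{i + 1:05d}")
            ethnicities.append(group)

    geno_cache: dict[tuple[str, str], dict[str, str]] = {}
    cn_cache: dict[str, tuple[int, int]] = {}

    truth_rows = []
    geno_rows: list[tuple[str, str, str]] = []
    per_sample_d6_cn: dict[str, tuple[int, int]] = {}
    for sample_id, group in zip(sample_ids, ethnicities):
        for gene, table in tables.items():
            dips = table.index.to_numpy()
            dip = str(rng.choice(dips, p=table[group].to_numpy()))
            if gene == "CYP2D6":
                if dip not in cn_cache:
                    cs = implied_copy_state(dip, panel)
                    cn_cache[dip] = (cs.exon9_cn, cs.intron2_cn)
                exon9, intron2 = cn_cache[dip]
                per_sample_d6_cn[sample_id] = (exon9, intron2)
            else:
                exon9 = intron2 = np.nan
            truth_rows.append(
                dict(sample_id=sample_id, ethnicity=group, gene=gene,
                     diplotype=dip, exon9_cn=exon9, intron2_cn=intron2)
            )
            key = (gene, dip)
            if key not in geno_cache:
                geno_cache[key] = panel.implied_genotypes(
                    gene, dip, config.n_for_unresolved
                )
            for assay_id, call in geno_cache[key].items():
                geno_rows.append((sample_id, assay_id, call))

    # calibrator: reference-genotype sample at CN 2/2
    cal = config.calibrator_id
    for gene in tables:
        truth_rows.append(
            dict(sample_id=cal, ethnicity="calibrator", gene=gene,
                 diplotype="*1/*1",
                 exon9_cn=2 if gene == "CYP2D6" else np.nan,
                 intron2_cn=2 if gene == "CYP2D6" else np.nan)
        )
        for assay_id, call in panel.implied_genotypes(gene, "*1/*1").items():
            geno_rows.append((cal, assay_id, call))
    per_sample_d6_cn[cal] = (2, 2)

    truth = pd.DataFrame(truth_rows)
    genotypes = pd.DataFrame(geno_rows, columns=["sample_id", "assay_id", "call"])

    fluorescence = _simulate_fluorescence(
        genotypes, per_sample_d6_cn, panel, config, rng
    )
    ct = _simulate_ct(per_sample_d6_cn, config, rng)
    sheet = pd.DataFrame(
        dict(
            sample_id=sample_ids + [cal],
            ethnicity=ethnicities + ["calibrator"],
            is_calibrator=[False] * len(sample_ids) + [True],
        )
    )
    return SimulatedCohort(truth, genotypes, fluorescence, ct, sheet)


def _simulate_fluorescence(
    genotypes: pd.DataFrame,
    d6_cn: dict[str, tuple[int, int]],
    panel: Panel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(genotypes)
    assay_gene = {a.assay_id: a.gene for a in panel.assays.values()}
    angles = genotypes["call"].map(_ANGLE_DEG).to_numpy(float)
    theta = np.radians(angles + rng.normal(0.0, config.angle_sd_deg, n))
    radius = np.clip(
        rng.normal(config.radius_mean, config.radius_sd, n), 0.2, None
    )
    # CYP2D6 assays of a whole-gene-deletion homozygote never amplify
    is_d6 = genotypes["assay_id"].map(assay_gene).eq("CYP2D6").to_numpy()
    no_template = genotypes["sample_id"].map(
        lambda s: d6_cn.get(s, (2, 2))[1] == 0
    ).to_numpy()
    dead = is_d6 & no_template
    radius[dead] = np.clip(
        rng.normal(config.ntc_radius, config.ntc_radius_sd, int(dead.sum())),
        0.0, None,
    )
    theta[dead] = rng.uniform(0.0, np.pi / 2.0, int(dead.sum()))
    frame = pd.DataFrame(
        dict(
            sample_id=genotypes["sample_id"],
            assay_id=genotypes["assay_id"],
            x=np.clip(radius * np.cos(theta), 0.0, None),
            y=np.clip(radius * np.sin(theta), 0.0, None),
            is_ntc=False,
        )
    )
    ntc_rows = []
    for assay_id in genotypes["assay_id"].unique():
        r = max(0.0, rng.normal(config.ntc_radius, config.ntc_radius_sd))
        a = rng.uniform(0.0, np.pi / 2.0)
        ntc_rows.append(
            dict(sample_id="NTC", assay_id=assay_id,
                 x=r * np.cos(a), y=r * np.sin(a), is_ntc=True)
        )
    return pd.concat([frame, pd.DataFrame(ntc_rows)], ignore_index=True)


def _simulate_ct(
    d6_cn: dict[str, tuple[int, int]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    reps = config.n_replicates
    for sample_id, (exon9, intron2) in d6_cn.items():
        for region, cn in (("exon9", exon9), ("intron2", intron2)):
            for well in range(reps):
                ref = config.reference_ct + rng.normal(0.0, config.ct_noise_sd)
                if cn == 0:
                    target = np.nan
                else:
                    target = (
                        config.reference_ct
                        + config.base_delta_ct
                        - np.log2(cn / 2.0)
                        + rng.normal(0.0, config.ct_noise_sd)
                    )
                rows.append(
                    dict(sample_id=sample_id, region=region, well=well + 1,
                         target_ct=target, reference_ct=ref)
                )
    return pd.DataFrame(rows)


def cohort_from_counts(
    counts: pd.DataFrame | None = None,
    expected_group_sizes: dict[str, int] | None = None,
) -> CohortTable:
    """Deterministic marginal cohort containing exactly the given per-gene
    diplotype counts (default: the built-in 506-subject table). Sample
    identities are per-gene placeholders, so the result is a *marginal*
    cohort: statistics coupling genes fall back to independence."""
    counts = load_cohort_counts() if counts is None else counts
    groups = [g for g in counts.columns if g in GROUPS or g not in
              ("gene", "diplotype", "phenotype")]
    if (counts[groups].to_numpy() < 0).any():
        raise SimulateError("negative diplotype counts")
    rows = []
    for gene, sub in counts.groupby("gene", sort=False):
        for group in groups:
            i = 0
            for _, r in sub.iterrows():
                for _ in range(int(r[group])):
                    i += 1
                    row = dict(
                        sample_id=f"{group[:2].upper()}{i:04d}:{gene}",
                        ethnicity=group, gene=gene, diplotype=r["diplotype"],
                    )
                    if "phenotype" in counts.columns:
                        row["phenotype"] = (
                            "" if pd.isna(r["phenotype"]) else str(r["phenotype"])
                        )
                    rows.append(row)
            if expected_group_sizes and group in expected_group_sizes:
                if i != expected_group_sizes[group]:
                    warnings.warn(
                        f"{gene}/{group}: counts total {i} != declared "
                        f"{expected_group_sizes[group]}; proceeding with {i}",
                        stacklevel=2,
                    )
    if not rows:
        return CohortTable(pd.DataFrame(columns=list(CohortTable.REQUIRED)))
    return CohortTable(pd.DataFrame(rows))
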