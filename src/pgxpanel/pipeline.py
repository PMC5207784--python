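"""End-to-end driver: raw measurements to phenotyped cohort."""

from __future__ import annotations

import pandas as pd

from .cnv import CnvConfig, call_cohort_cn
from .genotyping import GenotypingConfig, call_plate
from .panel import Panel, load_panel
from .phenotype import PhenotypeOptions, add_phenotypes
from .popstats import CohortTable
from .starcall import call_cohort

__all__ = ["run_pipeline", "cohort_from_results"]


def run_pipeline(
    genotype_calls: pd.DataFrame | None = None,
    fluorescence: pd.DataFrame | None = None,
    ct: pd.DataFrame | None = None,
    calibrator_id: str | None = None,
    panel: Panel | None = None,
    genotyping_config: GenotypingConfig | None = None,
    cnv_config: CnvConfig | None = None,
    phenotype_options: PhenotypeOptions | None = None,
) -> pd.DataFrame:
    """Run genotype calling (if fluorescence is given), copy-number calling
    (if Ct data is given), star-allele resolution and phenotype
    translation; returns the per-sample results frame."""
    panel = panel or load_panel()
    if genotype_calls is None:
        if fluorescence is None:
            raise ValueError("need genotype calls or fluorescence signals")
        genotype_calls, _ = call_plate(fluorescence, genotyping_config)
    cn_calls = None
    if ct is not None:
        if calibrator_id is None:
            raise ValueError("copy-number calling needs a calibrator id")
        cn_calls = call_cohort_cn(ct, calibrator_id, config=cnv_config)
    results = call_cohort(genotype_calls, cn_calls, panel)
    return add_phenotypes(results, panel, phenotype_options)


def cohort_from_results(
    results: pd.DataFrame, sample_sheet: pd.DataFrame
) -> CohortTable:
    """Join per-sample results with ethnicity labels into a cohort table."""
    merged = results.merge(sample_sheet, on="sample_id", how="inner")
    return CohortTable(merged.reset_index(drop=True))
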