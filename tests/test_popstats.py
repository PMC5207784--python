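"""Cohort statistics: frequencies, HWE, Fst, MAF, CN and actionable rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pgxpanel.popstats import (
    PopStatsError,
    actionable_rates,
    allele_frequencies,
    cn_concordance,
    cn_distribution,
    drug_actionable_rates,
    hwe_chisq,
    hwe_table,
    phenotype_table,
    pooled_maf,
    wright_fst,
)


# -- allele frequencies -----------------------------------------------------

def test_cyp2c9_star3_frequency_malay(cohort):
    freqs = allele_frequencies(cohort, "CYP2C9", round_digits=3)
    # 13 het + 1 hom over 126 subjects = 15/252
    assert freqs.loc["*3", "Malay"] == pytest.approx(0.060)
    assert freqs.loc["*3", "Indian"] == pytest.approx(0.128)
    assert freqs.loc["*3", "Chinese"] == pytest.approx(0.027)


def test_vkorc1_star2_frequency_chinese(cohort):
    freqs = allele_frequencies(cohort, "VKORC1", round_digits=3)
    assert freqs.loc["*2", "Chinese"] == pytest.approx(0.898)  # 361/402


def test_frequencies_sum_to_one_for_simple_genes(cohort):
    for gene in ("CYP2C9", "CYP3A5", "VKORC1"):
        freqs = allele_frequencies(cohort, gene)
        np.testing.assert_allclose(freqs.sum(axis=0), 1.0, atol=1e-12)


def test_und_subjects_stay_in_the_denominator(cohort):
    # Indian CYP2C19 *17: 54 of 2 x 179 chromosomes, UND subject included
    freqs = allele_frequencies(cohort, "CYP2C19")
    assert freqs.loc["*17", "Indian"] == pytest.approx(54 / 358)


def test_cyp2d6_uses_flagged_presence_convention(cohort):
    freqs = allele_frequencies(cohort, "CYP2D6")
    assert "presence" in freqs.attrs["convention"]


# -- Hardy-Weinberg ---------------------------------------------------------

def test_hwe_exact_proportions_give_zero():
    res = hwe_chisq(25, 50, 25)
    assert res.chi2 == pytest.approx(0.0) and res.pvalue == pytest.approx(1.0)


def test_hwe_hand_computed_example():
    # p = q = 0.5, expected (25, 50, 25)
    assert hwe_chisq(30, 40, 30).chi2 == pytest.approx(4.0)


def test_hwe_chinese_vkorc1_not_significant():
    res = hwe_chisq(161, 39, 1)
    assert res.chi2 == pytest.approx(0.7057, abs=1e-4)
    assert res.pvalue > 0.05


def test_hwe_monomorphic_not_applicable():
    assert not hwe_chisq(0, 0, 50).applicable


def test_hwe_agrees_with_brute_force_oracle():
    """Independent recomputation: expectations from allele counts, then
    the plain chi-squared sum, cross-checked against scipy."""
    rng = np.random.default_rng(3)
    for _ in range(300):
        n_aa, n_ab, n_bb = rng.integers(1, 200, size=3)
        n = n_aa + n_ab + n_bb
        p = (2 * n_aa + n_ab) / (2 * n)
        expected = [n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)]
        observed = [n_aa, n_ab, n_bb]
        oracle = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
        res = hwe_chisq(n_aa, n_ab, n_bb)
        assert res.chi2 == pytest.approx(oracle, abs=1e-9)
        scipy_chi2, _ = sps.chisquare(observed, expected, ddof=1)
        assert res.chi2 == pytest.approx(float(scipy_chi2), abs=1e-9)
        assert res.pvalue == pytest.approx(float(sps.chi2.sf(oracle, 1)), abs=1e-12)


def test_cohort_is_in_hardy_weinberg_equilibrium(cohort):
    table = hwe_table(cohort)
    applicable = table[table["applicable"]]
    assert len(applicable) >= 20
    assert (applicable["pvalue"] >= 0.05).all()


# -- Fst and pooled MAF -----------------------------------------------------

def test_fst_published_values():
    assert wright_fst([0.710, 0.182, 0.898]).fst == pytest.approx(0.382, abs=5e-4)
    assert wright_fst([0.024, 0.151, 0.010]).fst == pytest.approx(0.070, abs=6e-4)


def test_fst_zero_for_equal_frequencies():
    assert wright_fst([0.3, 0.3, 0.3]).fst == pytest.approx(0.0, abs=1e-12)


def test_fst_not_applicable_when_fixed_everywhere():
    assert not wright_fst([0.0, 0.0]).applicable
    assert not wright_fst([1.0, 1.0]).applicable


@settings(max_examples=200, derandomize=True)
@given(
    ps=st.lists(st.floats(0.01, 0.99), min_size=2, max_size=5)
)
def test_fst_invariant_to_allele_relabelling(ps):
    direct = wright_fst(ps).fst
    flipped = wright_fst([1 - p for p in ps]).fst
    assert direct == pytest.approx(flipped, abs=1e-12)
    assert -1e-12 <= direct <= 1.0


def test_pooled_maf_is_unweighted_mean():
    assert pooled_maf([0.274, 0.380, 0.373]) == pytest.approx(0.342)
    assert pooled_maf([0.060, 0.128, 0.027]) == pytest.approx(0.072)
    assert pooled_maf([0.31]) == pytest.approx(0.310)
    # no folding: frequencies above 0.5 are reported as-is
    assert pooled_maf([0.587, 0.637, 0.734]) == pytest.approx(0.653)


# -- phenotype and CN tables ------------------------------------------------

def test_phenotype_table_chinese_cyp3a5(cohort, panel):
    table = phenotype_table(cohort, "CYP3A5", panel)
    assert table.loc["PM", "Chinese"] == 113
    assert table.loc["PM", "Chinese_freq"] == pytest.approx(0.562)


def test_phenotype_table_indian_cyp2c9_pm_count(cohort, panel):
    table = phenotype_table(cohort, "CYP2C9", panel)
    assert table.loc["PM", "Indian"] == 6  # 2 (*2/*3) + 4 (*3/*3)


def test_cn_distribution_trivial_cohort(panel):
    import pandas as pd

    from pgxpanel.popstats import CohortTable

    df = pd.DataFrame(
        dict(sample_id=[f"S{i}" for i in range(10)], ethnicity="Chinese",
             gene="CYP2D6", diplotype="*1/*1")
    )
    dist = cn_distribution(CohortTable(df), panel)
    assert dist[("exon9", "Chinese")]["2"] == pytest.approx(1.0)
    assert dist[("intron2", "Chinese")]["2"] == pytest.approx(1.0)


def test_cn_distribution_chinese_high_copy_fraction(cohort, panel):
    dist = cn_distribution(cohort, panel)
    chinese_i2 = dist[("intron2", "Chinese")]
    # reconstructed diplotypes put ~43% at three and ~16% above three
    # intron-2 copies in this group (UND subjects carry no copy state)
    assert chinese_i2["3"] == pytest.approx(0.433, abs=0.02)
    assert chinese_i2["4 and above"] == pytest.approx(0.164, abs=0.02)


def test_two_assay_concordance_near_62_percent(cohort, panel):
    # *36 carriers split the two assays, deletions do not
    assert cn_concordance(cohort, panel) == pytest.approx(0.62, abs=0.01)


# -- actionable rates -------------------------------------------------------

def test_actionable_rates_on_reconstructed_cohort(cohort, panel):
    rates = actionable_rates(cohort, panel)
    assert rates["CYP2C9"] == pytest.approx(81 / 506)
    assert rates["CYP2C19"] == pytest.approx(344 / 506)
    assert rates["CYP2D6"] == pytest.approx(422 / 506)
    assert rates["CYP3A5"] == pytest.approx(71 / 506)
    assert 0.95 <= rates["any_gene"] <= 0.99


def test_all_reference_cohort_has_no_actionable_variants(panel):
    import pandas as pd

    from pgxpanel.popstats import CohortTable

    rows = []
    for gene, dip in (("CYP2C9", "*1/*1"), ("CYP2C19", "*1/*1"),
                      ("CYP2D6", "*1/*1"), ("CYP3A5", "*3/*3")):
        rows += [dict(sample_id=f"S{i}", ethnicity="Chinese", gene=gene,
                      diplotype=dip) for i in range(5)]
    rates = actionable_rates(CohortTable(pd.DataFrame(rows)), panel)
    assert all(v == 0.0 for v in rates.values())


def test_drug_rates_on_marginal_cohort(cohort, panel):
    """Single-gene drug rules are exact marginal counts; the two-gene
    warfarin rule uses per-ethnicity independence (hand-computed)."""
    rates = drug_actionable_rates(cohort, panel)
    assert rates["clopidogrel"] == pytest.approx(307 / 506)  # *2/*3/*6 carriers
    assert rates["codeine"] == pytest.approx(163 / 506)      # PM, PM-IM, IM
    assert rates["tacrolimus"] == pytest.approx(270 / 506)   # *1 carriers
    assert rates["warfarin"] == pytest.approx(0.50296, abs=1e-4)


def test_empty_group_rejected(panel):
    import pandas as pd

    from pgxpanel.popstats import CohortTable

    df = pd.DataFrame(
        dict(sample_id=["S1"], ethnicity=["Chinese"], gene=["CYP2C9"],
             diplotype=["UND"])
    )
    cohort = CohortTable(df)
    freqs = allele_frequencies(cohort, "CYP2C9")
    assert freqs.empty or freqs.sum().sum() == 0
    with pytest.raises(PopStatsError):
        allele_frequencies(cohort, "CYP2D6")
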