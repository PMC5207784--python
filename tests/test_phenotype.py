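"""Metabolizer-phenotype translation and actionability rules."""

import pytest

from pgxpanel._util import UND
from pgxpanel.phenotype import (
    PHENOTYPE_ORDER,
    PhenotypeOptions,
    actionable_flags,
    assign_phenotype,
    gene_actionable_variant,
)


@pytest.mark.parametrize(
    "gene,diplotype,expected,score",
    [
        ("CYP2C19", "*2/*17", "IM", None),
        ("CYP2D6", "*2A/*41", "EM", 2.0),
        ("CYP2D6", "*10/*36", "PM-IM", 0.5),
        ("CYP2D6", "*1/*1X2", "UM", 3.0),
        ("CYP2D6", "*1/*1", "EM", 2.0),
        ("CYP2D6", "*2A/*2AX2", "UM", 4.5),
        ("CYP2C9", "*2/*3", "PM", None),
        ("CYP3A5", "*1/*3", "IM", None),
    ],
)
def test_phenotype_examples(panel, gene, diplotype, expected, score):
    call = assign_phenotype(gene, diplotype, panel)
    assert call.phenotype == expected
    if score is not None:
        assert call.activity_score == pytest.approx(score)


def test_cohort_table_reproduced_exhaustively(panel, counts):
    """Every diplotype class of the built-in cohort maps to its recorded
    phenotype; the one disputed CYP2D6 diplotype is handled separately."""
    mismatches = []
    for _, row in counts.iterrows():
        if row["diplotype"] == UND or row["diplotype"] == "*4X2/*36":
            continue
        expected = row["phenotype"] if isinstance(row["phenotype"], str) else ""
        got = assign_phenotype(row["gene"], row["diplotype"], panel).phenotype or ""
        if got != expected:
            mismatches.append((row["gene"], row["diplotype"], got, expected))
    assert not mismatches


def test_disputed_diplotype_is_flagged_and_configurable(panel):
    call = assign_phenotype("CYP2D6", "*4X2/*36", panel)
    assert call.phenotype == "PM"  # additive score 0 + 0 + 0
    assert any("disputed" in w for w in call.warnings)
    legacy = assign_phenotype(
        "CYP2D6", "*4X2/*36", panel, PhenotypeOptions(legacy_labels=True)
    )
    assert legacy.phenotype == "IM"


def test_und_maps_to_und(panel):
    assert assign_phenotype("CYP2D6", UND, panel).phenotype == UND


def test_vkorc1_has_no_metabolizer_phenotype(panel):
    assert assign_phenotype("VKORC1", "*2/*2", panel).phenotype is None


def test_cyp2d6_phenotype_monotone_in_activity(panel, counts):
    """Adding a functional copy never lowers the class; swapping a copy
    for a lower-activity allele never raises it."""
    rank = {p: i for i, p in enumerate(PHENOTYPE_ORDER)}
    d6 = counts[(counts["gene"] == "CYP2D6") & (counts["diplotype"] != UND)]
    scored = []
    for text in d6["diplotype"]:
        call = assign_phenotype("CYP2D6", text, panel)
        scored.append((call.activity_score, rank[call.phenotype]))
    for (s1, r1) in scored:
        for (s2, r2) in scored:
            if s1 < s2:
                assert r1 <= r2
    # an added *1 copy strictly raises the score
    base = assign_phenotype("CYP2D6", "*10/*36", panel)
    more = assign_phenotype("CYP2D6", "*1-*10/*36", panel)
    assert more.activity_score > base.activity_score
    assert rank[more.phenotype] >= rank[base.phenotype]


ALL_REF = {
    "CYP2C9": "*1/*1", "CYP2C19": "*1/*1", "CYP2D6": "*1/*1",
    "CYP3A5": "*3/*3", "VKORC1": "*1/*1",
}


def test_actionable_flags(panel):
    flags = actionable_flags(ALL_REF, panel)
    assert flags == dict(
        warfarin=False, clopidogrel=False, codeine=False, tacrolimus=False
    )
    warf = actionable_flags({**ALL_REF, "CYP2C9": "*1/*3", "VKORC1": "*1/*2"}, panel)
    assert warf["warfarin"] is True
    aa_only = actionable_flags({**ALL_REF, "VKORC1": "*2/*2"}, panel)
    assert aa_only["warfarin"] is True  # *1/*1 CYP2C9 with the AA genotype
    ga_only = actionable_flags({**ALL_REF, "VKORC1": "*1/*2"}, panel)
    assert ga_only["warfarin"] is False
    clop = actionable_flags({**ALL_REF, "CYP2C19": "*1/*2"}, panel)
    assert clop["clopidogrel"] is True
    cod = actionable_flags({**ALL_REF, "CYP2D6": "*10/*10"}, panel)
    assert cod["codeine"] is True  # IM
    tac = actionable_flags({**ALL_REF, "CYP3A5": "*1/*3"}, panel)
    assert tac["tacrolimus"] is True
    und = actionable_flags({**ALL_REF, "CYP2D6": UND}, panel)
    assert und["codeine"] is None


def test_codeine_boundary_classes(panel):
    # IM-EM is not actionable under the default poor/intermediate rule
    imem = actionable_flags({**ALL_REF, "CYP2D6": "*1/*10"}, panel)
    assert imem["codeine"] is False
    pmim = actionable_flags({**ALL_REF, "CYP2D6": "*5/*10"}, panel)
    assert pmim["codeine"] is True


@pytest.mark.parametrize(
    "gene,diplotype,expected",
    [
        ("CYP2C9", "*1/*3", True),
        ("CYP2C9", "*1/*1", False),
        ("CYP2C19", "*1/*17", True),
        ("CYP2D6", "*1/*1", False),
        ("CYP2D6", "*1/*1X2", True),  # duplication is a copy-number departure
        ("CYP2D6", "*1/*10", True),
        ("CYP3A5", "*1/*1", True),   # the atypical-dosing homozygote
        ("CYP3A5", "*1/*3", False),
        ("CYP2D6", UND, None),
    ],
)
def test_gene_actionable_variant_conventions(panel, gene, diplotype, expected):
    assert gene_actionable_variant(gene, diplotype, panel) is expected
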