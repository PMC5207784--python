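"""Star-allele resolution: simple genes and CYP2D6 with copy state."""

from itertools import combinations_with_replacement

import numpy as np
import pytest

from pgxpanel._util import UND
from pgxpanel.nomenclature import parse_diplotype
from pgxpanel.starcall import (
    Cyp2d6CopyState,
    StarCallError,
    call_cyp2d6,
    call_simple_gene,
    implied_copy_state,
)
from pgxpanel.validation import load_hapmap_reference


def genotypes_for(panel, gene, diplotype):
    return panel.implied_genotypes(gene, diplotype)


@pytest.mark.parametrize(
    "gene,nonref,expected",
    [
        ("CYP2C19", {"rs4244285": "het"}, "*1/*2"),
        ("CYP2C9", {"rs1057910": "het"}, "*1/*3"),
        ("VKORC1", {"rs9923231": "hom_var"}, "*2/*2"),
        ("CYP2C19", {"rs4244285": "het", "rs12248560": "het"}, "*2/*17"),
        ("CYP3A5", {}, "*1/*1"),
    ],
)
def test_simple_gene_calls(panel, gene, nonref, expected):
    genotypes = {a: nonref.get(a, "hom_ref") for a in panel.gene_assays(gene)}
    call = call_simple_gene(genotypes, gene, panel)
    assert call.text == expected


def test_trans_phasing_of_double_heterozygote_is_flagged(panel):
    genotypes = {a: "hom_ref" for a in panel.gene_assays("CYP2C19")}
    genotypes.update({"rs4244285": "het", "rs12248560": "het"})
    call = call_simple_gene(genotypes, "CYP2C19", panel)
    assert call.text == "*2/*17" and "phase-assumed" in call.flags


def test_undetermined_variant_makes_simple_call_und(panel):
    genotypes = {a: "hom_ref" for a in panel.gene_assays("CYP2C19")}
    genotypes["rs4244285"] = "undetermined"  # *1/*1, *1/*2 and *2/*2 all fit
    assert call_simple_gene(genotypes, "CYP2C19", panel).is_und


def test_inconsistent_genotypes_yield_und(panel):
    genotypes = {a: "hom_ref" for a in panel.gene_assays("CYP2D6")}
    genotypes["rs16947"] = "hom_var"  # without rs1135840 matches no allele
    assert call_cyp2d6(genotypes, Cyp2d6CopyState(2, 2), panel).is_und


@pytest.mark.parametrize(
    "truth,exon9,intron2,expected",
    [
        ("*2AX2/*36", 2, 3, "*2AX2/*36"),
        ("(*10/*36)X2", 2, 4, "(*10/*36)X2"),
        ("*1X2/*36", 2, 3, "*1X2/*36"),
        ("*2A/*10", 2, 2, "*2A/*10"),
        ("*10/*36", 1, 2, "*10/*36"),
        ("*5/*5", 0, 0, "*5/*5"),
    ],
)
def test_cyp2d6_with_copy_state(panel, truth, exon9, intron2, expected):
    genotypes = genotypes_for(panel, "CYP2D6", truth)
    call = call_cyp2d6(genotypes, Cyp2d6CopyState(exon9, intron2), panel)
    assert call.text == expected


def test_deletion_absorbs_the_missing_copy(panel):
    """A het 100C>T / 4180G>C pattern at CN 1 resolves to *5/*10."""
    genotypes = {a: "hom_ref" for a in panel.gene_assays("CYP2D6")}
    genotypes.update({"rs1065852": "het", "rs1135840": "het"})
    call = call_cyp2d6(genotypes, Cyp2d6CopyState(1, 1), panel)
    assert call.text == "*5/*10"
    assert "hemizygous-het" in call.flags


def test_without_cn_mode_collapses_to_two_copies(panel):
    # the *2AX2/*36 genotype signature without CN reads as *2A/*10
    genotypes = genotypes_for(panel, "CYP2D6", "*2AX2/*36")
    call = call_cyp2d6(genotypes, None, panel)
    assert call.text == "*2A/*10" and call.mode == "no_cn"


def test_invalid_copy_state_rejected():
    with pytest.raises(StarCallError, match="intron2 >= exon9"):
        Cyp2d6CopyState(3, 2)


def test_implied_copy_state(panel):
    cs = implied_copy_state("*10X2/*36X3", panel)
    assert (cs.exon9_cn, cs.intron2_cn, cs.n_star36) == (2, 5, 3)
    cs = implied_copy_state("*4/*5", panel)
    assert (cs.exon9_cn, cs.intron2_cn) == (1, 1)


def test_cohort_vocabulary_is_recoverable(panel, counts):
    """Every CYP2D6 diplotype observed in the cohort is reproduced exactly
    from its own implied genotypes and copy state."""
    d6 = counts[(counts["gene"] == "CYP2D6") & (counts["diplotype"] != UND)]
    for text in d6["diplotype"]:
        state = implied_copy_state(text, panel)
        call = call_cyp2d6(genotypes_for(panel, "CYP2D6", text), state, panel)
        assert call.text == text, f"{text} -> {call.text}"


def test_copy_conservation_in_returned_calls(panel, counts):
    """Called diplotypes conserve both assay counts: non-*36 copies match
    exon 9 and all amplifying copies match intron 2."""
    d6 = counts[(counts["gene"] == "CYP2D6") & (counts["diplotype"] != UND)]
    for text in d6["diplotype"]:
        state = implied_copy_state(text, panel)
        call = call_cyp2d6(genotypes_for(panel, "CYP2D6", text), state, panel)
        back = implied_copy_state(call.diplotype, panel)
        assert (back.exon9_cn, back.intron2_cn) == (state.exon9_cn, state.intron2_cn)


def test_enumeration_is_total_and_crash_free(panel):
    """Brute-force harness: every multiset of CYP2D6 copies up to four
    copies yields a call or UND, with copy counts conserved."""
    rng = np.random.default_rng(17)
    names = sorted(a.name for a in panel.gene_alleles("CYP2D6") if a.name != "*5")
    multisets = [m for k in (1, 2, 3) for m in combinations_with_replacement(names, k)]
    four = list(combinations_with_replacement(names, 4))
    multisets += [four[i] for i in rng.choice(len(four), 200, replace=False)]
    for multiset in multisets:
        n36 = sum(n == "*36" for n in multiset)
        exon9, intron2 = len(multiset) - n36, len(multiset)
        # derive genotypes directly from the copy multiset
        copies = [panel.allele("CYP2D6", n) for n in multiset]
        genotypes = {}
        for assay in panel.gene_assays("CYP2D6"):
            carriers = sum(assay in c.defining_variants for c in copies)
            genotypes[assay] = (
                "hom_ref" if carriers == 0
                else "hom_var" if carriers == len(copies)
                else "het"
            )
        call = call_cyp2d6(genotypes, Cyp2d6CopyState(exon9, intron2), panel)
        assert not call.is_und, multiset
        back = implied_copy_state(call.diplotype, panel)
        assert (back.exon9_cn, back.intron2_cn) == (exon9, intron2)
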