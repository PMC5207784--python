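"""Translate diplotypes into metabolizer phenotypes and CPIC drug flags.

The CYP2D6 activity score sums per-copy values over all gene copies
(null 0, decreased 0.5, normal 1.0, *2A 1.5), so copy number feeds
directly into the predicted class."""

from pgxpanel import actionable_flags, assign_phenotype, load_panel

panel = load_panel()

examples = [
    ("CYP2D6", "*10/*36"),     # decreased + null -> 0.5
    ("CYP2D6", "*2AX2/*36"),   # duplicated high-activity allele -> 3.0
    ("CYP2D6", "*5/*10"),      # deletion + decreased -> 0.5
    ("CYP2C19", "*2/*17"),     # loss-of-function trumps the booster
    ("CYP3A5", "*1/*3"),
]
print("diplotype -> phenotype (activity score where defined):")
for gene, dip in examples:
    call = assign_phenotype(gene, dip, panel)
    score = "" if call.activity_score is None else f"  score={call.activity_score}"
    print(f"  {gene:8s} {dip:12s} -> {call.phenotype}{score}")

sample = {
    "CYP2C9": "*1/*3",
    "VKORC1": "*1/*2",
    "CYP2C19": "*1/*1",
    "CYP2D6": "*10/*36",
    "CYP3A5": "*3/*3",
}
flags = actionable_flags(sample, panel)
print(f"\nsample {sample}")
print("per-drug actionability:", flags)
print("\nwarfarin flags because a reduced-function CYP2C9 allele is paired")
print("with the VKORC1 -1639 GA genotype; codeine flags because the CYP2D6")
print("class (PM-IM) falls in the poor/intermediate range.")
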