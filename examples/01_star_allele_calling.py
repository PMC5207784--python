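"""Resolve a CYP2D6 diplotype from SNP genotypes plus the two-assay copy
state, and see why copy number matters for the *10/*36 hybrid.

A sample carries two *10-*36 tandems: the SNP assays see 100C>T and
4180G>C as homozygous, which without copy-number data reads as a plain
*10/*10. The exon-9 assay (blind to the hybrid) reports 2 copies while the
intron-2 assay reports 4 — the difference is the *36 count, and the caller
resolves the duplicated tandem.
"""

from pgxpanel import Cyp2d6CopyState, load_panel
from pgxpanel.starcall import call_cyp2d6

panel = load_panel()

genotypes = panel.implied_genotypes("CYP2D6", "(*10/*36)X2")
nonref = {a: c for a, c in genotypes.items() if c != "hom_ref"}
print("observed genotypes:", nonref)

without_cn = call_cyp2d6(genotypes, None, panel)
with_cn = call_cyp2d6(genotypes, Cyp2d6CopyState(exon9_cn=2, intron2_cn=4), panel)

print(f"without copy number : {without_cn.text}")
print(f"with CN exon9=2/intron2=4: {with_cn.text}")
print()
print("The SNP-only call (*10/*10, two decreased-function copies) and the")
print("resolved call ((*10/*36)X2, two decreased + two null copies) imply")
print("the same IM phenotype here, but in general the hybrid count changes")
print("the activity score and hence the predicted metabolizer class.")
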