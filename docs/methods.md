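# Methods

## Panel model

The panel is a versioned TSV shipped with the package
(`pgxpanel/data/panel.tsv`): 32 variant assays over five genes and the
star-allele definitions built on them, each allele carrying an activity
class (increased / normal / decreased / none), a numeric per-copy
activity score, and a structural flag (`snv-defined`,
`whole-gene-deletion` for CYP2D6*5, `hybrid-exon9-conversion` for
CYP2D6*36). Assays are keyed by identifier rather than rsid because one
locus (rs5030865) is probed for two different substitutions — G>T
defining *8 and G>A defining *14 — and must stay distinguishable; it
therefore appears as two assays, `rs5030865_T` and `rs5030865_A`, which is
also how the panel reaches its count of 32.

Two modelling choices are worth stating. First, rs16947 and rs1135840
are independent assays; *2 requires both and *2A additionally requires
the −1584C>G promoter variant (rs1080985). Second, the *2A score is
1.5 per copy rather than the 1.0 of a plain normal-function allele. This
value was reverse-engineered from the cohort classification the package
reproduces (*1/*1 → EM but *1/*2A → EM-UM, *2A/*2A → UM, *2A/*10 → EM),
and it lives in the definition file, not in code, so users who prefer a
strict CPIC score of 1.0 can edit one cell.

The forward map `Panel.implied_genotypes` converts a diplotype into the
genotype vector its copies imply: a variant is hom-var when every
amplifying copy carries it, het when some do, hom-ref when none; deletion
copies contribute no states, so a hemizygote such as *4/*5 implies
hom-var at the *4 sites. This map is the generative model for the
simulator and the reference point for round-trip tests.

## Copy-number calling (ddCt)

Inputs are replicate Ct values (quadruplicate by default) for the target
region and the RNaseP reference, per sample and per region. Replicates
are aggregated by arithmetic mean (an optional outlier trim — drop the
max-deviation replicate when the range exceeds 0.5 cycles — is off by
default). Copy number is `CN_cal × 2^(−ddCt)` against a calibrator of
known CN (default 2), rounded half-away-from-zero; confidence is
`1 − 2·|estimate − integer|`, mapping the worst case (exactly between
integers) to 0 and a perfect integer to 1. Calls below a configurable
confidence floor (default 0.5) are flagged, never dropped. Absent
amplification is encoded by the `no-Cq` literal; a replicate set with at
least half no-Cq target wells is called CN 0 (ddCt → +∞). Samples whose
integer exon-9 CN exceeds their intron-2 CN are flagged
`cn-inconsistent` — exon-9 copies are a subset of intron-2 copies, so the
configuration is physically impossible and indicates an assay problem.

Amplification-curve processing (thresholding, baselining) is upstream of
this package: inputs are Ct values, not fluorescence curves.

## Genotype calling from endpoint fluorescence

Each assay's plate forms up to three clusters in the two normalized dye
channels. The caller works on the polar angle θ = atan2(y, x): a 1-D
k-means seeded at 0°/45°/90° (hom-ref / het / hom-var), with empty
clusters retaining their seed so monomorphic assays resolve correctly.
Points whose radius falls below a floor — twice the median no-template-
control radius, or an absolute default of 0.1 when no NTCs are present —
are left undetermined. A silhouette-like separation score and per-assay
undetermined counts are reported as diagnostics, and a manual-override
table (sample, assay, forced call) mirrors the bench practice of manual
calling for assays with noisy probes. The thresholds are package
choices, exposed in `GenotypingConfig`; no numeric parameters of the
instrument's proprietary auto-caller are published, and reproducing it
exactly is a non-goal. Pipelines holding genotype TSVs can skip this
stage entirely.

## Star-allele resolution

For the non-CNV genes the caller matches the genotype vector exactly
against all unordered allele pairs; a unique match is the call and
anything else is UND — no fuzzy matching, mirroring the policy that
unmatched SNP combinations stay undetermined. Undetermined genotypes act
as wildcards, which naturally produces UND whenever the missing call
could change the answer. A double heterozygote such as CYP2C19
rs4244285 + rs12248560 is phased trans (*2/*17) because a cis
arrangement matches no defined allele; such calls carry a
`phase-assumed` flag.

CYP2D6 enumerates multisets of allele copies subject to: non-*36 copies
= exon-9 CN; total amplifying copies = intron-2 CN (the difference is the
*36 count); *5 copies only where the total leaves a haplotype slot empty
(CN 1 → one *5, CN 0 → *5/*5); and zygosity consistency as above. With a
single amplifying copy an observed het is accepted as the hemizygous
variant and flagged `hemizygous-het` — diploid-assumption genotype
callers can place hemizygotes on either side of the het/hom boundary, and
a *5/*10 subject genuinely presents as "het 100C>T at CN 1".

Among satisfying multisets the canonical representative minimizes
(1) the number of distinct star alleles, (2) the count of
reduced-function copies, (3) the rendered string. This reproduces the
reporting choice of `*1X2/*36` over the equally consistent `*1/*10-*36`,
and `*2AX2/*36` over `*2A/*10-*36`. Slot assignment follows the
notation's conventions: a single-allele multiset of k copies splits
⌊k/2⌋/⌈k/2⌉ (`*1/*1X2`); two alleles split into homogeneous slots
(`*10X2/*36X3`), except that a symmetric pair containing the hybrid
renders as a duplicated tandem (`(*10/*36)X2`) — *36 arises by 2D7 gene
conversion within tandem arrangements, so the tandem reading is the
biologically expected one when copy numbers permit it; three or more
distinct alleles fall back to an explicit chain (`*1/*10-*36`).
Multiplicities above three render as the literal `XN` (an unresolved
high copy count); where a number is needed downstream, N is instantiated
as 4. Without copy-number data the caller drops to a two-copy model with
*36 and *5 removed from the candidate set — neither is detectable from
SNPs alone — and marks results `mode=no_cn`.

## Phenotype translation

CYP2D6: total activity score over all copies, mapped
{0 → PM, 0.5 → PM-IM, 1.0 → IM, 1.5 → IM-EM, 2.0 → EM, 2.5 → EM-UM,
≥3.0 → UM}. CYP2C9 counts reduced-function alleles (0/1/2 → EM/IM/PM);
CYP2C19 counts loss-of-function alleles (2 → PM, 1 → IM even when paired
with *17; otherwise *17 carriers → UM, else EM — the UM label for *1/*17
follows the source classification rather than the later CPIC "rapid"
category); CYP3A5 counts *3; VKORC1 reports the genotype with no
metabolizer class. UND propagates.

One diplotype is classified inconsistently in the source cohort table:
*4X2/*36 is listed IM, but its additive score is 0 + 0 + 0 = 0, i.e. PM
(two null *4 copies and a null hybrid). The package follows the score
model, returns PM, and attaches an explicit warning; setting
`PhenotypeOptions(legacy_labels=True)` selects the tabulated IM instead.
We read the IM entry as a transcription anomaly — no activity model that
keeps *4 and *36 null can produce IM — but both behaviours are one flag
apart.

Drug actionability follows the four CPIC level-1A rules: warfarin
(CYP2C9 *2/*3 carrier with VKORC1 −1639 GA or AA, or CYP2C9 *1/*1 with
AA), clopidogrel (CYP2C19 *2/*3/*6 carrier), codeine (CYP2D6 class among
PM, PM-IM, IM — the boundary IM-EM class is excluded by default and the
set is configurable), tacrolimus (CYP3A5 *1 carrier). A drug whose input
gene is UND is reported not-evaluable. For per-gene carrier rates the
conventions are: CYP2C9 — any *2..*6; CYP2C19 — any non-*1 allele;
CYP2D6 — any departure from plain *1/*1, including pure copy-number
gains; CYP3A5 — the *1/*1 homozygote, i.e. the group for which standard
tacrolimus dosing (calibrated to the prevalent non-functional *3/*3) is
atypical.

## Population statistics

Allele frequencies divide by two chromosomes per subject; UND subjects
stay in the denominator and contribute no counted alleles (this matches
how the cohort tables report frequencies over full group sizes). For
CYP2D6, where multiplicities make "allele frequency" ambiguous, a
per-chromosome presence convention is used (each allele counted once per
haplotype slot carrying it) and the table is flagged as non-comparable to
copy-weighted conventions; no published convention we tested reproduces
the source's CYP2D6 frequency column from its own diplotype counts, so
those values are not asserted anywhere.

Hardy-Weinberg uses the plain 1-df chi-squared against p², 2pq, q²
expectations over called subjects; monomorphic variants are reported
not-applicable. Wright's Fst is the simple (Ht − Hs)/Ht with unweighted
group means — this, not the Weir-Cockerham variance-components
estimator, is what reproduces the published values. The
table-reproduction helper (`fst_table`) first rounds group frequencies
to three decimals because the published indices were computed from the
rounded frequencies (e.g. CYP2C9*2: raw frequencies give 0.025, rounded
give the published 0.026); `wright_fst` itself is exact on whatever it
is given. The cohort-level "pooled MAF" is the unweighted mean of the
three group frequencies, unfolded (values above 0.5 are reported as-is).
Reported frequencies round half-away-from-zero to three decimals.

Cohorts reconstructed from per-gene count tables are *marginal* — sample
identities do not correspond across genes — so cross-gene statistics
(the any-gene actionable rate, the two-gene warfarin rule) are computed
by per-ethnicity independence products, size-weighted across groups;
joint cohorts (simulated or assayed) are scored sample-by-sample.

## Synthetic data

The generator's defaults are the study conditions: group sizes
126/179/201, per-gene diplotype frequencies from the built-in cohort
count table (UND rows dropped and renormalized, as an unknown truth
cannot be simulated), quadruplicate Ct replicates with Gaussian noise of
sd 0.05 cycles per well and channel around the ddCt-implied means
(reference Ct nominal 25.0, calibrator dCt 0.5 — only differences enter
the ddCt), a designated calibrator at CN 2/2, CN 0 emitted as no-Cq, and
fluorescence clusters at 5°/45°/85° with angular sd 3° and radius
1.0 ± 0.05 (NTCs at radius 0.05).

What it deliberately does not emulate: linkage between genes within a
subject (genes are drawn independently, because only marginal tables are
published — joint statistics such as the any-gene actionable rate are
therefore reproduced only approximately, ~96–97% against a published
98%); plate/batch effects; amplification-curve artefacts; allelic
dropout or probe cross-reactivity beyond the Gaussian angle noise; and
real linkage disequilibrium within a gene (diplotypes are drawn whole,
so within-gene LD is exactly that of the generating table). Passing
round-trip tests therefore demonstrates the internal consistency of the
caller against its own generative model, not robustness to every failure
mode of real plates.

## Problem sizes and numerical choices

The acceptance suite runs the full pipeline on 3 × 2,000 simulated
subjects at the default noise (about 200k fluorescence wells and 50k Ct
wells), a size chosen to make 3-binomial-SE frequency comparisons
meaningful while keeping the whole suite fast; the frequency-recovery
property is pooled over five generator seeds because a single 2,000-
subject draw leaves irreducible sampling noise of its own. CYP2D6
enumeration is capped at exon-9 CN 6 (beyond the observed range; higher
states return UND with a flag) and memoised by genotype signature, which
makes cohort calling effectively linear in the number of *distinct*
signatures. Rounding of reported frequencies is half-away-from-zero;
integer CN rounding is half-away-from-zero; k-means runs at most 50
Lloyd iterations from fixed seeds, so results are order-independent and
deterministic.

## Known limitations

Only the 32 panel variants and the alleles defined on them are
considered: rare alleles sharing the panel's SNPs will be mis-assigned
to the defined allele with the same signature, and physical phasing of
duplications is notation-level only (which chromosome carries a
duplication is not resolved beyond the rendering conventions). The *5
deletion is inferred from copy number alone and is invisible at CN ≥ 2
(e.g. *1X2/*5 reads as *1/*1 with a duplication signature). The
CYP2C19 decreased-function alleles *9/*10 are folded into the
loss-of-function count for phenotype purposes; they do not occur in the
built-in cohort. VCF export is not provided — the panel is rsid-keyed
and ships no genomic coordinates, so TSVs are the exchange format.
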