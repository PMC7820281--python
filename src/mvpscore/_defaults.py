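"""Printed operating constants used across the package.

These mirror the published operating points of the MVP method: the gene
constraint cut on ExAC pLI, the rarity filters on population allele
frequency, and the rank-percentile thresholds used to call a de novo
missense variant pathogenic in each gene class.
"""

#: Genes with pLI >= this value are "constrained" (LoF intolerant).
PLI_CONSTRAINED_CUT = 0.5

#: General rarity filter: keep variants with MAF strictly below this.
MAF_THRESHOLD = 1e-4

#: Additional rarity filter applied to variants in constrained genes
#: during case/control de novo comparisons.
MAF_STRICT_THRESHOLD = 1e-6

#: Rank-percentile threshold calling a variant pathogenic in constrained genes.
THRESHOLD_CONSTRAINED = 0.70

#: Rank-percentile threshold for non-constrained genes.
THRESHOLD_NONCONSTRAINED = 0.75

#: Feature groups whose missing values are filled with 0 (protein-complex
#: membership style features); every other group is filled with -1.
COMPLEX_FILL_GROUPS = frozenset({"protein_complex"})
FILL_COMPLEX = 0.0
FILL_DEFAULT = -1.0

#: Label for genes with pLI >= cut.
CONSTRAINED = "constrained"
NONCONSTRAINED = "nonconstrained"
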