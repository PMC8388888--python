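"""COG functional-class counting for antisense targets, plus codon usage.

Counting conventions: a target with several COG letters contributes one
count per letter; a divergent/convergent pair contributes both members'
letters (two overlapping transcripts = counted twice); unclassified targets
are dropped. The codon table reports per-1000 frequencies and each codon's
share within its synonymous family — the quantity behind rare-codon
regulation arguments.
"""

from astrx import enrichment

# antisense targets: one convergent pair (both members translation class J),
# one dual-class target, one target without a COG assignment
cog_map = {"geneA": {"J"}, "geneB": {"J"}, "geneC": {"J", "C"}}
targets = [
    (("geneA", "geneB"), "asRNA_III"),
    (("geneC",), "asRNA_I"),
    (("geneX",), "asRNA_I"),
]
class_counts = enrichment.cog_class_counts(targets, cog_map)
print("asRNA-target COG counts:", dict(class_counts))

background = {"J": 40, "C": 80, "F": 40, "K": 40}
table = enrichment.cog_enrichment_table(class_counts, background)
print("\nenrichment vs background (ratio > 1 = over-represented):")
print(table[["fraction_class", "fraction_background", "ratio"]].round(3).to_string())

# codon usage over toy CDSs with proline codon CCA deliberately rare
cds = ["ATGCCGCCGCCGCCATAA", "ATGCCGCCCCCGTGGTAA"]
usage = enrichment.codon_usage(cds)
proline = usage[usage["amino_acid"] == "P"]
print("\nproline codon family:")
print(proline[["count", "per_1000", "fraction_within_aa"]].round(3).to_string())
rare = enrichment.rare_codons(usage, max_fraction=0.25)
print("rare codons (<25% of their family):", list(rare.index))
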