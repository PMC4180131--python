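"""Chromosomal distribution, gene structure and tandem pairs of the
published sugar-beet family catalogue.

Every number printed here is recomputed from the shipped 75-gene table:
class tallies, the chromosome-assignment count, the exon-structure
histogram of the two-repeat genes, and the three tandem (sister) gene
pairs found within 105 kb start-to-start.
"""

from mybfam import datasets
from mybfam.genome import (
    chromosome_distribution,
    detect_sister_pairs,
    exon_category_counts,
    family_statistics,
)

catalogue = datasets.load_catalogue()
genes = datasets.catalogue_gene_models(catalogue)

print("family classes:", catalogue["family_class"].value_counts().to_dict())
dist = chromosome_distribution(genes)
assigned = dist[dist["chromosome"] != "unanchored"]["n_genes"].sum()
print(f"chromosome-assigned: {assigned} of {len(genes)}")
print("exon histogram (two-repeat genes):",
      exon_category_counts(genes, class_filter="R2R3"))

for pair in detect_sister_pairs(genes, max_distance=105_000):
    print(f"sister pair {pair.gene_a}-{pair.gene_b} on {pair.chromosome}: "
          f"{pair.distance:,} bp apart (local tandem duplication)")

share = family_statistics(len(genes), 27_421, 1_271)
print(f"family share: {share.pct_of_proteome}% of the proteome, "
      f"{share.pct_of_tf}% of the transcription-factor complement")
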