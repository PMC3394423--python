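"""Score a bicluster's gene set for functional enrichment.

Builds a toy genome of 1,000 genes with three functional categories, a
bicluster of 50 genes deliberately loaded with members of the "ribosome"
category, and computes the hypergeometric upper-tail p-value for each
category: the probability of seeing at least that much overlap by chance.
"""

from frogbic import Bicluster, enrich_bicluster

genome_size = 1000
gene_ids = [f"G{i}" for i in range(genome_size)]

gene_sets = {
    "ribosome": {f"G{i}" for i in range(0, 80)},          # 80 genes
    "cell_cycle": {f"G{i}" for i in range(500, 560)},     # 60 genes
    "transport": {f"G{i}" for i in range(900, 1000)},     # 100 genes
}

# 50-gene bicluster: 30 ribosome genes + 20 unrelated ones
bicluster = Bicluster(tuple(range(30)) + tuple(range(200, 220)), (0, 1, 2))

table = enrich_bicluster(bicluster, gene_ids, gene_sets, genome_size)
print(table.to_string(index=False))
print()
print("The ribosome row has k=30 of its 80 genes inside the 50-gene bicluster;")
print("its tiny p-value says that overlap is essentially impossible by chance,")
print("while the untouched categories sit at p = 1. The p_bonferroni column")
print("multiplies p by the number of categories tested.")
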