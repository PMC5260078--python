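"""Hypergeometric gene-set enrichment with BH-FDR on a constructed query.

Builds a small collection in which one set ("TARGET") overlaps the query
heavily, runs the upper-tail hypergeometric test per set and reports
Benjamini-Hochberg q-values; significance is called at q < 0.25.
"""

from isap import GeneSetCollection, enrich, hypergeom_p
from isap.simulate import make_gene_sets

universe = [f"gene_{i:04d}" for i in range(300)]
query = universe[:12]

sets = make_gene_sets(universe[40:], n_sets=15, set_size=12, seed=2)
sets["TARGET"] = ("planted overlap", universe[:10])
collection = GeneSetCollection(sets=sets, universe=universe)

table = enrich(query, collection, fdr_threshold=0.25)
print("Top 5 gene sets (N universe, M set size, n query, k overlap):")
print(table.head(5).to_string(index=False))

row = table.iloc[0]
print(f"\nThe planted set attains p = {row['p']:.3g}: the chance of drawing "
      f">= {row['k']} of its {row['M']} members in a random {row['n']}-gene query "
      f"from {row['N']} genes.")
print("Direct check of the tail formula:",
      f"hypergeom_p(300, 10, 12, {row['k']}) = {hypergeom_p(300, 10, 12, int(row['k'])):.3g}")
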