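"""The three cross-tissue pathway-interaction network types.

Reuses the planted co-profiling cohort: two pathways hold the shifted genes
of the two tissues, so their (tissue, pathway) pair should dominate every
connectivity type — (1) sum of deltas above 0.6, (2) sum of all deltas with
a display cut at 3, (3) sum of all deltas at the rigorous FDR < 0.1.
"""

from isap import GeneSetCollection, build_pathway_network, compute_cross_tissue_deltas, enrich, select_tissues
from isap.experiments import (
    BACKGROUND_MARKERS,
    PLANTED_GENES_A,
    PLANTED_GENES_B,
    planted_cohort_config,
)
from isap.simulate import generate_cohort, make_gene_sets

dataset = generate_cohort(planted_cohort_config(seed=1))
tissues = select_tissues(dataset.meta)
markers = PLANTED_GENES_A + PLANTED_GENES_B + BACKGROUND_MARKERS
deltas = compute_cross_tissue_deltas(dataset, markers, tissues=tissues)

universe = list(dataset.expr.columns)
pool = [g for g in universe if g not in set(markers)]
sets = make_gene_sets(pool, n_sets=20, set_size=12, seed=1)
sets["PATH_A"] = ("planted pathway A", PLANTED_GENES_A)
sets["PATH_B"] = ("planted pathway B", PLANTED_GENES_B)
collection = GeneSetCollection(sets=sets, universe=universe)
enrichments = {t: enrich(markers, collection, fdr_threshold=0.25) for t in tissues}

for net_type in (1, 2, 3):
    table = build_pathway_network(deltas, enrichments, collection, net_type)
    top = table.iloc[0]
    print(f"type {net_type}: top edge ({top['tissue_a']}, {top['pathway_a']}) -- "
          f"({top['tissue_b']}, {top['pathway_b']}), "
          f"connectivity = {top['connectivity']:.3f} "
          f"over {top['n_marker_pairs']} marker pair(s)")

print("\nConnectivity sums |dK-S| over the marker pairs spanning the two pathways; "
      "the planted pair collects nine deltas of ~1, so it tops all three types.")
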