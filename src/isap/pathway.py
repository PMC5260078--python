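"""Cross-tissue pathway-interaction aging networks.

Nodes are (tissue, pathway) pairs where the pathway is enriched among that
tissue's aging markers; an edge between (A, P) and (B, Q) aggregates the
cross-tissue K-S deltas of all marker pairs (i in A, j in B) whose genes
belong to P and Q respectively.  Three connectivity types:

  1. sum of deltas exceeding a moderate threshold (0.6);
  2. sum of all deltas (edges conventionally *displayed* only when the sum
     exceeds 3, but every edge is retained in the output);
  3. sum of all deltas, with pathways restricted to the rigorous enrichment
     threshold q < 0.1.

A marker pair contributes to every pathway pair whose memberships it
satisfies (pathways overlap; no exclusive assignment), so connectivity is
independent of enumeration order.
"""

from __future__ import annotations

import logging

import pandas as pd

from .enrichment import DEFAULT_FDR, STRICT_FDR, GeneSetCollection

log = logging.getLogger(__name__)

TYPE1_DELTA_CUT = 0.6
TYPE2_DISPLAY_MIN_SUM = 3.0

EDGE_COLUMNS = [
    "tissue_a", "pathway_a", "tissue_b", "pathway_b", "type", "connectivity",
    "n_marker_pairs", "display",
]


def significant_pathways(enrichments: dict[str, pd.DataFrame], fdr: float) -> dict[str, list[str]]:
    """Per tissue, the pathway terms with q below the threshold."""
    out: dict[str, list[str]] = {}
    for tissue, table in enrichments.items():
        if table.empty:
            log.warning("tissue %s has no enriched pathway; contributes no nodes", tissue)
            out[tissue] = []
            continue
        out[tissue] = list(table.loc[table["q"] < fdr, "term"])
        if not out[tissue]:
            log.warning("tissue %s has no pathway at FDR < %g; contributes no nodes", tissue, fdr)
    return out


def build_pathway_network(
    deltas: pd.DataFrame,
    enrichments: dict[str, pd.DataFrame],
    collection: GeneSetCollection,
    network_type: int,
    probe_gene_map: dict[str, str] | None = None,
    type1_delta_cut: float = TYPE1_DELTA_CUT,
    display_min_sum: float = TYPE2_DISPLAY_MIN_SUM,
    fdr_default: float = DEFAULT_FDR,
    fdr_strict: float = STRICT_FDR,
) -> pd.DataFrame:
    """Pathway-interaction edges for one network type, sorted by connectivity.

    ``deltas`` must be the UNthresholded cross-tissue edge table (the
    type-specific cuts are applied here, not the 0.95 co-profiling filter).
    """
    if network_type not in (1, 2, 3):
        raise ValueError("network_type must be 1, 2 or 3")
    fdr = fdr_strict if network_type == 3 else fdr_default
    sig = significant_pathways(enrichments, fdr)
    members = {term: set(genes) for term, (_, genes) in collection.sets.items()}
    probe_gene_map = probe_gene_map or {}

    def gene_of(marker: str) -> str:
        return probe_gene_map.get(marker, marker)

    rows = []
    for (ta, tb), sub in deltas.groupby(["tissue_a", "tissue_b"], sort=True):
        genes_a = sub["marker_a"].map(gene_of)
        genes_b = sub["marker_b"].map(gene_of)
        for P in sig.get(ta, []):
            in_p = genes_a.isin(members.get(P, set()))
            for Q in sig.get(tb, []):
                mask = in_p & genes_b.isin(members.get(Q, set()))
                if not mask.any():
                    continue  # no contributing marker pair -> edge absent
                d = sub.loc[mask, "delta"]
                if network_type == 1:
                    conn = float(d[d > type1_delta_cut].sum())
                    if conn == 0:
                        continue
                else:
                    conn = float(d.sum())
                rows.append({
                    "tissue_a": ta, "pathway_a": P, "tissue_b": tb, "pathway_b": Q,
                    "type": network_type, "connectivity": conn,
                    "n_marker_pairs": int(mask.sum()),
                    "display": bool(conn > display_min_sum) if network_type == 2 else True,
                })
    out = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return out.sort_values("connectivity", ascending=False, kind="stable").reset_index(drop=True)
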