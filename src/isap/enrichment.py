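"""Hypergeometric gene-set enrichment with Benjamini-Hochberg FDR control.

The enrichment p-value for a query of n genes overlapping a term of M genes
in k members, within a universe of N genes, is the upper tail

    p(X >= k) = 1 - sum_{j=0}^{k-1} C(M,j) C(N-M,n-j) / C(N,n),

evaluated through the hypergeometric survival function.  Collections are
read from GSEA-dialect GMT files (term <TAB> description <TAB> members...).
The default significance threshold is q < 0.25; the rigorous pathway-network
mode uses q < 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_FDR = 0.25
STRICT_FDR = 0.1


@dataclass
class GeneSetCollection:
    """Term -> (name, members), restricted to a gene universe."""

    sets: dict[str, tuple[str, list[str]]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        restricted: dict[str, tuple[str, list[str]]] = {}
        for term, (name, members) in self.sets.items():
            kept = [g for g in dict.fromkeys(members) if g in uni]
            if kept:
                restricted[term] = (name, kept)
        self.sets = restricted

    @classmethod
    def from_gmt(cls, path, universe: list[str]) -> "GeneSetCollection":
        return cls(sets=read_gmt(path), universe=universe)

    def terms_of(self, gene: str) -> set[str]:
        return {t for t, (_, members) in self.sets.items() if gene in members}


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Read a GSEA-dialect GMT file: term, description, member genes (tab-separated)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT rows need term, description and >=1 gene")
        sets[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in sets.items():
            fh.write("\t".join([term, desc, *members]) + "\n")


def hypergeom_p(N: int, M: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k); k=0 gives exactly 1."""
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"need M, n in [0, N]; got N={N}, M={M}, n={n}")
    if not 0 <= k <= min(M, n):
        raise ValueError(f"need 0 <= k <= min(M, n); got k={k}, M={M}, n={n}")
    if k == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, N, M, n)))


def enrich(
    query_genes,
    collection: GeneSetCollection,
    fdr_threshold: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """One row per gene set: overlap counts, p, BH q, significance flag.

    Query genes outside the universe are dropped with a warning; an empty
    query yields an empty table.
    """
    uni = set(collection.universe)
    query = [g for g in dict.fromkeys(query_genes)]
    outside = [g for g in query if g not in uni]
    if outside:
        log.warning("dropping %d query gene(s) outside the universe", len(outside))
    query_set = {g for g in query if g in uni}

    columns = ["term", "name", "N", "M", "n", "k", "p", "q", "significant"]
    if not query_set or not collection.sets:
        return pd.DataFrame(columns=columns)

    N = len(uni)
    n = len(query_set)
    rows = []
    for term, (name, members) in collection.sets.items():
        M = len(members)
        k = len(query_set.intersection(members))
        rows.append({"term": term, "name": name, "N": N, "M": M, "n": n, "k": k,
                     "p": hypergeom_p(N, M, n, k)})
    table = pd.DataFrame(rows)
    _, qvals, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table["q"] = qvals
    table["significant"] = table["q"] < fdr_threshold
    return table.sort_values(["p", "term"], kind="stable").reset_index(drop=True)[columns]


def read_probe_gene_map(path) -> dict[str, str]:
    """Two-column TSV (probe, gene) -> dict."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))
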