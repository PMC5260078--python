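"""Aging-specific cross-tissue co-profiling network.

Samples are stratified into young (age <= 50) and old (age >= 60).  Within
each tissue, every marker profile is discretized to {-1, 0, +1} using the
tissue-wide mean +/- sd thresholds.  For every cross-tissue marker pair the
two-sample Kolmogorov-Smirnov statistic

    K-S = sup |F1 - F2|

is computed separately in the young and the old stratum; the edge weight is
the absolute difference |K-S_old - K-S_young| ("delta"), filtered at a high
threshold (0.95 by default) to keep only pairs whose cross-tissue
co-profiling changes sharply with age.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import OmicsDataset
from .enrichment import GeneSetCollection, enrich

log = logging.getLogger(__name__)

YOUNG_AGE_MAX = 50.0
OLD_AGE_MIN = 60.0
DEFAULT_DELTA_THRESHOLD = 0.95
DEFAULT_TOP_DELTA_CUT = 0.85

EDGE_COLUMNS = ["tissue_a", "marker_a", "tissue_b", "marker_b", "ks_young", "ks_old", "delta"]


@dataclass
class AgeStrata:
    """Young / old / excluded sample ID lists (disjoint, exhaustive)."""

    young: list[str]
    old: list[str]
    excluded: list[str]


def assign_strata(meta: pd.DataFrame, young_max: float = YOUNG_AGE_MAX, old_min: float = OLD_AGE_MIN) -> AgeStrata:
    age = meta["age"].astype(float)
    young = list(meta.index[age <= young_max])
    old = list(meta.index[age >= old_min])
    excluded = list(meta.index[(age > young_max) & (age < old_min)])
    return AgeStrata(young=young, old=old, excluded=excluded)


def select_tissues(
    meta: pd.DataFrame,
    min_per_group: int = 3,
    strict: bool = True,
    young_max: float = YOUNG_AGE_MAX,
    old_min: float = OLD_AGE_MIN,
) -> list[str]:
    """Tissues whose young AND old strata each exceed ``min_per_group`` samples.

    The bound is strict by default ("more than 3" = at least 4); pass
    ``strict=False`` for >=.  Raises if fewer than two tissues qualify.
    """
    strata = assign_strata(meta, young_max, old_min)
    young = meta.loc[strata.young, "tissue"].value_counts()
    old = meta.loc[strata.old, "tissue"].value_counts()
    ok = []
    for tissue in sorted(meta["tissue"].unique()):
        ny, no = int(young.get(tissue, 0)), int(old.get(tissue, 0))
        passes = (ny > min_per_group and no > min_per_group) if strict else (
            ny >= min_per_group and no >= min_per_group
        )
        if passes:
            ok.append(tissue)
    if len(ok) < 2:
        raise ValueError(
            f"only {len(ok)} tissue(s) have both young and old strata above {min_per_group}; need >= 2"
        )
    n_pairs = len(ok) * (len(ok) - 1) // 2
    log.info("%d tissues qualify -> %d tissue-tissue pairs", len(ok), n_pairs)
    return ok


def discretize(values, mean: float, sd: float) -> np.ndarray:
    """Three-level discretization: < mean-sd -> -1, > mean+sd -> +1, else 0.

    Boundary values fall in the middle band.  sd = 0 yields all zeros with a
    warning.
    """
    v = np.asarray(values, dtype=float)
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        log.warning("discretize called with sd=0; returning all-zero vector")
        return np.zeros_like(v)
    return np.where(v < mean - sd, -1.0, np.where(v > mean + sd, 1.0, 0.0))


def ks_statistic(sample_1, sample_2) -> float:
    """Two-sample K-S statistic: sup over the joint support of |ECDF1 - ECDF2|."""
    s1 = np.sort(np.asarray(sample_1, dtype=float))
    s2 = np.sort(np.asarray(sample_2, dtype=float))
    if s1.size == 0 or s2.size == 0:
        raise ValueError("both samples must be non-empty")
    support = np.union1d(s1, s2)
    cdf1 = np.searchsorted(s1, support, side="right") / s1.size
    cdf2 = np.searchsorted(s2, support, side="right") / s2.size
    return float(np.max(np.abs(cdf1 - cdf2)))


def compute_cross_tissue_deltas(
    dataset: OmicsDataset,
    markers,
    tissues: list[str] | None = None,
    young_max: float = YOUNG_AGE_MAX,
    old_min: float = OLD_AGE_MIN,
    discretized: bool = True,
) -> pd.DataFrame:
    """Unthresholded edge table over all cross-tissue marker pairs.

    One row per (tissue_a, marker_i) x (tissue_b, marker_j) with tissue_a <
    tissue_b, carrying ks_young, ks_old and delta = |ks_old - ks_young|.
    Discretization thresholds (mean +/- sd) are computed per (tissue, marker)
    over ALL of that tissue's samples, so they are stratum-independent.
    ``discretized=False`` runs the K-S on raw values (debugging mode).
    """
    markers = list(dict.fromkeys(markers))
    if tissues is None:
        tissues = select_tissues(dataset.meta, young_max=young_max, old_min=old_min)

    # per (tissue, marker): discretized young / old value vectors
    young_vals: dict[tuple[str, str], np.ndarray] = {}
    old_vals: dict[tuple[str, str], np.ndarray] = {}
    for tissue in tissues:
        sub = dataset.tissue_subset(tissue)
        strata = assign_strata(sub.meta, young_max, old_min)
        for marker in markers:
            values = sub.feature_values(marker)
            if discretized:
                disc = discretize(values.to_numpy(), float(values.mean()), float(values.std(ddof=1)))
                disc = pd.Series(disc, index=values.index)
            else:
                disc = values
            young_vals[(tissue, marker)] = disc.loc[strata.young].to_numpy()
            old_vals[(tissue, marker)] = disc.loc[strata.old].to_numpy()

    rows = []
    for ta, tb in itertools.combinations(tissues, 2):
        for mi in markers:
            for mj in markers:
                yw_a, yw_b = young_vals[(ta, mi)], young_vals[(tb, mj)]
                od_a, od_b = old_vals[(ta, mi)], old_vals[(tb, mj)]
                if min(map(len, (yw_a, yw_b, od_a, od_b))) == 0:
                    log.warning("stratum empty for (%s,%s)x(%s,%s); pair skipped", ta, mi, tb, mj)
                    continue
                ks_y = ks_statistic(yw_a, yw_b)
                ks_o = ks_statistic(od_a, od_b)
                rows.append({
                    "tissue_a": ta, "marker_a": mi, "tissue_b": tb, "marker_b": mj,
                    "ks_young": ks_y, "ks_old": ks_o, "delta": abs(ks_o - ks_y),
                })
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def build_co_profiling_network(
    dataset: OmicsDataset,
    markers,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    tissues: list[str] | None = None,
    deltas: pd.DataFrame | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Edges with delta strictly above the threshold, sorted by delta descending."""
    if deltas is None:
        deltas = compute_cross_tissue_deltas(dataset, markers, tissues=tissues, **kwargs)
    kept = deltas[deltas["delta"] > delta_threshold]
    return kept.sort_values(["delta", "tissue_a", "marker_a"], ascending=[False, True, True],
                            kind="stable").reset_index(drop=True)


def tissue_degree_summary(edges: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue degree in the co-profiling network (distinct partner tissues)."""
    partners: dict[str, set[str]] = {}
    for _, row in edges.iterrows():
        partners.setdefault(row["tissue_a"], set()).add(row["tissue_b"])
        partners.setdefault(row["tissue_b"], set()).add(row["tissue_a"])
    rows = [{"tissue": t, "degree": len(p)} for t, p in sorted(partners.items())]
    return pd.DataFrame(rows, columns=["tissue", "degree"]).sort_values(
        "degree", ascending=False, kind="stable").reset_index(drop=True)


def _marker_gene(marker: str, probe_gene_map: dict[str, str] | None) -> str | None:
    if probe_gene_map and marker in probe_gene_map:
        return probe_gene_map[marker]
    if probe_gene_map is not None and marker.startswith(("cg", "probe")):
        return None  # unmapped methylation probe
    return marker


def shared_go_terms(
    edges: pd.DataFrame,
    collection: GeneSetCollection,
    probe_gene_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per edge, the GO-style terms annotating both endpoint genes.

    Edges are returned ranked by shared-term count; unmapped endpoints give
    an empty set (logged).
    """
    rows = []
    for _, edge in edges.iterrows():
        ga = _marker_gene(edge["marker_a"], probe_gene_map)
        gb = _marker_gene(edge["marker_b"], probe_gene_map)
        if ga is None or gb is None:
            log.info("edge (%s, %s): unmapped endpoint; no shared terms",
                     edge["marker_a"], edge["marker_b"])
            shared: set[str] = set()
        else:
            shared = collection.terms_of(ga) & collection.terms_of(gb)
        rows.append({**edge, "shared_terms": sorted(shared), "n_shared": len(shared)})
    out = pd.DataFrame(rows, columns=[*edges.columns, "shared_terms", "n_shared"])
    return out.sort_values("n_shared", ascending=False, kind="stable").reset_index(drop=True)


def enrich_top_delta_genes(
    edges: pd.DataFrame,
    collection: GeneSetCollection,
    delta_cut: float = DEFAULT_TOP_DELTA_CUT,
    probe_gene_map: dict[str, str] | None = None,
    fdr_threshold: float = 0.25,
) -> pd.DataFrame:
    """Enrichment of the unique genes on edges with delta above the cut."""
    top = edges[edges["delta"] > delta_cut]
    genes = []
    for marker in pd.concat([top["marker_a"], top["marker_b"]]):
        g = _marker_gene(marker, probe_gene_map)
        if g is not None:
            genes.append(g)
    return enrich(list(dict.fromkeys(genes)), collection, fdr_threshold=fdr_threshold)
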