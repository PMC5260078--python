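"""Reusable simulation experiments exercising the pipeline end to end.

Each experiment builds its own synthetic inputs, runs the method and returns
the measured quantities.  They back the worked examples and the acceptance
checks; problem sizes are chosen so each run takes seconds on one CPU.
"""

from __future__ import annotations

import numpy as np

from .cross_tissue import build_co_profiling_network, compute_cross_tissue_deltas, select_tissues
from .data import OmicsDataset
from .enrichment import GeneSetCollection, enrich
from .pathway import build_pathway_network
from .preprocess import preprocess_dataset
from .regression import IsapHyperparams, compare_methods, fit_isap
from .simulate import SimulationConfig, generate_cohort, make_gene_sets


def _split(dataset: OmicsDataset, n_train_tissues: int):
    tissues = dataset.tissue_labels
    train_t, test_t = tissues[:n_train_tissues], tissues[n_train_tissues:]
    meta = dataset.meta
    train = list(meta.index[meta["tissue"].isin(train_t)])
    test = list(meta.index[meta["tissue"].isin(test_t)])
    return train, test


def marker_recovery_experiment(seed: int, hyper: IsapHyperparams | None = None) -> dict:
    """Fit the pipeline on one default cohort; count recovered planted markers.

    Returns the number of planted methylation/expression features present in
    the fitted marker set (out of 5 and 3).
    """
    cfg = SimulationConfig(seed=seed)
    dataset = preprocess_dataset(generate_cohort(cfg))
    train, _ = _split(dataset, n_train_tissues=cfg.n_tissues)
    hyper = hyper or IsapHyperparams(seed=seed)
    _, markers = fit_isap(dataset, hyper, train_samples=train)
    gt = generate_cohort(cfg).ground_truth
    found = set(markers.features)
    meth_true = set(gt.loc[gt["modality"] == "methylation", "feature"])
    expr_true = set(gt.loc[gt["modality"] == "expression", "feature"])
    return {
        "n_meth_recovered": len(meth_true & found),
        "n_meth_planted": len(meth_true),
        "n_expr_recovered": len(expr_true & found),
        "n_expr_planted": len(expr_true),
    }


def method_ordering_experiment(seed: int, hyper: IsapHyperparams | None = None) -> dict:
    """Held-out-tissue SSE of the integrated model vs single-modality Lasso.

    Four of the six default tissues train, two are held out; signal is
    planted in both modalities, so integrating expression should not hurt.
    """
    cfg = SimulationConfig(seed=seed)
    dataset = preprocess_dataset(generate_cohort(cfg))
    train, test = _split(dataset, n_train_tissues=4)
    return compare_methods(dataset, train, test, hyper or IsapHyperparams(seed=seed))


# -- planted cross-tissue co-profiling signal ---------------------------------

PLANTED_GENES_A = ["gene_0010", "gene_0011", "gene_0012"]
PLANTED_GENES_B = ["gene_0020", "gene_0021", "gene_0022"]
BACKGROUND_MARKERS = ["gene_0030", "gene_0031"]
PLANTED_PATHWAYS = {"PATH_A": PLANTED_GENES_A, "PATH_B": PLANTED_GENES_B}


def planted_cohort_config(seed: int, magnitude: float = 200.0) -> SimulationConfig:
    """Cohort carrying an anti-correlated old-age shift between two tissues.

    The mean +/- sd discretization bands separate the strata only while the
    old fraction of a tissue stays clearly below one half (above it, the
    shifted stratum dominates the tissue mean and the band flips onto the
    young samples), so the age range puts the old stratum at about a third
    of each tissue and tissues are large enough that sampling noise cannot
    push it near the boundary.
    """
    pairs = [(0, 1, a, b, magnitude) for a, b in zip(PLANTED_GENES_A, PLANTED_GENES_B)]
    return SimulationConfig(
        n_tissues=4,
        samples_per_tissue=100,
        age_range=(20.0, 80.0),
        old_shift_pairs=pairs,
        seed=seed,
    )


def planted_edge_experiment(seed: int, delta_threshold: float = 0.95) -> dict:
    """Recover the planted co-profiling edge and its pathway-pair signal.

    Measures: the delta of the planted (tissue, gene) pair, whether every
    planted marker pair survives the co-profiling threshold, and whether the
    planted pathway pair attains the maximal connectivity in all three
    pathway-network types.
    """
    cfg = planted_cohort_config(seed)
    dataset = generate_cohort(cfg)
    tissues = select_tissues(dataset.meta)
    markers = PLANTED_GENES_A + PLANTED_GENES_B + BACKGROUND_MARKERS
    deltas = compute_cross_tissue_deltas(dataset, markers, tissues=tissues)

    planted_mask = (
        (deltas["tissue_a"] == "tissue_00")
        & (deltas["tissue_b"] == "tissue_01")
        & deltas["marker_a"].isin(PLANTED_GENES_A)
        & deltas["marker_b"].isin(PLANTED_GENES_B)
    )
    planted_delta = float(deltas.loc[planted_mask, "delta"].min())
    edges = build_co_profiling_network(dataset, markers, delta_threshold=delta_threshold, deltas=deltas)
    edge_recovered = bool(planted_mask.sum() > 0 and planted_delta > delta_threshold)

    # pathway layer: planted pathways contain exactly the planted genes, and
    # background sets draw from the remaining genes so a random set cannot
    # coincide with the planted construct
    universe = list(dataset.expr.columns)
    background_pool = [g for g in universe if g not in set(markers)]
    sets = make_gene_sets(background_pool, n_sets=20, set_size=12, seed=seed, planted=None)
    sets["PATH_A"] = ("planted pathway A", list(PLANTED_GENES_A))
    sets["PATH_B"] = ("planted pathway B", list(PLANTED_GENES_B))
    collection = GeneSetCollection(sets=sets, universe=universe)
    enrichments = {t: enrich(markers, collection, fdr_threshold=0.25) for t in tissues}

    pathway_maximal = {}
    for net_type in (1, 2, 3):
        table = build_pathway_network(deltas, enrichments, collection, net_type)
        if table.empty:
            pathway_maximal[net_type] = False
            continue
        top = table.iloc[0]
        pathway_maximal[net_type] = bool(
            {top["pathway_a"], top["pathway_b"]} == {"PATH_A", "PATH_B"}
            and {top["tissue_a"], top["tissue_b"]} == {"tissue_00", "tissue_01"}
        )
    return {
        "planted_delta": planted_delta,
        "edge_recovered": edge_recovered,
        "n_edges": int(len(edges)),
        "pathway_maximal": pathway_maximal,
    }
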