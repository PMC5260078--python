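"""End-to-end pipeline: preprocess -> fit -> enrichment -> PPI -> cross-tissue -> pathways.

Configuration carries every file path and threshold (all defaulting to the
method's standard values) and round-trips through YAML.  Each executed stage
records its parameters and outputs in a JSON provenance manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import cross_tissue, pathway, ppi
from .data import OmicsDataset, read_matrix_tsv, read_meta_tsv
from .enrichment import GeneSetCollection, enrich, read_probe_gene_map
from .preprocess import PreprocessParams, preprocess_dataset
from .regression import IsapHyperparams, MarkerSet, evaluate, fit_isap, predict

log = logging.getLogger(__name__)

ALL_STAGES = ("preprocess", "fit", "enrich", "ppi", "xtissue", "pathnet")


@dataclass
class PipelineConfig:
    # input paths
    meth: str = ""
    expr: str = ""
    meta: str = ""
    gmt: str = ""
    string_edges: str = ""
    probe_gene_map: str = ""
    train_tissues: list[str] = field(default_factory=list)
    test_tissues: list[str] = field(default_factory=list)
    # thresholds (method defaults)
    n_pcs_removed: int = 3
    score_cutoff: int = 700
    fdr: float = 0.25
    fdr_strict: float = 0.1
    delta_threshold: float = 0.95
    top_delta_cut: float = 0.85
    type1_delta_cut: float = 0.6
    display_min_sum: float = 3.0
    young_age_max: float = 50.0
    old_age_min: float = 60.0
    min_per_group: int = 3
    strict_min_per_group: bool = True
    n_perm: int = 1000
    n_focal: int = 10
    max_genes: int = 20
    max_pls_components: int = 5
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    out_dir: str = "isap_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        # out_dir is not an analysis parameter; identical analyses must hash equal
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig, note: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {note} | config={config.digest()}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; return the provenance manifest (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "config_digest": config.digest(), "stages": []}

    dataset = OmicsDataset(
        meth=read_matrix_tsv(config.meth),
        expr=read_matrix_tsv(config.expr),
        meta=read_meta_tsv(config.meta),
    )
    markers: MarkerSet | None = None
    probe_map = read_probe_gene_map(config.probe_gene_map) if config.probe_gene_map else {}
    deltas = None
    enrichments: dict[str, pd.DataFrame] = {}
    collection = None

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        log.info("stage %s done", stage)

    try:
        if "preprocess" in config.stages:
            dataset = preprocess_dataset(dataset, PreprocessParams(n_pcs_removed=config.n_pcs_removed))
            dataset.to_dir(out / "preprocessed")
            record("preprocess", n_pcs_removed=config.n_pcs_removed,
                   n_samples=len(dataset.samples), out=str(out / "preprocessed"))

        if "fit" in config.stages:
            train_tissues = config.train_tissues or dataset.tissue_labels
            train = list(dataset.meta.index[dataset.meta["tissue"].isin(train_tissues)])
            hyper = IsapHyperparams(max_genes=config.max_genes,
                                    max_pls_components=config.max_pls_components,
                                    seed=config.seed)
            model, markers = fit_isap(dataset, hyper, train_samples=train)
            _write_table(markers.table, out / "markers.tsv", config,
                         "aging markers (weight in years per SD unit)")
            pred = predict(model, dataset.meth, dataset.expr)
            per_sample = pd.DataFrame({
                "sample": dataset.samples,
                "tissue": dataset.tissues.to_numpy(),
                "age": dataset.ages.to_numpy(),
                "predicted_age": pred,
            })
            _write_table(per_sample, out / "predictions.tsv", config, "per-sample predictions (years)")
            test_tissues = config.test_tissues
            groups = dataset.tissues.to_numpy()
            report = evaluate(pred, dataset.ages.to_numpy(), groups)
            report["type"] = ["test" if g in test_tissues else "training" for g in report["group"]]
            _write_table(report, out / "regression_report.tsv", config,
                         "per-tissue report: residual_error=sum of squared errors (years^2)")
            model_json = {
                "lambda_chosen": model.lambda_chosen,
                "train_age_mean": model.train_age_mean,
                "n_components": model.n_components,
                "meth_coefs": {k: float(v) for k, v in model.meth_coefs.items() if v != 0},
                "lasso_intercept": model.lasso_intercept,
                "selected_genes": model.selected_genes,
                "pls_coef": list(map(float, model.pls_coef)),
                "pls_intercept": model.pls_intercept,
            }
            (out / "model.json").write_text(json.dumps(model_json, indent=1))
            record("fit", n_markers=len(markers.table), lambda_chosen=model.lambda_chosen,
                   n_selected_genes=len(model.selected_genes))

        if markers is None and set(config.stages) & {"enrich", "ppi", "xtissue", "pathnet"}:
            raise RuntimeError("downstream stages need the fit stage")

        if "enrich" in config.stages or "pathnet" in config.stages or "xtissue" in config.stages:
            collection = GeneSetCollection.from_gmt(config.gmt, universe=list(dataset.expr.columns))

        if "enrich" in config.stages:
            table = enrich(markers.genes(probe_map), collection, fdr_threshold=config.fdr)
            _write_table(table, out / "enrichment.tsv", config,
                         f"hypergeometric enrichment, BH-FDR, significant at q<{config.fdr}")
            record("enrich", n_terms=len(table), n_significant=int(table["significant"].sum())
                   if not table.empty else 0)

        if "ppi" in config.stages:
            graph = ppi.load_string_edges(config.string_edges, score_cutoff=config.score_cutoff)
            subnet = ppi.marker_shortest_paths(graph, markers.genes(probe_map))
            focal = list(subnet.ranked()["gene"].head(config.n_focal))
            pvals = ppi.betweenness_permutation_test(
                graph, markers.genes(probe_map), focal, n_perm=config.n_perm,
                seed=config.seed, observed=subnet.betweenness)
            table = ppi.betweenness_table(subnet, pvals, config.n_perm)
            _write_table(table, out / "betweenness.tsv", config,
                         f"marker-pair path counts; permutation p over n_perm={config.n_perm}")
            ppi.write_string_edges(subnet.subgraph, out / "ppi_subnetwork.tsv")
            nx.write_graphml(subnet.subgraph, out / "ppi_subnetwork.graphml")
            record("ppi", n_nodes=subnet.subgraph.number_of_nodes(),
                   n_edges=subnet.subgraph.number_of_edges(),
                   n_markers_in_graph=len(subnet.markers))

        if "xtissue" in config.stages or "pathnet" in config.stages:
            tissues = cross_tissue.select_tissues(
                dataset.meta, min_per_group=config.min_per_group,
                strict=config.strict_min_per_group,
                young_max=config.young_age_max, old_min=config.old_age_min)
            deltas = cross_tissue.compute_cross_tissue_deltas(
                dataset, markers.features, tissues=tissues,
                young_max=config.young_age_max, old_min=config.old_age_min)

        if "xtissue" in config.stages:
            edges = cross_tissue.build_co_profiling_network(
                dataset, markers.features, delta_threshold=config.delta_threshold, deltas=deltas)
            _write_table(edges, out / "cross_tissue_edges.tsv", config,
                         f"co-profiling edges, |dK-S| > {config.delta_threshold}")
            _write_table(cross_tissue.tissue_degree_summary(edges), out / "tissue_degrees.tsv",
                         config, "tissue degree in the co-profiling network")
            shared = cross_tissue.shared_go_terms(edges, collection, probe_map)
            shared["shared_terms"] = shared["shared_terms"].map(",".join)
            _write_table(shared, out / "shared_terms.tsv", config, "terms shared by edge endpoints")
            top = cross_tissue.enrich_top_delta_genes(
                deltas, collection, delta_cut=config.top_delta_cut,
                probe_gene_map=probe_map, fdr_threshold=config.fdr)
            _write_table(top, out / "top_delta_enrichment.tsv", config,
                         f"enrichment of genes on |dK-S| > {config.top_delta_cut} edges")
            g = nx.Graph()
            for _, e in edges.iterrows():
                g.add_edge(f"{e['tissue_a']}|{e['marker_a']}", f"{e['tissue_b']}|{e['marker_b']}",
                           delta=float(e["delta"]))
            nx.write_graphml(g, out / "cross_tissue.graphml")
            record("xtissue", n_edges=len(edges), n_tissues=len(tissues))

        if "pathnet" in config.stages:
            enrichments = {
                t: enrich(
                    MarkerSet(markers.table).genes(probe_map), collection, fdr_threshold=config.fdr)
                for t in {*deltas["tissue_a"], *deltas["tissue_b"]}
            }
            for net_type in (1, 2, 3):
                table = pathway.build_pathway_network(
                    deltas, enrichments, collection, net_type, probe_gene_map=probe_map,
                    type1_delta_cut=config.type1_delta_cut, display_min_sum=config.display_min_sum,
                    fdr_default=config.fdr, fdr_strict=config.fdr_strict)
                _write_table(table, out / f"pathway_network_type{net_type}.tsv", config,
                             f"type-{net_type} pathway connectivity (sum of |dK-S|)")
            record("pathnet", types=[1, 2, 3])
    except Exception as err:  # halt with stage context; partial outputs retained
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
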