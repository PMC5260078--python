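# isap — integrating and stepwise age prediction with cross-tissue aging networks

`isap` predicts chronological age from **paired DNA-methylation and
gene-expression matrices** and then maps the selected aging markers onto
molecular networks.  It is aimed at epigenomics / systems-biology analysts
who have per-sample methylation and expression profiles across one or more
normal tissues and want (a) an interpretable multi-omics age regressor and
(b) the downstream network views of its markers: protein-interaction
bottlenecks, cross-tissue co-profiling changes between young and old
donors, and pathway-pair interaction maps.

## The method

**Age regression** is a two-stage integration:

1. *Methylation stage* — Lasso of train-mean-centred age `y` on the
   standardized methylation matrix `X_m`:
   `min_β  (1/2n)‖y − X_m β‖² + λ‖β‖₁`, with λ chosen by cross-validation
   (leave-one-tissue-out for multi-tissue models, 5-fold within a tissue).
   The nonzero coefficients are the methylation markers; the residuals
   `r = y − X_m β̂` carry what methylation cannot explain.
2. *Expression stage* — genes are ranked by `|corr(x_g, r)|`; a forward
   stepwise loop grows the candidate set along that ranking, compresses each
   candidate set with single-response PLS (NIPALS) and scores it by honest
   cross-validated squared error (the ranking is recomputed inside every
   training fold).  The gene count `g*` is chosen first, then the PLS
   component count `c*`; an intercept-only baseline competes, so pure-noise
   expression falls back to the methylation stage alone.

The final predictor is `ŷ = ȳ_train + X_m β̂ + T(X_e) γ̂`, and flattening the
PLS composition gives one regression weight per marker (methylation probe or
gene) — the **aging markers**, ranked by `|weight|`.

**Network analyses** of the markers:

- *Enrichment* — upper-tail hypergeometric test
  `p(X ≥ k) = 1 − Σ_{j<k} C(M,j)C(N−M,n−j)/C(N,n)` per gene set, with
  Benjamini–Hochberg FDR (default call at q < 0.25).
- *PPI bottlenecks* — on a STRING-flavour graph (edges with confidence
  score > 700), one shortest path per marker pair; a node's *betweenness* is
  the count of marker-pair paths through it, and a permutation test
  (1000 random marker sets of the same size) asks whether that count is
  marker-specific or generic hubness.
- *Cross-tissue co-profiling* — samples split into young (≤ 50 y) and old
  (≥ 60 y); marker profiles discretized per tissue at mean ± sd; for every
  cross-tissue marker pair the two-sample K-S statistic `sup|F₁ − F₂|` is
  computed per stratum, and edges keep pairs with
  `|K-S_old − K-S_young| > 0.95`.
- *Pathway interaction networks* — (tissue, pathway) nodes from per-tissue
  enrichment; edge connectivity aggregates the marker-pair K-S deltas
  between two pathways' member genes in three flavours (deltas > 0.6;
  all deltas with a display cut at 3; all deltas at the rigorous q < 0.1).

A synthetic-cohort generator plants a configurable linear age signal split
between the modalities, a rank-3 confounder (removed by the 3-PC
preprocessing) and old-age cross-tissue shifts, so every stage is testable
without external data.

## Worked example

`python examples/01_simulate_and_predict_age.py` generates a six-tissue
cohort (50 samples/tissue, ages ~30–85) with 5 planted methylation and 3
planted expression causal features, trains on four tissues and predicts the
other two:

```
Lasso penalty chosen by CV: 0.3162
Methylation markers (nonzero Lasso weights): 15
Expression genes selected by stepwise PLS:   3 (1 PLS component(s))

Top 5 aging markers by |weight| (years per SD unit):
   modality    feature    weight  rank
methylation probe_0069 -3.900408     1
methylation probe_0165  3.468535     2
methylation probe_0016  3.404740     3
methylation probe_0175  3.286688     4
methylation probe_0076 -3.043064     5

Held-out tissue report (residual_error = sum of squared errors, years^2):
    group  residual_error  correlation  median_error   n
tissue_04         841.419        0.980         2.528  50
tissue_05        2479.569        0.950         3.829  50
      all        3320.989        0.963         2.893 100

Planted causal features recovered in the marker set: 8/8
```

All 8 planted causal features are recovered, held-out predicted ages
correlate at 0.96 with truth, and the median signed error is ~3 years.
The other example scripts walk through enrichment (`02`), PPI betweenness
(`03`), the cross-tissue network (`04`), the pathway networks (`05`) and
the end-to-end pipeline with its provenance manifest (`06`).

## Command line

A thin CLI mirrors the library:
`isap simulate | preprocess | fit | enrich | ppi | xtissue | pathnet | run`
(see `isap COMMAND --help`; `isap run --config cfg.yaml` chains all stages
and writes a JSON provenance manifest).

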