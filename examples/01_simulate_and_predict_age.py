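"""Fit the two-stage age regressor on a synthetic multi-tissue cohort.

Generates a six-tissue cohort with five methylation-causal and three
expression-causal features, removes the planted rank-3 confounder with the
3-PC correction, trains on four tissues and predicts the two held-out ones.
"""

import numpy as np

from isap import IsapHyperparams, SimulationConfig, evaluate, fit_isap, generate_cohort, predict
from isap.preprocess import preprocess_dataset

cfg = SimulationConfig(seed=1)
dataset = preprocess_dataset(generate_cohort(cfg))

tissues = dataset.tissue_labels
train = list(dataset.meta.index[dataset.meta["tissue"].isin(tissues[:4])])
test = dataset.subset(dataset.meta.index[dataset.meta["tissue"].isin(tissues[4:])])

model, markers = fit_isap(dataset, IsapHyperparams(seed=1), train_samples=train)

print(f"Lasso penalty chosen by CV: {model.lambda_chosen:.4g}")
print(f"Methylation markers (nonzero Lasso weights): {(model.meth_coefs != 0).sum()}")
print(f"Expression genes selected by stepwise PLS:   {len(model.selected_genes)} "
      f"({model.n_components} PLS component(s))")
print("\nTop 5 aging markers by |weight| (years per SD unit):")
print(markers.table.head(5).to_string(index=False))

pred = predict(model, test.meth, test.expr)
report = evaluate(pred, test.ages.to_numpy(), test.tissues.to_numpy())
print("\nHeld-out tissue report (residual_error = sum of squared errors, years^2):")
print(report.round(3).to_string(index=False))

gt = generate_cohort(cfg).ground_truth
recovered = gt["feature"].isin(markers.features)
print(f"\nPlanted causal features recovered in the marker set: "
      f"{int(recovered.sum())}/{len(gt)}")
print("A correlation near 1 and a small median signed error on held-out tissues "
      "mean the planted linear age signal was captured from both modalities.")
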