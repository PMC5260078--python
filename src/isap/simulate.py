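"""Synthetic paired methylation/expression cohorts with a planted age signal.

The generator emulates the inputs of the age-prediction pipeline: a
multi-tissue cohort whose chronological age is, by construction, an exact
linear function of a small set of causal features split between the two
modalities, optionally confounded by a rank-3 batch component and carrying
planted old-age distribution shifts for the cross-tissue network stages.

Construction
------------
1. A latent uniform age ``u ~ U(age_range)`` is drawn per sample and centred
   at the range midpoint (the generator's mean-age constant).
2. Every feature starts as standard-Gaussian background noise.  Each causal
   feature f additionally receives an age-proportional component
   ``c_f * (u - mean_age)`` where the loadings ``c_f = beta_f / sum(beta^2)``
   are scaled so that the planted coefficients ``beta_f`` (magnitude
   ``*_effect_sd`` years per unit, random sign) reproduce the latent age.
3. The realised age is then *re-derived* from the features:
   ``age = mean_age + sum_f beta_f x_f + Gaussian(0, noise_sd)``.
   With ``noise_sd = 0`` and no confounder the linear model holds exactly;
   with no causal features and no noise all ages collapse to the mean-age
   constant.
4. A rank-3 confounder (shared sample scores, modality-specific loadings,
   scaled by ``batch_strength``) is added to both matrices *after* the age is
   derived, so it genuinely confounds rather than carrying signal.
5. ``old_shift_pairs`` plant cross-tissue co-profiling signal: for each entry
   ``(tissue_a, tissue_b, feature_a, feature_b, magnitude)``, feature_a is
   shifted by +magnitude in tissue_a's old samples (age >= 60) and feature_b
   by -magnitude in tissue_b's old samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import OmicsDataset

OLD_AGE_MIN = 60.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the reference condition used throughout the test
    harness: six tissues of fifty samples, 200 features per modality with
    five methylation-causal features (2.0 years/unit) and three
    expression-causal features (1.0 years/unit), 1.0 years of residual noise
    and a unit-scale rank-3 confounder.
    """

    n_tissues: int = 6
    samples_per_tissue: int = 50
    n_meth_features: int = 200
    n_expr_features: int = 200
    n_meth_causal: int = 5
    n_expr_causal: int = 3
    meth_effect_sd: float = 2.0
    expr_effect_sd: float = 1.0
    noise_sd: float = 1.0
    age_range: tuple[float, float] = (30.0, 85.0)
    batch_strength: float = 1.0
    old_shift_pairs: list[tuple[int, int, str, str, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_tissues", "samples_per_tissue", "n_meth_features", "n_expr_features"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimulationConfig.{name} must be positive")
        if not 0 <= self.n_meth_causal <= self.n_meth_features:
            raise ValueError("SimulationConfig.n_meth_causal exceeds n_meth_features")
        if not 0 <= self.n_expr_causal <= self.n_expr_features:
            raise ValueError("SimulationConfig.n_expr_causal exceeds n_expr_features")
        for name in ("meth_effect_sd", "expr_effect_sd", "noise_sd", "batch_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimulationConfig.{name} must be non-negative")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("SimulationConfig.age_range must satisfy min < max")
        for entry in self.old_shift_pairs:
            ta, tb, fa, fb, mag = entry
            if not (0 <= ta < self.n_tissues and 0 <= tb < self.n_tissues):
                raise ValueError(f"SimulationConfig.old_shift_pairs tissue index out of range: {entry}")

    @property
    def mean_age(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


def meth_feature_names(n: int) -> list[str]:
    return [f"probe_{i:04d}" for i in range(n)]


def expr_feature_names(n: int) -> list[str]:
    return [f"gene_{i:04d}" for i in range(n)]


def tissue_names(n: int) -> list[str]:
    return [f"tissue_{i:02d}" for i in range(n)]


def generate_cohort(config: SimulationConfig) -> OmicsDataset:
    """Generate one synthetic cohort. Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    tissues = tissue_names(config.n_tissues)
    n = config.n_tissues * config.samples_per_tissue
    sample_ids = [
        f"{t}_s{i:03d}" for t in tissues for i in range(config.samples_per_tissue)
    ]
    tissue_of = np.repeat(tissues, config.samples_per_tissue)

    u = rng.uniform(*config.age_range, size=n)
    s = u - config.mean_age

    meth_cols = meth_feature_names(config.n_meth_features)
    expr_cols = expr_feature_names(config.n_expr_features)
    meth = rng.standard_normal((n, config.n_meth_features))
    expr = rng.standard_normal((n, config.n_expr_features))

    meth_causal = sorted(rng.choice(config.n_meth_features, size=config.n_meth_causal, replace=False))
    expr_causal = sorted(rng.choice(config.n_expr_features, size=config.n_expr_causal, replace=False))
    beta_m = config.meth_effect_sd * rng.choice([-1.0, 1.0], size=config.n_meth_causal)
    beta_e = config.expr_effect_sd * rng.choice([-1.0, 1.0], size=config.n_expr_causal)

    total_sq = float(np.sum(beta_m**2) + np.sum(beta_e**2))
    if total_sq > 0:
        for idx, b in zip(meth_causal, beta_m):
            meth[:, idx] += (b / total_sq) * s
        for idx, b in zip(expr_causal, beta_e):
            expr[:, idx] += (b / total_sq) * s

    age = (
        config.mean_age
        + meth[:, meth_causal] @ beta_m
        + expr[:, expr_causal] @ beta_e
        + config.noise_sd * rng.standard_normal(n)
    )

    # Rank-3 confounder added after age derivation: shared per-sample scores,
    # modality-specific loadings.
    if config.batch_strength > 0:
        scores = rng.standard_normal((n, 3))
        meth += config.batch_strength * scores @ rng.standard_normal((3, config.n_meth_features)) / np.sqrt(3)
        expr += config.batch_strength * scores @ rng.standard_normal((3, config.n_expr_features)) / np.sqrt(3)

    meth_df = pd.DataFrame(meth, index=sample_ids, columns=meth_cols)
    expr_df = pd.DataFrame(expr, index=sample_ids, columns=expr_cols)

    old_mask = age >= OLD_AGE_MIN
    for ta, tb, fa, fb, mag in config.old_shift_pairs:
        mask_a = (tissue_of == tissues[ta]) & old_mask
        mask_b = (tissue_of == tissues[tb]) & old_mask
        for feat, delta, mask in ((fa, +mag, mask_a), (fb, -mag, mask_b)):
            if feat in meth_df.columns:
                target = meth_df
            elif feat in expr_df.columns:
                target = expr_df
            else:
                raise ValueError(f"old_shift_pairs names unknown feature {feat!r}")
            target.loc[mask, feat] = target.loc[mask, feat] + delta

    meta = pd.DataFrame({"tissue": tissue_of, "age": age}, index=sample_ids)

    gt_rows = [
        {"modality": "methylation", "feature": meth_cols[i], "coefficient": b}
        for i, b in zip(meth_causal, beta_m)
    ] + [
        {"modality": "expression", "feature": expr_cols[i], "coefficient": b}
        for i, b in zip(expr_causal, beta_e)
    ]
    ground_truth = pd.DataFrame(gt_rows, columns=["modality", "feature", "coefficient"])

    return OmicsDataset(meth=meth_df, expr=expr_df, meta=meta, ground_truth=ground_truth)


# -- companion synthetic resources -------------------------------------------


def make_probe_gene_map(probes: list[str], genes: list[str], seed: int = 0) -> pd.DataFrame:
    """Synthetic probe -> gene-symbol mapping table (columns: probe, gene).

    Each probe is assigned a gene symbol drawn (with replacement) from the
    supplied gene list, mimicking the many-to-one probe annotation of real
    methylation arrays.
    """
    rng = np.random.default_rng(seed)
    assigned = rng.choice(genes, size=len(probes), replace=True)
    return pd.DataFrame({"probe": probes, "gene": assigned})


def make_gene_sets(
    genes: list[str],
    n_sets: int = 20,
    set_size: int = 15,
    seed: int = 0,
    planted: dict[str, list[str]] | None = None,
) -> dict[str, tuple[str, list[str]]]:
    """Random gene-set collection in GMT shape: term -> (description, members).

    ``planted`` entries are included verbatim (padded with random genes up to
    ``set_size``), which lets tests construct coherent pathway signal.
    """
    rng = np.random.default_rng(seed)
    sets: dict[str, tuple[str, list[str]]] = {}
    planted = planted or {}
    for term, members in planted.items():
        members = list(dict.fromkeys(members))
        pool = [g for g in genes if g not in members]
        pad = max(0, set_size - len(members))
        extra = list(rng.choice(pool, size=min(pad, len(pool)), replace=False)) if pad else []
        sets[term] = (f"planted set {term}", members + extra)
    for i in range(n_sets):
        term = f"SET_{i:03d}"
        if term in sets:
            continue
        members = list(rng.choice(genes, size=min(set_size, len(genes)), replace=False))
        sets[term] = (f"random set {i}", members)
    return sets


def make_string_edges(
    n_nodes: int = 40,
    edge_prob: float = 0.15,
    seed: int = 0,
    score_range: tuple[int, int] = (400, 999),
    node_names: list[str] | None = None,
) -> pd.DataFrame:
    """Random STRING-flavour edge table (columns: protein_a, protein_b, score)."""
    rng = np.random.default_rng(seed)
    nodes = node_names if node_names is not None else [f"PROT{i:03d}" for i in range(n_nodes)]
    rows = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if rng.random() < edge_prob:
                rows.append(
                    {
                        "protein_a": nodes[i],
                        "protein_b": nodes[j],
                        "score": int(rng.integers(*score_range)),
                    }
                )
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])


def write_gene_sets_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in sets.items():
            fh.write("\t".join([term, desc, *members]) + "\n")
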