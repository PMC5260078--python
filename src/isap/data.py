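"""Paired multi-omics dataset container and its TSV dialect.

An :class:`OmicsDataset` holds a methylation matrix and an expression matrix
over the same samples, plus per-sample metadata (tissue label, age in years).
All downstream stages — preprocessing, the ISAP regressor, the cross-tissue
networks — consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

META_COLUMNS = ("tissue", "age")


@dataclass
class OmicsDataset:
    """Paired methylation/expression matrices with sample metadata.

    Parameters
    ----------
    meth : DataFrame, samples x probes
    expr : DataFrame, samples x genes (same row order as ``meth``)
    meta : DataFrame indexed by sample with ``tissue`` (str) and ``age``
        (float, years) columns.
    ground_truth : optional DataFrame of planted causal features with columns
        ``modality``, ``feature``, ``coefficient`` (years per unit).
    """

    meth: pd.DataFrame
    expr: pd.DataFrame
    meta: pd.DataFrame
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.expr.index):
            raise ValueError("meth and expr must share identical sample ordering")
        if not self.meth.index.equals(self.meta.index):
            raise ValueError("meta must be indexed by the same samples as the matrices")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise ValueError(f"meta is missing required column {col!r}")
        if self.meta["age"].isna().any() or self.meta["tissue"].isna().any():
            raise ValueError("every sample needs a tissue and an age")
        if self.meth.isna().any().any() or self.expr.isna().any().any():
            raise ValueError("matrices contain missing values; impute before constructing")
        for frame in (self.meth, self.expr, self.meta):
            frame.index.name = "sample"

    # -- convenience accessors -------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.meth.index)

    @property
    def tissues(self) -> pd.Series:
        """Sample -> tissue label."""
        return self.meta["tissue"]

    @property
    def ages(self) -> pd.Series:
        """Sample -> age in years."""
        return self.meta["age"].astype(float)

    @property
    def tissue_labels(self) -> list[str]:
        return sorted(self.meta["tissue"].unique())

    def subset(self, samples) -> "OmicsDataset":
        samples = list(samples)
        return OmicsDataset(
            meth=self.meth.loc[samples].copy(),
            expr=self.expr.loc[samples].copy(),
            meta=self.meta.loc[samples].copy(),
            ground_truth=self.ground_truth,
        )

    def tissue_subset(self, tissue: str) -> "OmicsDataset":
        return self.subset(self.meta.index[self.meta["tissue"] == tissue])

    def feature_values(self, feature: str) -> pd.Series:
        """Resolve a feature ID against both matrices (IDs must not collide)."""
        in_meth = feature in self.meth.columns
        in_expr = feature in self.expr.columns
        if in_meth and in_expr:
            raise KeyError(f"feature {feature!r} is ambiguous (present in both modalities)")
        if in_meth:
            return self.meth[feature]
        if in_expr:
            return self.expr[feature]
        raise KeyError(f"feature {feature!r} not found in either modality")

    def feature_modality(self, feature: str) -> str:
        if feature in self.meth.columns:
            return "methylation"
        if feature in self.expr.columns:
            return "expression"
        raise KeyError(feature)

    # -- TSV round-trip ----------------------------------------------------------

    def to_dir(self, path) -> None:
        """Write meth.tsv / expr.tsv / meta.tsv (+ ground_truth.tsv) to a directory."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.meth.to_csv(path / "meth.tsv", sep="\t", index_label="sample")
        self.expr.to_csv(path / "expr.tsv", sep="\t", index_label="sample")
        self.meta.to_csv(path / "meta.tsv", sep="\t", index_label="sample")
        if self.ground_truth is not None:
            self.ground_truth.to_csv(path / "ground_truth.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path) -> "OmicsDataset":
        path = Path(path)
        meth = pd.read_csv(path / "meth.tsv", sep="\t", index_col="sample")
        expr = pd.read_csv(path / "expr.tsv", sep="\t", index_col="sample")
        meta = pd.read_csv(path / "meta.tsv", sep="\t", index_col="sample")
        gt_path = path / "ground_truth.tsv"
        gt = pd.read_csv(gt_path, sep="\t") if gt_path.exists() else None
        return cls(meth=meth, expr=expr, meta=meta, ground_truth=gt)


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a samples x features TSV (first column sample ID, header row of features)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_meta_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file {path} lacks columns {missing}")
    return meta
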