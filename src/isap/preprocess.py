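"""Preprocessing: per-tissue SVD confounder removal and feature standardization.

Each tissue block, separately per modality, is column-centred, has the
projection onto its top principal components (default 3) removed, and is
then standardized to zero mean / unit sample variance per feature.  Ages are
centred at the *training* mean only, which is retained for prediction-time
re-addition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import OmicsDataset

log = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    n_pcs_removed: int = 3
    standardize: bool = True


def svd_correct(matrix, n_pcs: int = 3):
    """Remove the top-``n_pcs`` principal components from a samples x features matrix.

    Columns are centred first; the least-squares projection of each (centred)
    feature column onto the top left singular vectors is subtracted.  With
    ``n_pcs=0`` the column-centred matrix is returned unchanged in shape.
    Idempotent for fixed ``n_pcs``.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute before svd_correct")
    if n_pcs < 0:
        raise ValueError("n_pcs must be non-negative")
    n = X.shape[0]
    if n_pcs >= n:
        raise ValueError(f"n_pcs={n_pcs} must be smaller than the number of samples ({n})")
    Xc = X - X.mean(axis=0, keepdims=True)
    if n_pcs == 0:
        out = Xc
    else:
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(s > s[0] * max(Xc.shape) * np.finfo(float).eps)) if s.size else 0
        if n_pcs > rank:
            raise ValueError(f"n_pcs={n_pcs} exceeds the matrix rank ({rank})")
        Uk = U[:, :n_pcs]
        out = Xc - Uk @ (Uk.T @ Xc)
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def standardize(matrix):
    """Scale each feature column to mean 0, sample sd 1 (ddof=1).

    Constant columns are dropped with a logged warning; an all-constant
    matrix raises.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    frame = matrix if is_frame else pd.DataFrame(np.asarray(matrix, dtype=float))
    sd = frame.std(axis=0, ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index
    if len(constant) == len(frame.columns):
        raise ValueError("all features are constant; nothing to standardize")
    if len(constant):
        log.warning("dropping %d constant feature(s): %s", len(constant), list(constant)[:10])
        frame = frame.drop(columns=constant)
        sd = sd.drop(constant)
    out = (frame - frame.mean(axis=0)) / sd
    return out if is_frame else out.to_numpy()


def center_ages(train_ages, test_ages=None):
    """Centre both age vectors at the TRAIN mean; return (train, test, train_mean)."""
    train = np.asarray(train_ages, dtype=float)
    if train.size == 0:
        raise ValueError("training ages must be non-empty")
    mean = float(train.mean())
    test = None if test_ages is None else np.asarray(test_ages, dtype=float) - mean
    return train - mean, test, mean


def intersect_features(ids_a, ids_b) -> list[str]:
    """Features present on both platforms, in the order of the first list."""
    keep = set(ids_b)
    return [f for f in ids_a if f in keep]


def preprocess_dataset(dataset: OmicsDataset, params: PreprocessParams | None = None) -> OmicsDataset:
    """Apply per-tissue SVD correction then standardization to both modalities.

    Every tissue block is treated on its own samples (test tissues are thus
    corrected independently of training tissues).  Features that come out
    constant in any tissue are dropped globally so the matrices stay aligned.
    """
    params = params or PreprocessParams()
    blocks_meth, blocks_expr = [], []
    for tissue in dataset.tissue_labels:
        sub = dataset.tissue_subset(tissue)
        m = svd_correct(sub.meth, params.n_pcs_removed)
        e = svd_correct(sub.expr, params.n_pcs_removed)
        if params.standardize:
            m = standardize(m)
            e = standardize(e)
        blocks_meth.append(m)
        blocks_expr.append(e)
    meth_cols = set.intersection(*(set(b.columns) for b in blocks_meth))
    expr_cols = set.intersection(*(set(b.columns) for b in blocks_expr))
    meth_cols = [c for c in dataset.meth.columns if c in meth_cols]
    expr_cols = [c for c in dataset.expr.columns if c in expr_cols]
    meth = pd.concat([b[meth_cols] for b in blocks_meth]).loc[dataset.samples]
    expr = pd.concat([b[expr_cols] for b in blocks_expr]).loc[dataset.samples]
    return OmicsDataset(meth=meth, expr=expr, meta=dataset.meta.copy(), ground_truth=dataset.ground_truth)
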