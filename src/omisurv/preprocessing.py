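"""Generic omic preprocessing and kernel construction.

Preprocessing is deliberately simple (feature-mean imputation, variance
filter, centering, optional unit-variance scaling): it stands in for
platform-specific QC, which is outside this package's scope. Kernels follow
GBLUP practice: K = XX'/p rescaled so that mean(diag K) = 1, which puts the
variance components of omic layers with different feature counts on a common
scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import AlignmentError, Cohort, KernelMatrix, OmicMatrix

logger = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    n_imputed_cells: int
    n_dropped_features: int
    dropped_feature_ids: list


class OmicPreprocessor(BaseEstimator, TransformerMixin):
    """Impute, filter and center/scale an omic matrix, sklearn-transformer style.

    Parameters
    ----------
    impute : bool
        Replace missing cells by the feature mean.
    center : bool
        Subtract the feature mean.
    scale : bool
        Divide by the feature standard deviation (ddof=1).
    min_var : float
        Features with variance below this are dropped.
    """

    def __init__(self, impute: bool = True, center: bool = True,
                 scale: bool = False, min_var: float = 1e-8):
        self.impute = impute
        self.center = center
        self.scale = scale
        self.min_var = min_var

    def fit(self, X, y=None):
        V = np.asarray(X, dtype=float)
        if V.size == 0:
            raise ValueError("empty omic matrix")
        mean_ = np.nanmean(V, axis=0)
        if self.impute:
            V = np.where(np.isnan(V), mean_, V)
        with np.errstate(invalid="ignore"):
            var_ = np.nanvar(V, axis=0, ddof=1)
        keep = np.isfinite(var_) & (var_ >= self.min_var) & np.isfinite(mean_)
        if not keep.any():
            raise ValueError("all features dropped by the variance filter")
        self.feature_mean_ = mean_
        self.feature_var_ = var_
        self.keep_mask_ = keep
        return self

    def transform(self, X):
        V = np.asarray(X, dtype=float)
        if self.impute:
            V = np.where(np.isnan(V), self.feature_mean_, V)
        V = V[:, self.keep_mask_]
        if self.center:
            V = V - V.mean(axis=0)
        if self.scale:
            sd = V.std(axis=0, ddof=1)
            V = V / np.where(sd > 0, sd, 1.0)
        return V


def preprocess_omic(m: OmicMatrix, impute: bool = True, center: bool = True,
                    scale: bool = False, min_var: float = 1e-8):
    """Preprocess an :class:`OmicMatrix`; returns (matrix, report)."""
    pre = OmicPreprocessor(impute=impute, center=center, scale=scale, min_var=min_var)
    V = m.to_array()
    n_missing = int(np.isnan(V).sum())
    pre.fit(V)
    out = pre.transform(V)
    kept = np.asarray(m.feature_ids)[pre.keep_mask_]
    dropped = [f for f, k in zip(m.feature_ids, pre.keep_mask_) if not k]
    if dropped:
        logger.info("preprocess_omic(%s): dropped %d low-variance features", m.kind, len(dropped))
    df = pd.DataFrame(out, index=m.sample_ids, columns=kept)
    report = PreprocessReport(n_missing if impute else 0, len(dropped), dropped)
    return OmicMatrix(df, m.kind, m.feature_meta), report


def compute_kernel(m: OmicMatrix, rank_tol: float = 1e-8) -> KernelMatrix:
    """Linear (GBLUP) kernel K = XX'/p, rescaled so mean(diag K) = 1.

    The input is expected to be preprocessed (centered); the eigendecomposition
    is computed and near-null components truncated at ``rank_tol * lambda_max``.
    """
    X = m.to_array()
    n, p = X.shape
    if n < 2:
        raise ValueError("kernel requires at least 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("kernel input contains non-finite values; preprocess first")
    K = X @ X.T / p
    md = np.mean(np.diag(K))
    if md <= 0:
        raise ValueError("degenerate kernel: zero diagonal (constant features?)")
    K = K / md
    return KernelMatrix.from_matrix(K, m.sample_ids, rank_tol=rank_tol)


@dataclass
class AlignmentReport:
    n_common: int
    losses: dict  # source name -> number of samples not in the common set


def align_samples(cohort: Cohort, omics: dict[str, OmicMatrix]):
    """Restrict cohort and omic layers to their common samples, in cohort order.

    Returns ``(cohort, omics, report)``.
    """
    if not omics:
        raise ValueError("at least one omic layer is required")
    common = pd.Index(cohort.sample_ids)
    for m in omics.values():
        common = common.intersection(pd.Index(m.sample_ids))
    common = [s for s in cohort.sample_ids if s in set(common)]
    if not common:
        raise AlignmentError("no samples shared by cohort and all omic layers")
    losses = {"clinical": cohort.n - len(common)}
    for name, m in omics.items():
        losses[name] = len(m.sample_ids) - len(common)
    out_omics = {name: m.subset(common) for name, m in omics.items()}
    return cohort.subset(common), out_omics, AlignmentReport(len(common), losses)


def build_kernels(omics: dict[str, OmicMatrix], scale: bool = True,
                  min_var: float = 1e-8, rank_tol: float = 1e-8) -> dict[str, KernelMatrix]:
    """Preprocess each omic layer and build its kernel (convenience wrapper)."""
    kernels = {}
    for name, m in omics.items():
        pre, _ = preprocess_omic(m, impute=True, center=True, scale=scale, min_var=min_var)
        kernels[name] = compute_kernel(pre, rank_tol=rank_tol)
    return kernels
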