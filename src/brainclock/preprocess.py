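"""Per-cohort normalization: outlier masking, sample QC, KNN imputation,
standardization, and nuisance-covariate residualization.

Each cohort is cleaned independently (datasets arrive on different scales;
cross-cohort comparability is restored later by the clock's recalibration
lines). The pipeline order is

    flag_outliers -> drop_outlier_samples -> knn_impute -> standardize
        -> residualize_covariates

Matrices are genes x samples DataFrames on an approximately Gaussian (e.g.
log) expression scale; outlier flagging assumes that scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)

__all__ = [
    "OutlierPolicy",
    "ImputePolicy",
    "CovariateSpec",
    "flag_outliers",
    "drop_outlier_samples",
    "knn_impute",
    "standardize",
    "residualize_covariates",
    "preprocess_cohort",
    "QCReport",
]


@dataclass(frozen=True)
class OutlierPolicy:
    """sd_threshold: |z| above which an entry is masked (leave-in z, sample
    SD with ddof=1). max_outlier_fraction: per-sample flagged-gene fraction
    above which the whole sample is dropped."""

    sd_threshold: float = 4.0
    max_outlier_fraction: float = 0.05

    def __post_init__(self):
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")
        if not 0 < self.max_outlier_fraction <= 1:
            raise ValueError("max_outlier_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ImputePolicy:
    """k nearest samples (Euclidean over co-observed genes, unweighted)."""

    k: int = 10

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class CovariateSpec:
    """Ordered nuisance covariate names; chronological age is never allowed
    (the whole point is to preserve the age signature)."""

    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if "age" in self.covariates:
            raise ValueError("chronological age must not be residualized out")


@dataclass
class QCReport:
    flags_per_sample: pd.Series = field(default_factory=pd.Series)
    flags_per_gene: pd.Series = field(default_factory=pd.Series)
    dropped_samples: list = field(default_factory=list)
    dropped_genes: list = field(default_factory=list)


def flag_outliers(matrix: pd.DataFrame, policy: OutlierPolicy) -> pd.DataFrame:
    """Boolean mask of entries with per-gene leave-in |z| > threshold.

    z uses each gene's mean and SD over all its samples; zero-variance genes
    produce no flags. Requires >= 3 samples.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples to flag outliers")
    x = matrix.to_numpy(float)
    mean = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(x - mean) / sd
    z[~np.isfinite(z)] = 0.0  # zero-variance genes, pre-existing NaNs
    return pd.DataFrame(z > policy.sd_threshold, index=matrix.index, columns=matrix.columns)


def drop_outlier_samples(
    matrix: pd.DataFrame, mask: pd.DataFrame, policy: OutlierPolicy
) -> tuple[pd.DataFrame, list]:
    """Remove samples whose flagged-gene fraction exceeds the policy cap."""
    if not (mask.index.equals(matrix.index) and mask.columns.equals(matrix.columns)):
        raise ValueError("mask is not aligned with the matrix")
    frac = mask.mean(axis=0)
    dropped = list(frac.index[frac > policy.max_outlier_fraction])
    if len(dropped) == matrix.shape[1]:
        raise ValueError("all samples exceeded the outlier-fraction threshold")
    keep = [c for c in matrix.columns if c not in set(dropped)]
    return matrix[keep], dropped


def knn_impute(matrix: pd.DataFrame, policy: ImputePolicy) -> pd.DataFrame:
    """Fill missing entries with the unweighted mean of the k nearest samples
    (nan-Euclidean distance over co-observed genes; only samples observing
    the target gene serve as donors). Observed entries pass through bit-exact.
    """
    n_samples = matrix.shape[1]
    if policy.k >= n_samples:
        raise ValueError("k must be < number of samples")
    x = matrix.to_numpy(float)
    all_missing_samples = np.isnan(x).all(axis=0)
    if all_missing_samples.any():
        bad = matrix.columns[all_missing_samples].tolist()
        raise ValueError(f"samples with all entries missing: {bad}")
    observed_per_gene = (~np.isnan(x)).sum(axis=1)
    if (observed_per_gene < policy.k).any():
        bad = matrix.index[observed_per_gene < policy.k].tolist()
        raise ValueError(f"genes with fewer than k observed values: {bad[:5]}")
    if not np.isnan(x).any():
        return matrix.copy()
    imputer = KNNImputer(n_neighbors=policy.k, weights="uniform")
    filled = imputer.fit_transform(x.T).T
    return pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each gene to mean 0 and scale to SD 1 (ddof=1).

    Zero-variance genes cannot be scaled and are dropped with a warning.
    """
    x = matrix.to_numpy(float)
    if np.isnan(x).any():
        raise ValueError("standardize requires a complete matrix (impute first)")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        dropped = matrix.index[flat].tolist()
        logger.warning("dropping %d zero-variance genes: %s", len(dropped), dropped[:5])
        warnings.warn(f"dropping {len(dropped)} zero-variance genes")
    out = (x - mean) / np.where(sd == 0, 1.0, sd)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns).loc[~flat]


def _design_matrix(samples: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    cols = [pd.Series(1.0, index=samples.index, name="intercept")]
    for c in covariates:
        if c not in samples.columns:
            raise KeyError(f"covariate '{c}' not in sample table")
        v = samples[c]
        if pd.api.types.is_numeric_dtype(v):
            cols.append(v.astype(float))
        else:
            dummies = pd.get_dummies(v, prefix=c, drop_first=True, dtype=float)
            cols.extend(dummies[c] for c in dummies.columns)
    return pd.concat(cols, axis=1)


def residualize_covariates(
    matrix: pd.DataFrame, samples: pd.DataFrame, spec: CovariateSpec
) -> pd.DataFrame:
    """Replace each gene by its OLS residual on the nuisance design.

    The design is intercept + continuous covariates + indicator-coded
    categoricals; residuals are exactly orthogonal to every design column.
    A rank-deficient design raises, naming the collinear columns. With an
    empty covariate list this reduces to mean-centering.
    """
    missing = matrix.columns.difference(samples.index)
    if len(missing):
        raise ValueError(f"matrix columns missing from the sample table: {list(missing)[:5]}")
    sub = samples.reindex(matrix.columns)
    design = _design_matrix(sub, spec.covariates)
    d = design.to_numpy(float)
    rank = np.linalg.matrix_rank(d)
    if rank < d.shape[1]:
        _, r, piv = scipy.linalg.qr(d, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(d.shape) * np.finfo(float).eps
        bad = [design.columns[j] for j in piv[diag < tol]] or [design.columns[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    xt = matrix.to_numpy(float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(d, xt, rcond=None)
    resid = xt - d @ beta
    return pd.DataFrame(resid.T, index=matrix.index, columns=matrix.columns)


def preprocess_cohort(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: CovariateSpec = CovariateSpec(),
    outlier_policy: OutlierPolicy = OutlierPolicy(),
    impute_policy: ImputePolicy = ImputePolicy(),
) -> tuple[pd.DataFrame, QCReport]:
    """Run the full per-cohort cleaning pipeline; returns (matrix, QC report).

    The returned matrix is covariate-orthogonal AND unit-variance per gene:
    residuals are rescaled to SD 1 at the end (residualization shrinks each
    gene's SD by its covariate R^2; rescaling keeps the downstream penalty
    scale meaningful and makes the whole pipeline idempotent). Genes fully
    explained by covariates end up with ~zero residual variance and are
    dropped at this step.
    """
    mask = flag_outliers(matrix, outlier_policy)
    report = QCReport(
        flags_per_sample=mask.sum(axis=0), flags_per_gene=mask.sum(axis=1)
    )
    kept, dropped = drop_outlier_samples(matrix, mask, outlier_policy)
    report.dropped_samples = dropped
    masked = kept.mask(mask[kept.columns])
    complete = knn_impute(masked, impute_policy) if masked.isna().any().any() else kept
    before = set(complete.index)
    std = standardize(complete)
    resid = residualize_covariates(std, samples, covariates)
    out = standardize(resid)
    report.dropped_genes = sorted(before - set(out.index))
    return out, report
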