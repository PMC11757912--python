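"""Count normalization, empirical-Bayes batch adjustment, and PCA diagnostics.

Normalization follows the median-of-ratios recipe; the batch adjustment is a
parametric empirical-Bayes location/scale correction of a log-expression
matrix, with the condition kept as a covariate so biological signal is not
absorbed into the batch terms.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ValidationError
from .expression import (BATCH_ADJUSTED, LOG_NORMALIZED, RAW_COUNTS,
                         ExpressionMatrix)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample s: factor_s = median over usable genes g of
    count_gs / geometric_mean_g, where usable genes have a strictly positive
    geometric mean (i.e. no zero count in any sample).
    """
    if matrix.scale != RAW_COUNTS:
        raise ValidationError("size factors require raw counts")
    counts = matrix.values.to_numpy(float)
    if counts.sum() == 0:
        raise DegenerateInputError("all-zero count matrix")
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise DegenerateInputError("no gene with nonzero counts in every sample")
    log_gm = np.log(counts[usable]).mean(axis=1)
    ratios = counts[usable] / np.exp(log_gm)[:, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise DegenerateInputError("non-positive size factor")
    return pd.Series(factors, index=matrix.samples, name="size_factor")


def size_factors_per_batch(matrix: ExpressionMatrix) -> pd.Series:
    """Size factors computed within each batch separately, then combined."""
    out = pd.Series(np.nan, index=matrix.samples, dtype=float)
    for batch in sorted(matrix.batch_labels().unique()):
        cols = [s for s, b in matrix.batch_labels().items() if b == batch]
        sub = ExpressionMatrix(matrix.values[cols],
                               matrix.sample_meta.loc[cols], matrix.scale)
        out[cols] = size_factors(sub)
    return out.rename("size_factor")


def log_normalize(matrix: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """log2(count / factor + 1)."""
    if matrix.scale != RAW_COUNTS:
        raise ValidationError("log_normalize requires raw counts")
    factors = factors.reindex(matrix.samples)
    if factors.isna().any() or (factors <= 0).any():
        raise ValidationError("size factors must be positive for every sample")
    normed = np.log2(matrix.values.to_numpy(float) / factors.to_numpy()[None, :] + 1.0)
    return matrix.with_values(
        pd.DataFrame(normed, index=matrix.values.index, columns=matrix.values.columns),
        LOG_NORMALIZED)


def filter_low_expression(matrix: ExpressionMatrix, min_count: int = 10,
                          min_fraction: float = 0.25) -> ExpressionMatrix:
    """Keep genes with count >= min_count in at least min_fraction of samples."""
    if matrix.scale != RAW_COUNTS:
        raise ValidationError("low-expression filter operates on raw counts")
    frac = (matrix.values.to_numpy() >= min_count).mean(axis=1)
    keep = matrix.values.index[frac >= min_fraction]
    return matrix.subset_genes(keep)


# ---------------------------------------------------------------------------
# empirical-Bayes location/scale batch adjustment
# ---------------------------------------------------------------------------

def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2 if s2 > 0 else np.inf


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2 if s2 > 0 else np.inf


def _it_solve(z_batch, gamma_hat, delta_hat, gamma_bar, tau2, a, b,
              conv: float = 1e-4, max_iter: int = 200):
    """Iterative EB shrinkage of per-gene batch location and scale."""
    n = z_batch.shape[0]
    gamma_old = gamma_hat.copy()
    delta_old = delta_hat.copy()
    shrink_scale = np.isfinite(a) and np.isfinite(b) and a > 1
    for _ in range(max_iter):
        gamma_new = ((n * tau2 * gamma_hat + delta_old * gamma_bar)
                     / (n * tau2 + delta_old))
        if shrink_scale:
            sum2 = ((z_batch - gamma_new[None, :]) ** 2).sum(axis=0)
            delta_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        else:
            delta_new = delta_hat
        change = max(
            np.max(np.abs(gamma_new - gamma_old) / np.maximum(np.abs(gamma_old), 1e-8)),
            np.max(np.abs(delta_new - delta_old) / np.maximum(np.abs(delta_old), 1e-8)),
        )
        gamma_old, delta_old = gamma_new, delta_new
        if change < conv:
            break
    return gamma_old, np.maximum(delta_old, 1e-12)


def combat_adjust(matrix: ExpressionMatrix, covariate: str = "condition",
                  parametric_conv: float = 1e-4) -> ExpressionMatrix:
    """Parametric EB location/scale batch adjustment of a log matrix.

    Fits per-gene means with the covariate retained, standardizes, estimates
    per-gene-per-batch location and scale, shrinks both toward batch-level
    hyperpriors (normal for location, inverse-gamma for scale, method of
    moments), removes them, and restores the original scale.
    """
    if matrix.scale != LOG_NORMALIZED:
        raise ValidationError("batch adjustment expects a log_normalized matrix")
    meta = matrix.sample_meta
    batches = matrix.batch_labels()
    levels = sorted(batches.unique())
    if len(levels) == 1:
        warnings.warn("single batch: adjustment is the identity", UserWarning)
        out = matrix.copy()
        out.scale = BATCH_ADJUSTED
        return out
    sizes = batches.value_counts()
    if (sizes < 2).any():
        raise ValidationError("every batch needs at least 2 samples")
    n_cond = meta[covariate].nunique()
    for b in levels:
        if meta.loc[batches == b, covariate].nunique() < n_cond:
            warnings.warn(f"batch {b!r} lacks some {covariate} levels "
                          "(batch partially confounded with the covariate)",
                          UserWarning)

    y = matrix.values.to_numpy(float).T  # samples x genes
    n_samples, _ = y.shape
    batch_design = pd.get_dummies(batches)[levels].to_numpy(float)
    cov_design = pd.get_dummies(meta[covariate].astype(str),
                                drop_first=True).to_numpy(float)
    design = np.hstack([batch_design, cov_design]) if cov_design.size else batch_design

    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    n_b = batch_design.sum(axis=0)
    grand_mean = (n_b / n_samples) @ beta[:len(levels)]
    stand_mean = np.tile(grand_mean, (n_samples, 1))
    if cov_design.size:
        stand_mean = stand_mean + cov_design @ beta[len(levels):]
    resid = y - design @ beta
    var_pooled = np.maximum((resid ** 2).mean(axis=0), 1e-12)
    sd_pooled = np.sqrt(var_pooled)

    z = (y - stand_mean) / sd_pooled[None, :]
    z_adj = np.empty_like(z)
    for b_idx, b in enumerate(levels):
        mask = batch_design[:, b_idx].astype(bool)
        zb = z[mask]
        gamma_hat = zb.mean(axis=0)
        delta_hat = zb.var(axis=0, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = max(gamma_hat.var(ddof=1), 1e-12)
        gamma_star, delta_star = _it_solve(
            zb, gamma_hat, delta_hat, gamma_bar, tau2,
            _aprior(delta_hat), _bprior(delta_hat), conv=parametric_conv)
        z_adj[mask] = (zb - gamma_star[None, :]) / np.sqrt(delta_star)[None, :]

    adjusted = (z_adj * sd_pooled[None, :] + stand_mean).T
    return matrix.with_values(
        pd.DataFrame(adjusted, index=matrix.values.index,
                     columns=matrix.values.columns),
        BATCH_ADJUSTED)


# ---------------------------------------------------------------------------
# PCA diagnostics
# ---------------------------------------------------------------------------

def pca_variance(matrix: ExpressionMatrix) -> np.ndarray:
    """Fractions of variance along successive principal components
    (samples as observations); empty for a constant matrix."""
    if matrix.n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    x = matrix.values.to_numpy(float).T
    x = x - x.mean(axis=0)
    if np.allclose(x, 0):
        return np.array([])
    s = np.linalg.svd(x, compute_uv=False)
    var = s ** 2
    var = var[var > var.sum() * 1e-12]
    return var / var.sum()


def pc_scores(matrix: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """Per-sample scores on the first principal components."""
    x = matrix.values.to_numpy(float).T
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(scores, index=matrix.samples,
                        columns=[f"PC{i + 1}" for i in range(k)])


def batch_r_squared(scores: pd.Series, batches: pd.Series) -> float:
    """One-way ANOVA R^2 of a score vector against batch labels."""
    scores = pd.Series(scores)
    batches = pd.Series(batches).reindex(scores.index)
    grand = scores.mean()
    ss_tot = ((scores - grand) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    ss_between = sum(len(grp) * (grp.mean() - grand) ** 2
                     for _, grp in scores.groupby(batches))
    return float(ss_between / ss_tot)
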