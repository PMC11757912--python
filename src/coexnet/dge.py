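"""Differential expression: empirical-Bayes moderated t, BH adjustment,
and significance/fold-change filtering.

The moderated test shrinks per-gene pooled variances toward a common prior
whose degrees of freedom and location are estimated by method of moments on
the log sample variances, then refers the statistic to a t distribution with
augmented degrees of freedom.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .exceptions import ValidationError
from .expression import LOG_SCALES, ExpressionMatrix

UP, DOWN, NS = "up", "down", "ns"


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0^2 from sample variances.

    Method of moments on z = log(s2): under the scaled chi-square model the
    mean and variance of z involve di/trigamma functions of df/2 and d0/2;
    the excess variance of z over trigamma(df/2) pins down d0.
    Returns (d0, s0_squared); d0 = inf when the variances are underdispersed.
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValidationError("need at least two positive sample variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(((e - e_mean) ** 2).sum() / (len(e) - 1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    return float(d0), float(s0_sq)


def moderated_t(matrix: ExpressionMatrix, prior_df: float | None = None,
                groups: tuple[str, str] = ("tumor", "normal")) -> pd.DataFrame:
    """Two-group moderated t test per gene.

    log2fc is group[0] minus group[1] mean.  ``prior_df`` overrides the
    estimated d0 (0 recovers the ordinary pooled-variance t test).
    Returns a DataFrame indexed by gene with columns log2fc, t, p.
    """
    if matrix.scale not in LOG_SCALES:
        raise ValidationError("moderated t expects log-scale expression")
    cond = matrix.sample_meta["condition"]
    m1 = (cond == groups[0]).to_numpy()
    m2 = (cond == groups[1]).to_numpy()
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValidationError(f"both conditions need >= 2 samples (got {n1}/{n2})")
    df = n1 + n2 - 2
    if df <= 0:
        raise ValidationError("zero residual degrees of freedom")

    x = matrix.values.to_numpy(float)
    g1, g2 = x[:, m1], x[:, m2]
    mean1, mean2 = g1.mean(axis=1), g2.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v2 = g2.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df

    if prior_df is None:
        d0, s0_sq = squeeze_variances(s2, df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = squeeze_variances(s2, df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)

    log2fc = mean1 - mean2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0),
                     np.where(log2fc == 0, 0.0, np.inf * np.sign(log2fc)))
    df_total = df + d0
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame({"log2fc": log2fc, "t": t, "p": np.clip(p, 0.0, 1.0)},
                        index=matrix.values.index)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValidationError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def deg_table(results: pd.DataFrame, alpha: float = 0.05,
              fc_min: float = 1.0) -> pd.DataFrame:
    """Annotate a moderated-t table with padj and an up/down/ns direction."""
    if not {"log2fc", "p"}.issubset(results.columns):
        raise ValidationError("results must have log2fc and p columns")
    out = results.copy()
    out["padj"] = bh_adjust(out["p"].to_numpy())
    direction = np.full(len(out), NS, dtype=object)
    sig = out["padj"].to_numpy() < alpha
    lfc = out["log2fc"].to_numpy()
    direction[sig & (lfc >= fc_min)] = UP
    direction[sig & (lfc <= -fc_min)] = DOWN
    out["direction"] = direction
    return out


def filter_degs(results: pd.DataFrame, alpha: float = 0.05,
                fc_min: float = 1.0) -> tuple[list[str], list[str]]:
    """Gene lists passing padj < alpha with log2fc >= fc_min (up) or
    <= -fc_min (down); always disjoint."""
    table = deg_table(results, alpha=alpha, fc_min=fc_min)
    up = list(table.index[table["direction"] == UP])
    down = list(table.index[table["direction"] == DOWN])
    return up, down
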