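"""Pairwise Pearson correlation between grouped genes with significance
tests and a signed significance summary."""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .dge import bh_adjust
from .expression import ExpressionMatrix

GROUP_PAIR_ORDER = ("group_a", "group_b")


def pairwise_pearson(matrix: ExpressionMatrix, groups: dict,
                     adjust: str = "bh") -> pd.DataFrame:
    """Correlation report over all unordered pairs of grouped genes.

    ``groups`` maps gene id -> group label (e.g. hub / nonhub / focal).
    p-values come from t = r sqrt((n-2)/(1-r^2)) with n-2 df; pairs with a
    zero-variance member are flagged undefined.  ``adjust`` is 'bh' or 'none'.
    """
    if adjust not in ("bh", "none"):
        raise ValidationError("adjust must be 'bh' or 'none'")
    genes = sorted(groups)
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"grouped genes absent from matrix: {missing[:5]}")
    n = matrix.n_samples
    if n < 3:
        raise ValidationError("need at least 3 samples for correlation tests")
    x = matrix.values.loc[genes].to_numpy(float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_mat = np.corrcoef(x)

    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            defined = sd[i] > 0 and sd[j] > 0
            if defined:
                r = float(np.clip(r_mat[i, j], -1.0, 1.0))
                if abs(r) == 1.0:
                    p = 0.0
                else:
                    t = r * np.sqrt((n - 2) / (1.0 - r * r))
                    p = float(2.0 * stats.t.sf(abs(t), n - 2))
            else:
                r, p = np.nan, np.nan
            rows.append({"gene_a": genes[i], "gene_b": genes[j],
                         "group_a": groups[genes[i]], "group_b": groups[genes[j]],
                         "r": r, "p": p, "n": n, "defined": defined})
    report = pd.DataFrame(rows)
    report["padj"] = np.nan
    mask = report["defined"].to_numpy()
    if mask.any() and adjust == "bh":
        report.loc[mask, "padj"] = bh_adjust(report.loc[mask, "p"].to_numpy())
    elif mask.any():
        report.loc[mask, "padj"] = report.loc[mask, "p"]
    return report


def sign_summary(report: pd.DataFrame, alpha: float = 0.05,
                 use_adjusted: bool = True) -> pd.DataFrame:
    """Counts of positive-significant / negative-significant / ns pairs per
    unordered group pair; undefined pairs count as ns.  Counts partition the
    report."""
    pcol = "padj" if use_adjusted else "p"
    buckets: dict[tuple, dict] = {}
    for row in report.itertuples(index=False):
        key = tuple(sorted((row.group_a, row.group_b)))
        b = buckets.setdefault(key, {"positive_significant": 0,
                                     "negative_significant": 0, "ns": 0})
        p = getattr(row, pcol)
        if row.defined and np.isfinite(p) and p < alpha:
            if row.r > 0:
                b["positive_significant"] += 1
            elif row.r < 0:
                b["negative_significant"] += 1
            else:
                b["ns"] += 1
        else:
            b["ns"] += 1
    rows = [{"group_a": k[0], "group_b": k[1], **v}
            for k, v in sorted(buckets.items())]
    return pd.DataFrame(rows, columns=["group_a", "group_b",
                                       "positive_significant",
                                       "negative_significant", "ns"])
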