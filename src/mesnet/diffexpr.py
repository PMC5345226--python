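"""Differential expression between the two cohorts.

Genes are ranked by a per-gene Welch (unequal-variance) two-sample t
test on log-scale normalized values, with the effect size reported as
the difference of cohort means (a log2 fold change on log2 data), and
Benjamini-Hochberg adjustment over all genes.  The selection rule is
the published one: |log2FC| >= 1 (inclusive) and FDR q <= 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .errors import ValidationError

__all__ = ["differential_expression", "filter_deg", "bh_adjust"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(low: ExpressionMatrix, high: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene Welch t-test between cohorts; returns gene/log2fc/p/q table.

    Requires identical gene axes and at least 3 samples per cohort.  A
    gene with zero variance in both cohorts and equal means gets p = 1.
    """
    if list(low.gene_ids) != list(high.gene_ids):
        raise ValidationError("cohort matrices must share an identical gene axis")
    if low.n_samples < 3 or high.n_samples < 3:
        raise ValidationError("need at least 3 samples per cohort")
    mean_low = low.values.mean(axis=1)
    mean_high = high.values.mean(axis=1)
    log2fc = mean_high - mean_low
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(high.values, low.values, axis=1, equal_var=False)
    zero_var = (low.values.var(axis=1) == 0) & (high.values.var(axis=1) == 0)
    equal = zero_var & (np.abs(log2fc) < 1e-300)
    p = np.where(equal, 1.0, p)
    p = np.where(zero_var & ~equal, 0.0, p)  # deterministic difference
    t = np.where(equal, 0.0, t)
    return pd.DataFrame({
        "gene_id": low.gene_ids,
        "log2fc": log2fc,
        "t_stat": t,
        "p": p,
        "q": bh_adjust(p),
    })


def filter_deg(table: pd.DataFrame, lfc_threshold: float = 1.0,
               deg_fdr: float = 0.05) -> list:
    """Genes with |log2fc| >= lfc_threshold and q <= deg_fdr, ascending q."""
    if lfc_threshold <= 0 or deg_fdr <= 0:
        raise ValidationError("thresholds must be positive")
    if table.empty:
        return []
    keep = table[(table["log2fc"].abs() >= lfc_threshold) & (table["q"] <= deg_fdr)]
    keep = keep.sort_values(["q", "gene_id"], kind="mergesort")
    return list(keep["gene_id"])
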