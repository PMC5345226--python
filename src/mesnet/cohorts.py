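"""Metagene scoring and quartile-tail cohort selection.

A sample's metagene score is the unweighted mean of its normalized
expression over a fixed gene signature.  Cohorts are the two tails of
the score distribution: the ``ceil(fraction * N)`` lowest-scoring
samples form the low cohort and the same number of highest-scoring
samples the high cohort, everything else excluded.  Ties at a boundary
are broken by sample id so membership never depends on input order.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = ["metagene_score", "select_cohorts", "LOW_MS", "HIGH_MS", "EXCLUDED"]

LOW_MS = "LOW_MS"
HIGH_MS = "HIGH_MS"
EXCLUDED = "EXCLUDED"


def metagene_score(expr: ExpressionMatrix, signature) -> pd.Series:
    """Mean expression of the signature genes, one score per sample.

    Signature genes absent from the matrix are logged and skipped; if
    none are present this is an error listing the missing ids.
    """
    signature = list(dict.fromkeys(signature))
    present = [g for g in signature if g in set(expr.gene_ids)]
    missing = [g for g in signature if g not in set(expr.gene_ids)]
    if not present:
        raise ValidationError(f"no signature genes present in matrix; missing: {missing}")
    if missing:
        log.info("metagene_score: %d/%d signature genes absent, skipped: %s",
                 len(missing), len(signature), missing[:10])
    sub = expr.subset_genes(present)
    scores = pd.Series(sub.values.mean(axis=0), index=expr.sample_ids, name="metagene_score")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("non-finite metagene score")
    return scores


def select_cohorts(scores: pd.Series, fraction: float = 0.25) -> pd.Series:
    """Assign LOW_MS / HIGH_MS / EXCLUDED labels from metagene scores.

    k = ceil(fraction * N) samples go to each tail.  Samples are ordered
    by (score, sample_id); the first k become LOW_MS and the last k
    HIGH_MS, so ties are resolved lexicographically and deterministically.
    """
    if not (0 < fraction <= 0.5):
        raise ValidationError("fraction must be in (0, 0.5]")
    n = len(scores)
    k = math.ceil(fraction * n)
    if 2 * k > n:
        raise ValidationError(f"cohort size {k} infeasible for {n} samples (need N >= 2/fraction)")
    order = sorted(scores.index, key=lambda s: (scores[s], s))
    labels = pd.Series(EXCLUDED, index=scores.index, name="cohort")
    labels[order[:k]] = LOW_MS
    labels[order[-k:]] = HIGH_MS
    return labels
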