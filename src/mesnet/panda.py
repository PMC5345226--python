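"""Message-passing inference of TF->gene regulatory networks.

The network is seeded by a sequence-motif prior (TF x gene) and refined
by passing messages between three evidence layers: TF-TF cooperativity
(PPI), the evolving network itself, and gene-gene co-expression.  Each
round computes a *responsibility* R = T(P, W) — how well a TF's
interaction partners agree on a target — and an *availability*
A = T(W, C) — how well a gene's co-expression neighborhood agrees with
its regulators — where T is a continuous Tanimoto similarity.  The
network moves toward their average at learning rate ``alpha``, and the
PPI and co-expression layers are in turn pulled toward the network's
row/column self-similarity with a diagonal stabilization term.
Iteration stops when the mean absolute change of W drops below ``tol``.

Edge weights are z-score-like: positive values measure confidence that
an edge exists, negative values confidence that it does not.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import ExpressionMatrix, MotifPrior, PPIMatrix, RegulatoryNetwork
from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = ["normalize_network", "tanimoto", "panda_infer"]


def normalize_network(m: np.ndarray) -> np.ndarray:
    """Z-score a matrix jointly by rows and columns.

    ``out_ij = (rowz_ij + colz_ij) / 2`` where rowz uses the mean/sd of
    row i and colz of column j.  Any row or column with zero sd falls
    back to the z-score against the whole matrix; an entirely constant
    matrix normalizes to zeros with a warning.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("normalize_network needs a matrix with >= 2 rows and columns")
    overall_sd = m.std()
    if overall_sd == 0:
        log.warning("normalize_network: constant matrix, returning zeros")
        return np.zeros_like(m)
    overall_z = (m - m.mean()) / overall_sd

    row_mean = m.mean(axis=1, keepdims=True)
    row_sd = m.std(axis=1, keepdims=True)
    col_mean = m.mean(axis=0, keepdims=True)
    col_sd = m.std(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rowz = (m - row_mean) / row_sd
        colz = (m - col_mean) / col_sd
    rowz = np.where(np.broadcast_to(row_sd == 0, m.shape), overall_z, rowz)
    colz = np.where(np.broadcast_to(col_sd == 0, m.shape), overall_z, colz)
    return 0.5 * rowz + 0.5 * colz


def tanimoto(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Continuous Tanimoto similarity of the rows of x against the columns of y.

    ``T_ij = (x_i . y_j) / sqrt(||x_i||^2 + ||y_j||^2 - |x_i . y_j|)``;
    a pair with zero denominator (both vectors zero) gets T = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[1] != y.shape[0]:
        raise ValidationError(f"inner dimensions disagree: {x.shape} vs {y.shape}")
    dot = x @ y
    xn = np.sum(x * x, axis=1)[:, None]
    yn = np.sum(y * y, axis=0)[None, :]
    denom = xn + yn - np.abs(dot)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = dot / np.sqrt(denom)
    return np.where(denom <= 0, 0.0, out)


def _stabilized(sim: np.ndarray, alpha: float, step: int) -> np.ndarray:
    """Replace the diagonal of a self-similarity matrix by a growing scale term.

    diag_i = sd(off-diagonal of row i) * dim * exp(2 * alpha * step);
    keeps the self-edge from dominating while letting the layer's scale
    track the network's growth across iterations.
    """
    n = sim.shape[0]
    out = sim.copy()
    if n > 1:
        off = sim[~np.eye(n, dtype=bool)].reshape(n, n - 1)
        np.fill_diagonal(out, off.std(axis=1) * n * np.exp(2 * alpha * step))
    return out


def panda_infer(
    expr: ExpressionMatrix,
    motif: MotifPrior,
    ppi: PPIMatrix | None = None,
    alpha: float = 0.1,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> RegulatoryNetwork:
    """Infer one condition's regulatory network by message passing.

    The co-expression layer is the Pearson correlation of the motif
    prior's genes across the condition's samples; genes in the
    expression matrix but absent from the motif prior are dropped from
    the network's gene axis (logged).  ``ppi=None`` uses the identity
    (no cooperativity information).  Deterministic: same inputs give a
    bitwise-identical network.  With ``max_iter=0`` the normalized motif
    prior is returned unchanged.  Non-convergence within ``max_iter``
    returns the last iterate with ``converged=False`` and a warning.
    """
    if not (0 < alpha <= 1):
        raise ValidationError("alpha must be in (0, 1]")
    if ppi is None:
        ppi = PPIMatrix.identity(motif.tf_ids)
    if not set(motif.tf_ids) <= set(ppi.tf_ids):
        raise ValidationError("motif TFs must be a subset of PPI TFs")
    if not set(motif.gene_ids) <= set(expr.gene_ids):
        missing = sorted(set(motif.gene_ids) - set(expr.gene_ids))
        raise ValidationError(f"motif genes absent from expression: {missing[:10]}")
    n_dropped = len(set(expr.gene_ids) - set(motif.gene_ids))
    if n_dropped:
        log.info("panda_infer: %d expression genes outside the motif prior dropped", n_dropped)

    sub = expr.subset_genes(motif.gene_ids)
    # align PPI to the motif TF order
    order = [ppi.tf_ids.index(t) for t in motif.tf_ids]
    P0 = ppi.weights[np.ix_(order, order)]
    C0 = np.corrcoef(sub.values)
    C0 = np.nan_to_num(C0, nan=0.0)  # constant gene rows have undefined correlation
    np.fill_diagonal(C0, 1.0)

    W = normalize_network(motif.weights)
    if max_iter == 0:
        return RegulatoryNetwork(list(motif.tf_ids), list(motif.gene_ids), W,
                                 converged=True, n_iter=0)
    P = normalize_network(P0)
    C = normalize_network(C0)

    converged = False
    step = 0
    for step in range(1, max_iter + 1):
        R = tanimoto(P, W)        # responsibility: PPI vs network
        A = tanimoto(W, C)        # availability: network vs co-expression
        W_new = (1 - alpha) * W + alpha * 0.5 * (R + A)
        delta = float(np.mean(np.abs(W_new - W)))
        W = W_new
        # pull the evidence layers toward the network's self-similarity
        P = (1 - alpha) * P + alpha * _stabilized(tanimoto(W, W.T), alpha, step)
        C = (1 - alpha) * C + alpha * _stabilized(tanimoto(W.T, W), alpha, step)
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("panda_infer: no convergence after %d iterations (last delta %.3g)",
                    max_iter, delta)
    return RegulatoryNetwork(list(motif.tf_ids), list(motif.gene_ids), W,
                             converged=converged, n_iter=step)
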