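"""Differential comparison of condition-specific regulatory networks.

Each condition gets a leave-one-out jackknife ensemble of networks
(one replicate per left-out sample).  Edges are compared between
conditions by Welch t-tests across replicate weights with BH adjustment
over all TF x gene edges, filtered at the published operating point
(|delta weight| >= 1 and -log10 FDR > 25), and partitioned into
phenotype-unique and shared subnetworks.  Gene-level rewiring is scored
by differential *indegree* — the summed positive weight of a gene's
retained incoming edges — tested across replicates.  A permutation of
gene labels provides the empirical null for the whole procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .containers import ExpressionMatrix, MotifPrior, PPIMatrix, RegulatoryNetwork
from .diffexpr import bh_adjust
from .errors import ValidationError
from .panda import panda_infer

log = logging.getLogger(__name__)

__all__ = [
    "NetworkEnsemble",
    "FilteredNetworkPair",
    "jackknife_ensemble",
    "aggregate",
    "edge_tests",
    "filter_edges",
    "permute_gene_labels",
    "differential_indegree",
    "run_differential_network",
]

_TINY_FDR = 1e-300  # floor before -log10 so exact zeros stay finite


@dataclass
class NetworkEnsemble:
    """Jackknife replicates of one condition's network, sharing axes."""

    networks: list
    labels: list  # left-out sample id per replicate

    def __post_init__(self):
        if not self.networks:
            raise ValidationError("ensemble must contain at least one replicate")
        ref = self.networks[0]
        for net in self.networks:
            if net.tf_ids != ref.tf_ids or net.gene_ids != ref.gene_ids:
                raise ValidationError("ensemble replicates must share tf/gene axes")
        if len(self.labels) != len(self.networks):
            raise ValidationError("one label per replicate required")

    @property
    def tf_ids(self):
        return self.networks[0].tf_ids

    @property
    def gene_ids(self):
        return self.networks[0].gene_ids

    def stack(self) -> np.ndarray:
        """(replicates, TFs, genes) weight array."""
        return np.stack([net.W for net in self.networks])


@dataclass
class FilteredNetworkPair:
    """Disjoint partition of the retained differential edges.

    A retained edge "exists" in a condition when its aggregated weight
    exceeds ``existence_tau``.  Edges below the existence threshold in
    both conditions (differences in the confidence of *absence*) are
    excluded from the partition but kept in ``absent`` for inspection;
    the three sets partition the retained set exactly.
    """

    unique_low: pd.DataFrame
    unique_high: pd.DataFrame
    shared: pd.DataFrame
    absent: pd.DataFrame | None = None
    existence_tau: float = 0.0
    counts: dict = field(default_factory=dict)

    def __post_init__(self):
        keys = [set(map(tuple, df[["tf", "gene"]].to_numpy()))
                for df in (self.unique_low, self.unique_high, self.shared)]
        if (keys[0] & keys[1]) or (keys[0] & keys[2]) or (keys[1] & keys[2]):
            raise ValidationError("unique/shared edge sets must be disjoint")
        self.counts = {
            "unique_low": len(self.unique_low),
            "unique_high": len(self.unique_high),
            "shared": len(self.shared),
        }

    @property
    def retained(self) -> pd.DataFrame:
        return pd.concat([self.unique_low, self.unique_high, self.shared],
                         ignore_index=True)

    @property
    def n_retained(self) -> int:
        return sum(self.counts.values())


def jackknife_ensemble(expr: ExpressionMatrix, motif: MotifPrior,
                       ppi: PPIMatrix | None, config: RunConfig) -> NetworkEnsemble:
    """One network per left-out sample; deterministic given the inputs."""
    if expr.n_samples < 4:
        raise ValidationError("jackknife needs at least 4 samples")
    networks, labels = [], []
    for s in expr.sample_ids:
        net = panda_infer(expr.drop_sample(s), motif, ppi,
                          alpha=config.alpha, tol=config.tol, max_iter=config.max_iter)
        networks.append(net)
        labels.append(s)
    return NetworkEnsemble(networks, labels)


def aggregate(ens: NetworkEnsemble) -> RegulatoryNetwork:
    """Element-wise mean of the replicate weight matrices."""
    return RegulatoryNetwork(list(ens.tf_ids), list(ens.gene_ids),
                             ens.stack().mean(axis=0))


def edge_tests(ens_low: NetworkEnsemble, ens_high: NetworkEnsemble) -> pd.DataFrame:
    """Per-edge Welch t across replicate weights, BH over all edges.

    Returns one row per (tf, gene) with mean_low, mean_high,
    delta = mean_high - mean_low, t_stat, p, fdr and neglog10_fdr.
    Edges with zero variance and zero difference get t = 0, p = 1.
    """
    if ens_low.tf_ids != ens_high.tf_ids or ens_low.gene_ids != ens_high.gene_ids:
        raise ValidationError("ensembles must share tf/gene axes")
    if len(ens_low.networks) < 3 or len(ens_high.networks) < 3:
        raise ValidationError("need at least 3 replicates per condition")
    lo, hi = ens_low.stack(), ens_high.stack()
    mean_low, mean_high = lo.mean(axis=0), hi.mean(axis=0)
    delta = mean_high - mean_low
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(hi, lo, axis=0, equal_var=False)
    zero_var = (lo.var(axis=0) == 0) & (hi.var(axis=0) == 0)
    same = zero_var & (delta == 0)
    t = np.where(same, 0.0, t)
    p = np.where(same, 1.0, np.where(zero_var & (delta != 0), 0.0, p))
    fdr = bh_adjust(p.ravel()).reshape(p.shape)
    tf_col = np.repeat(ens_low.tf_ids, len(ens_low.gene_ids))
    gene_col = np.tile(ens_low.gene_ids, len(ens_low.tf_ids))
    return pd.DataFrame({
        "tf": tf_col,
        "gene": gene_col,
        "mean_low": mean_low.ravel(),
        "mean_high": mean_high.ravel(),
        "delta": delta.ravel(),
        "t_stat": t.ravel(),
        "p": p.ravel(),
        "fdr": fdr.ravel(),
        "neglog10_fdr": -np.log10(np.clip(fdr.ravel(), _TINY_FDR, None)),
    })


def filter_edges(cmp: pd.DataFrame, min_delta_w: float = 1.0,
                 min_neglog10_fdr: float = 25.0,
                 existence_tau: float = 0.0) -> FilteredNetworkPair:
    """Retain edges with |delta| >= min_delta_w and -log10 FDR strictly above
    min_neglog10_fdr, then partition them by condition-wise existence."""
    if min_delta_w <= 0 or min_neglog10_fdr <= 0:
        raise ValidationError("thresholds must be positive")
    passing = cmp[(cmp["delta"].abs() >= min_delta_w)
                  & (cmp["neglog10_fdr"] > min_neglog10_fdr)].copy()
    in_low = passing["mean_low"] > existence_tau
    in_high = passing["mean_high"] > existence_tau
    return FilteredNetworkPair(
        unique_low=passing[in_low & ~in_high].reset_index(drop=True),
        unique_high=passing[in_high & ~in_low].reset_index(drop=True),
        shared=passing[in_low & in_high].reset_index(drop=True),
        absent=passing[~in_low & ~in_high].reset_index(drop=True),
        existence_tau=existence_tau,
    )


def permute_gene_labels(expr_low: ExpressionMatrix, expr_high: ExpressionMatrix,
                        which: str = "both", seed: int = 0):
    """Uniformly permute the gene id vector of one or both matrices.

    Values are untouched — rows are only relabeled — so each sample's
    value multiset is preserved.  Deterministic under ``seed``; the two
    matrices receive independent permutations when ``which='both'``.
    """
    if which not in {"low", "high", "both"}:
        raise ValidationError("which must be 'low', 'high' or 'both'")
    rng = np.random.default_rng(seed)

    def _permute(expr):
        perm = rng.permutation(len(expr.gene_ids))
        ids = [expr.gene_ids[i] for i in perm]
        return ExpressionMatrix(ids, list(expr.sample_ids), expr.values.copy())

    out_low = _permute(expr_low) if which in {"low", "both"} else expr_low
    out_high = _permute(expr_high) if which in {"high", "both"} else expr_high
    return out_low, out_high


def differential_indegree(ens_low: NetworkEnsemble, ens_high: NetworkEnsemble,
                          filtered: FilteredNetworkPair | None,
                          indegree_p: float = 0.05) -> pd.DataFrame:
    """Per-gene rewiring test: Welch t on replicate indegrees between conditions.

    A gene's indegree in one replicate is the sum of positive weights of
    its retained incoming edges (``filtered=None`` uses all edges).
    Genes with no retained edges keep indegree 0 in both conditions and
    p = 1.  ``differential`` flags raw p <= indegree_p.
    """
    if ens_low.tf_ids != ens_high.tf_ids or ens_low.gene_ids != ens_high.gene_ids:
        raise ValidationError("ensembles must share tf/gene axes")
    tfs, genes = ens_low.tf_ids, ens_low.gene_ids
    mask = np.ones((len(tfs), len(genes)), dtype=bool)
    if filtered is not None:
        mask[:] = False
        ti = {t: i for i, t in enumerate(tfs)}
        gi = {g: i for i, g in enumerate(genes)}
        for df in (filtered.unique_low, filtered.unique_high, filtered.shared):
            for tf, gene in df[["tf", "gene"]].itertuples(index=False):
                mask[ti[tf], gi[gene]] = True

    def indegrees(stack):
        pos = np.clip(stack, 0.0, None) * mask  # (reps, TF, gene)
        return pos.sum(axis=1)                  # (reps, gene)

    deg_lo, deg_hi = indegrees(ens_low.stack()), indegrees(ens_high.stack())
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(deg_hi, deg_lo, axis=0, equal_var=False)
    delta_deg = deg_hi.mean(axis=0) - deg_lo.mean(axis=0)
    zero_var = (deg_lo.var(axis=0) == 0) & (deg_hi.var(axis=0) == 0)
    same = zero_var & (delta_deg == 0)
    t = np.where(same, 0.0, t)
    p = np.where(same, 1.0, np.where(zero_var & (delta_deg != 0), 0.0, p))
    no_edges = ~mask.any(axis=0)
    p = np.where(no_edges, 1.0, p)
    t = np.where(no_edges, 0.0, t)
    return pd.DataFrame({
        "gene_id": genes,
        "indegree_low": deg_lo.mean(axis=0),
        "indegree_high": deg_hi.mean(axis=0),
        "t_stat": t,
        "p": p,
        "differential": p <= indegree_p,
    })


def calibrate_min_delta_w(expr_low: ExpressionMatrix, expr_high: ExpressionMatrix,
                          motif: MotifPrior, ppi: PPIMatrix | None,
                          config: RunConfig, n_permutations: int = 3,
                          quantile: float = 0.99, seed: int = 0) -> float:
    """Choose the edge |delta-weight| cutoff from the permutation null.

    The weight-difference scale of a message-passing network depends on
    the problem size, so the cutoff is calibrated against the
    distribution of the data rather than fixed: gene labels of both
    matrices are permuted ``n_permutations`` times, the full jackknife
    edge comparison is rerun on each, and the cutoff is the given
    quantile of |delta| over the permuted edges that exist (aggregated
    weight above the existence threshold) in at least one condition.
    Deterministic under ``seed``.
    """
    if not (0 < quantile <= 1):
        raise ValidationError("quantile must be in (0, 1]")
    if n_permutations < 1:
        raise ValidationError("need at least one permutation")
    pooled = []
    for r in range(n_permutations):
        plo, phi = permute_gene_labels(expr_low, expr_high, "both",
                                       seed=seed * n_permutations + r)
        ens_lo = jackknife_ensemble(plo, motif, ppi, config)
        ens_hi = jackknife_ensemble(phi, motif, ppi, config)
        cmp = edge_tests(ens_lo, ens_hi)
        exists = (cmp["mean_low"] > 0) | (cmp["mean_high"] > 0)
        pooled.append(cmp.loc[exists, "delta"].abs().to_numpy())
    cutoff = float(np.quantile(np.concatenate(pooled), quantile))
    log.info("calibrated min_delta_w = %.3f (%d permutations, quantile %.3f)",
             cutoff, n_permutations, quantile)
    return cutoff


def run_differential_network(expr_low: ExpressionMatrix, expr_high: ExpressionMatrix,
                             motif: MotifPrior, ppi: PPIMatrix | None,
                             config: RunConfig, calibrate: bool = False,
                             n_permutations: int = 3,
                             calibration_quantile: float = 0.99) -> dict:
    """Full differential-network stage; returns every intermediate product.

    With ``calibrate=True`` the |delta| cutoff is taken from the
    permutation null (see :func:`calibrate_min_delta_w`) instead of
    ``config.min_delta_w``, following the source procedure of choosing
    filter thresholds from the observed weight distributions.
    """
    ens_low = jackknife_ensemble(expr_low, motif, ppi, config)
    ens_high = jackknife_ensemble(expr_high, motif, ppi, config)
    cmp = edge_tests(ens_low, ens_high)
    min_delta_w = config.min_delta_w
    if calibrate:
        min_delta_w = calibrate_min_delta_w(
            expr_low, expr_high, motif, ppi, config,
            n_permutations=n_permutations, quantile=calibration_quantile,
            seed=config.seed)
    filtered = filter_edges(cmp, min_delta_w, config.min_neglog10_fdr)
    indeg = differential_indegree(ens_low, ens_high, filtered, config.indegree_p)
    return {
        "ensemble_low": ens_low,
        "ensemble_high": ens_high,
        "aggregate_low": aggregate(ens_low),
        "aggregate_high": aggregate(ens_high),
        "edge_comparison": cmp,
        "min_delta_w": min_delta_w,
        "filtered": filtered,
        "indegree": indeg,
    }
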