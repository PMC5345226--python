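"""Synthetic study generator with known planted structure.

Emulates the statistical skeleton of a two-cohort glioma study: two
expression cohorts that differ by condition-specific TF->gene regulatory
edges and by an upward shift of a signature metagene in the high
condition, plus survival times drawn from a proportional-hazards model
with known coefficients on the signature genes, age, and tumor type.

The expression model is linear-Gaussian: per sample, each TF has a
standard-normal activity; a target gene is the effect-weighted sum of
the activities of the TFs with an edge into it in that condition, plus
Gaussian noise.  Each TF's own expression row is its activity plus
noise, so Pearson co-expression between a TF and its targets carries
the planted edge signal.  Every operation is deterministic under its
seed argument.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, MotifPrior, PPIMatrix
from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticTruth",
    "generate_truth",
    "simulate_expression",
    "simulate_survival",
    "draw_clinical_covariates",
    "write_truth",
    "read_truth",
]

# Fixed clinical effects (log-hazard units): modest age effect and a
# strong high-grade effect, the two covariates any glioma survival model
# must control for.
AGE_BETA = 0.04
TYPE_BETA = 1.5  # GBM vs LGG indicator


@dataclass
class SyntheticTruth:
    """Planted ground truth: regulatory edges, signature shift, survival model."""

    tf_ids: list
    gene_ids: list
    edge_set_low: dict   # (tf, gene) -> effect size (expression units / unit activity)
    edge_set_high: dict
    signature_genes: list
    shift: float         # log2-units upshift of signature genes in the high condition
    survival_beta: dict  # covariate name -> log-hazard coefficient
    baseline_hazard: float  # events per day
    censor_rate: float
    seed: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = set(self.tf_ids) | set(self.gene_ids)
        for edges in (self.edge_set_low, self.edge_set_high):
            for tf, gene in edges:
                if tf not in set(self.tf_ids) or gene not in set(self.gene_ids):
                    raise ValidationError(f"edge ({tf}, {gene}) references undeclared ids")
        if not set(self.signature_genes) <= ids:
            raise ValidationError("signature genes must be declared gene ids")
        if not (0 <= self.censor_rate < 1):
            raise ValidationError("censor_rate must be in [0, 1)")

    @property
    def specific_edges_low(self) -> set:
        return set(self.edge_set_low) - set(self.edge_set_high)

    @property
    def specific_edges_high(self) -> set:
        return set(self.edge_set_high) - set(self.edge_set_low)


def generate_truth(
    n_tfs: int = 10,
    n_genes: int = 50,
    n_shared_edges: int = 30,
    n_specific_edges_per_condition: int = 10,
    n_signature_genes: int = 10,
    shift: float = 2.0,
    survival_beta_scale: float = 1.0,
    fp_fraction: float = 0.2,
    effect_size: float = 1.0,
    n_program_tfs_per_condition: int = 1,
    baseline_hazard: float = 1e-3,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> tuple[SyntheticTruth, MotifPrior, PPIMatrix]:
    """Draw a random planted truth plus the motif prior and PPI that go with it.

    Condition-specific edges are organized as regulator *programs*: each
    condition owns ``n_program_tfs_per_condition`` dedicated TFs whose
    target modules (``n_specific_edges_per_condition`` genes split among
    them) are regulated only in that condition — emulating a master
    regulator switching on a coherent program, the way mesenchymal
    drivers behave.  Shared edges are scattered over the remaining TFs
    and genes.  The motif prior contains every true edge (union over
    conditions) plus a ``fp_fraction`` of false-positive motif hits; the
    PPI connects TFs that share at least one target.  Identical seeds
    give identical outputs.
    """
    for name, v in [("n_tfs", n_tfs), ("n_genes", n_genes)]:
        if v <= 0:
            raise ValidationError(f"{name} must be positive")
    n_true = n_shared_edges + 2 * n_specific_edges_per_condition
    if n_true > n_tfs * n_genes:
        raise ValidationError(
            f"requested {n_true} edges exceed capacity {n_tfs * n_genes}")
    if n_signature_genes > n_genes:
        raise ValidationError("more signature genes than genes")
    n_prog = n_program_tfs_per_condition if n_specific_edges_per_condition else 0
    if n_prog and (2 * n_prog >= n_tfs or 2 * n_specific_edges_per_condition > n_genes):
        raise ValidationError("program layout infeasible: too few TFs or genes")

    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]

    gene_perm = [gene_ids[i] for i in rng.permutation(n_genes)]
    tf_perm = [tf_ids[i] for i in rng.permutation(n_tfs)]
    n_spec = n_specific_edges_per_condition
    prog_genes_low = gene_perm[:n_spec]
    prog_genes_high = gene_perm[n_spec:2 * n_spec]
    rest_genes = gene_perm[2 * n_spec:]
    prog_tfs_low = tf_perm[:n_prog]
    prog_tfs_high = tf_perm[n_prog:2 * n_prog]
    shared_tfs = tf_perm[2 * n_prog:]

    def _program(tfs, genes):
        if not tfs:
            return []
        per = -(-len(genes) // len(tfs))  # ceil split of the module
        return [(tfs[min(i // per, len(tfs) - 1)], g) for i, g in enumerate(genes)]

    only_low = _program(prog_tfs_low, prog_genes_low)
    only_high = _program(prog_tfs_high, prog_genes_high)
    if n_shared_edges > len(shared_tfs) * len(rest_genes):
        raise ValidationError("requested shared edges exceed capacity outside the programs")
    flat = rng.choice(len(shared_tfs) * len(rest_genes), size=n_shared_edges, replace=False)
    shared = [(shared_tfs[k // len(rest_genes)], rest_genes[k % len(rest_genes)])
              for k in flat]
    edge_set_low = {e: effect_size for e in shared + only_low}
    edge_set_high = {e: effect_size for e in shared + only_high}

    signature = sorted(rng.choice(gene_ids, size=n_signature_genes, replace=False))
    beta = {g: float(s) * survival_beta_scale
            for g, s in zip(signature, rng.choice([-1.0, 1.0], size=n_signature_genes))}
    beta["age_years"] = AGE_BETA
    beta["type_GBM"] = TYPE_BETA

    # motif prior: all true edges plus false positives on non-edges
    true_union = set(edge_set_low) | set(edge_set_high)
    w = np.zeros((n_tfs, n_genes))
    ti = {t: i for i, t in enumerate(tf_ids)}
    gi = {g: i for i, g in enumerate(gene_ids)}
    for tf, g in true_union:
        w[ti[tf], gi[g]] = 1.0
    n_fp = int(round(fp_fraction * len(true_union)))
    non_edges = [k for k in range(n_tfs * n_genes)
                 if (tf_ids[k // n_genes], gene_ids[k % n_genes]) not in true_union]
    if n_fp > 0:
        for k in rng.choice(non_edges, size=min(n_fp, len(non_edges)), replace=False):
            w[k // n_genes, k % n_genes] = 1.0
    motif = MotifPrior(tf_ids, gene_ids, w)

    # PPI: TFs sharing at least one target interact
    ppi_w = np.eye(n_tfs)
    targets = {tf: {g for t2, g in true_union if t2 == tf} for tf in tf_ids}
    for i in range(n_tfs):
        for j in range(i + 1, n_tfs):
            if targets[tf_ids[i]] & targets[tf_ids[j]]:
                ppi_w[i, j] = ppi_w[j, i] = 0.5
    ppi = PPIMatrix(tf_ids, ppi_w)

    truth = SyntheticTruth(
        tf_ids=tf_ids, gene_ids=gene_ids,
        edge_set_low=edge_set_low, edge_set_high=edge_set_high,
        signature_genes=list(signature), shift=shift,
        survival_beta=beta, baseline_hazard=baseline_hazard,
        censor_rate=censor_rate, seed=int(seed),
    )
    return truth, motif, ppi


def simulate_expression(
    truth: SyntheticTruth,
    n_samples_per_condition: int = 50,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Simulate the two cohorts' expression matrices.

    Rows are the target genes followed by the TFs themselves (a TF's row
    is its activity plus noise).  Signature genes get a +shift offset in
    the high condition.  Returns ``(low, high)``.
    """
    if n_samples_per_condition < 3:
        raise ValidationError("need at least 3 samples per condition")
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    row_ids = list(truth.gene_ids) + list(truth.tf_ids)
    gi = {g: i for i, g in enumerate(truth.gene_ids)}
    ti = {t: i for i, t in enumerate(truth.tf_ids)}
    out = []
    for cond, edges, prefix in (("low", truth.edge_set_low, "LOW"),
                                ("high", truth.edge_set_high, "HIGH")):
        n = n_samples_per_condition
        act = rng.standard_normal((len(truth.tf_ids), n))
        X = np.zeros((len(row_ids), n))
        for (tf, gene), eff in edges.items():
            X[gi[gene], :] += eff * act[ti[tf], :]
        X[len(truth.gene_ids):, :] = act
        X += rng.normal(0.0, noise_sd, size=X.shape)
        if cond == "high" and truth.shift != 0:
            for g in truth.signature_genes:
                X[gi[g], :] += truth.shift
        samples = [f"{prefix}_{i + 1:03d}" for i in range(n)]
        out.append(ExpressionMatrix(row_ids, samples, X))
    return out[0], out[1]


def draw_clinical_covariates(sample_ids, types, seed: int = 0) -> np.ndarray:
    """Draw ages typical of the two diagnoses: LGG ~ N(41, 8), GBM ~ N(60, 8)."""
    rng = np.random.default_rng(seed)
    means = np.where(np.asarray(types) == "GBM", 60.0, 41.0)
    return np.clip(rng.normal(means, 8.0), 18.0, None)


def simulate_survival(truth: SyntheticTruth, expression: ExpressionMatrix,
                      ages, types, seed: int = 0):
    """Draw survival from the planted proportional-hazards model.

    Event time ~ Exponential(baseline_hazard * exp(beta' x)) with
    x = (signature-gene expressions, age, GBM indicator).  Censoring is
    uniform on [0, Q] with Q calibrated numerically so the realized
    censoring fraction matches ``truth.censor_rate``.  Returns a
    clinical table (sample_id, age_years, type, os_days, event).
    """
    import pandas as pd

    ages = np.asarray(ages, dtype=float)
    types = list(types)
    n = expression.n_samples
    if len(ages) != n or len(types) != n:
        raise ValidationError("ages/types must align with expression samples")
    rng = np.random.default_rng(seed)

    lp = np.zeros(n)
    pos = {g: i for i, g in enumerate(expression.gene_ids)}
    for g in truth.signature_genes:
        if g not in pos:
            raise ValidationError(f"signature gene {g} absent from expression matrix")
        lp += truth.survival_beta[g] * expression.values[pos[g], :]
    lp += truth.survival_beta["age_years"] * ages
    lp += truth.survival_beta["type_GBM"] * (np.asarray(types) == "GBM")
    lp -= lp.mean()  # baseline hazard carries the overall scale

    rate = truth.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)

    if truth.censor_rate == 0:
        os_days, event = t_event, np.ones(n, dtype=int)
    else:
        u = rng.uniform(size=n)

        def censored_fraction(q):
            return float(np.mean(u * q < t_event))

        lo, hi = 1e-9, float(np.max(t_event)) * 1e3
        target = truth.censor_rate
        for _ in range(200):  # bisection on the (nonincreasing) empirical fraction
            mid = np.sqrt(lo * hi)
            if censored_fraction(mid) > target:
                lo = mid
            else:
                hi = mid
        q = hi
        c = u * q
        event = (t_event <= c).astype(int)
        os_days = np.minimum(t_event, c)
        realized = 1.0 - event.mean()
        if abs(realized - target) > 0.1:
            log.warning("realized censoring %.2f misses target %.2f", realized, target)

    return pd.DataFrame({
        "sample_id": expression.sample_ids,
        "age_years": ages,
        "type": types,
        "os_days": os_days,
        "event": event,
    })


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "tf_ids": truth.tf_ids,
        "gene_ids": truth.gene_ids,
        "edge_set_low": [[t, g, e] for (t, g), e in truth.edge_set_low.items()],
        "edge_set_high": [[t, g, e] for (t, g), e in truth.edge_set_high.items()],
        "signature_genes": truth.signature_genes,
        "shift": truth.shift,
        "survival_beta": truth.survival_beta,
        "baseline_hazard": truth.baseline_hazard,
        "censor_rate": truth.censor_rate,
        "seed": truth.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SyntheticTruth(
        tf_ids=d["tf_ids"], gene_ids=d["gene_ids"],
        edge_set_low={(t, g): e for t, g, e in d["edge_set_low"]},
        edge_set_high={(t, g): e for t, g, e in d["edge_set_high"]},
        signature_genes=d["signature_genes"], shift=d["shift"],
        survival_beta=d["survival_beta"], baseline_hazard=d["baseline_hazard"],
        censor_rate=d["censor_rate"], seed=d["seed"],
    )
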