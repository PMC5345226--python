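"""Prognostic modeling: Cox regression, LASSO signature extraction,
prognostic-index stratification, log-rank tests, and validation-style
embeddings.

The prognostic index (risk score) of a sample is the linear component
of a fitted Cox model, PI = sum_i beta_i * x_i over the model's nonzero
covariates; the median PI splits samples into high- and low-risk
groups.  The sparse gene signature comes from an L1-penalized Cox fit
in which clinical covariates (age, tumor type) stay unpenalized, with
the penalty weight chosen by cross-validated partial likelihood.

The unpenalized fitter maximizes the Cox partial likelihood with
Breslow tie handling by Newton iteration (gradient norm < 1e-8);
standard errors come from the inverse observed information.  Efron tie
handling is available behind a flag (delegated to lifelines).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .containers import ExpressionMatrix, validate_clinical
from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "PenalizedCoxFit",
    "PIResult",
    "SurvivalComparison",
    "fit_cox",
    "lasso_cox",
    "prognostic_index",
    "logrank",
    "per_gene_cox",
    "report_embedding",
    "encode_type",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass
class CoxFit:
    """Cox proportional-hazards fit: per-covariate inference plus log-likelihood."""

    summary: pd.DataFrame  # index covariate; coef, se, hr, hr_ci_low, hr_ci_high, p
    loglik: float
    converged: bool = True
    flags: dict = field(default_factory=dict)

    @property
    def coefficients(self) -> pd.Series:
        return self.summary["coef"]

    @property
    def nonzero(self) -> list:
        return list(self.summary.index[self.summary["coef"] != 0.0])


@dataclass
class PenalizedCoxFit(CoxFit):
    """L1-penalized Cox fit; gene coefficients penalized, clinical ones not."""

    lambda_: float = 0.0
    penalized: pd.Series | None = None  # bool per covariate
    cv_path: pd.DataFrame | None = None

    @property
    def support(self) -> list:
        """Penalized covariates that survived with a nonzero coefficient."""
        s = self.summary["coef"]
        pen = self.penalized if self.penalized is not None else pd.Series(True, index=s.index)
        return list(s.index[(s != 0.0) & pen])


@dataclass
class PIResult:
    """Per-sample prognostic index and median-split risk group."""

    table: pd.DataFrame  # index sample_id; columns pi, risk_group
    median: float

    @property
    def pi(self) -> pd.Series:
        return self.table["pi"]

    @property
    def risk_group(self) -> pd.Series:
        return self.table["risk_group"]


@dataclass
class SurvivalComparison:
    """Two-sample log-rank result plus the group hazard ratio."""

    chi2: float
    p: float
    hr: float
    hr_ci_low: float
    hr_ci_high: float
    flags: dict = field(default_factory=dict)


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.shape != events.shape:
        raise ValidationError("times and events must align")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValidationError("events must be binary 0/1")
    if np.any(times < 0) or np.any(~np.isfinite(times)):
        raise ValidationError("times must be finite and nonnegative")
    if events.sum() < 1:
        raise ValidationError("need at least one event")
    return times, events.astype(int)


def _breslow_quantities(beta, X, times, events):
    """Breslow partial log-likelihood, gradient, and Hessian at beta."""
    n, p = X.shape
    eta = X @ beta
    eta_c = eta - eta.max()  # guard exp overflow; cancels in ratios
    w = np.exp(eta_c)
    order = np.argsort(-times, kind="mergesort")
    ll, grad = 0.0, np.zeros(p)
    hess = np.zeros((p, p))
    S0, S1 = 0.0, np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = times[order[i]]
        j = i
        while j < n and times[order[j]] == t:  # admit all samples tied at t
            k = order[j]
            S0 += w[k]
            S1 += w[k] * X[k]
            S2 += w[k] * np.outer(X[k], X[k])
            j += 1
        for k in order[i:j]:
            if events[k]:
                mu = S1 / S0
                ll += eta_c[k] - np.log(S0)
                grad += X[k] - mu
                hess -= S2 / S0 - np.outer(mu, mu)
        i = j
    return ll, grad, hess


def _newton_breslow(X, times, events, max_iter=60, gtol=1e-8):
    n, p = X.shape
    beta = np.zeros(p)
    ll, grad, hess = _breslow_quantities(beta, X, times, events)
    converged, separated = False, False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        # step halving on log-likelihood decrease
        scale = 1.0
        for _ in range(30):
            ll_new, g_new, h_new = _breslow_quantities(beta + scale * step, X, times, events)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll, grad, hess = ll_new, g_new, h_new
        if np.max(np.abs(beta)) > 50:
            separated = True  # monotone likelihood / perfect separation
            break
    else:
        pass
    if not converged and np.max(np.abs(grad)) < gtol:
        converged = True
    return beta, ll, grad, hess, converged, separated


def fit_cox(covariates: pd.DataFrame, times, events, ties: str = "breslow") -> CoxFit:
    """Fit a Cox proportional-hazards model.

    ``covariates`` is samples x covariates with no missing values.
    Breslow tie handling solves the partial likelihood by Newton
    iteration; ``ties='efron'`` delegates to lifelines.  Monotone
    likelihood (perfect separation) is reported via
    ``flags['separation']`` rather than raised.
    """
    if covariates.isna().any().any():
        raise ValidationError("covariates contain missing values")
    times, events = _check_surv(times, events)
    if len(covariates) != len(times):
        raise ValidationError("covariate rows must align with times")
    X = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)

    if ties == "efron":
        df = covariates.copy()
        df["_time"], df["_event"] = times, events
        cph = CoxPHFitter()
        cph.fit(df, duration_col="_time", event_col="_event")
        s = cph.summary
        summary = pd.DataFrame({
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": np.exp(s["coef"]),
            "hr_ci_low": np.exp(s["coef"] - _Z975 * s["se(coef)"]),
            "hr_ci_high": np.exp(s["coef"] + _Z975 * s["se(coef)"]),
            "p": s["p"],
        })
        summary.index = names
        return CoxFit(summary, float(cph.log_likelihood_), True, {"ties": "efron"})
    if ties != "breslow":
        raise ValidationError("ties must be 'breslow' or 'efron'")

    beta, ll, grad, hess, converged, separated = _newton_breslow(X, times, events)
    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(names), np.nan)
    # monotone likelihood: a coefficient drifting off to +-inf with a flat likelihood
    if np.any((np.abs(beta) > 10) & ((se > 5) | ~np.isfinite(se))):
        separated = True
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    clip = lambda v: np.clip(v, -700, 700)  # noqa: E731 - exp overflow guard
    summary = pd.DataFrame({
        "coef": beta,
        "se": se,
        "hr": np.exp(clip(beta)),
        "hr_ci_low": np.exp(clip(beta - _Z975 * se)),
        "hr_ci_high": np.exp(clip(beta + _Z975 * se)),
        "p": pvals,
    }, index=names)
    flags = {"ties": "breslow"}
    if separated:
        flags["separation"] = True
        log.warning("fit_cox: monotone likelihood suspected (separation)")
    return CoxFit(summary, float(ll), converged and not separated, flags)


def encode_type(types) -> pd.DataFrame:
    """One-hot encode the type/grade column, dropping the first (reference) level."""
    cats = sorted(pd.unique(pd.Series(list(types))))
    if len(cats) < 2:
        return pd.DataFrame(index=range(len(list(types))))
    arr = pd.Series(list(types))
    return pd.DataFrame({f"type_{c}": (arr == c).astype(float) for c in cats[1:]})


def _clinical_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    enc = encode_type(clinical["type"])
    enc.index = clinical.index
    out = pd.concat([clinical[["age_years"]].astype(float), enc], axis=1)
    return out


def lasso_cox(gene_matrix: pd.DataFrame, clinical: pd.DataFrame,
              n_folds: int = 5, seed: int = 0,
              alphas=None) -> PenalizedCoxFit:
    """L1-penalized Cox fit of genes plus unpenalized age and type.

    ``gene_matrix`` is samples x genes, rows aligned with the clinical
    table.  Gene covariates are standardized before penalization and
    coefficients reported on the original scale; age and the type
    indicator carry penalty factor 0 so the penalty can never exclude
    them.  The penalty weight is chosen to maximize the k-fold
    cross-validated test partial likelihood (folds seeded for
    determinism), then the model is refit on all samples.
    """
    clinical = validate_clinical(clinical.reset_index(drop=True))
    if len(gene_matrix) != len(clinical):
        raise ValidationError("gene matrix rows must align with clinical samples")
    times, events = _check_surv(clinical["os_days"], clinical["event"])
    n_events = int(events.sum())
    if n_events == 0:
        raise ValidationError("all samples censored; cannot fit")
    if n_events < 10:
        log.warning("lasso_cox: only %d events; estimates will be unstable", n_events)

    genes = list(gene_matrix.columns)
    G = gene_matrix.to_numpy(dtype=float)
    mu, sd = G.mean(axis=0), G.std(axis=0)
    keep = sd > 0
    if not keep.all():
        log.warning("lasso_cox: %d constant genes dropped", int((~keep).sum()))
        genes = [g for g, k in zip(genes, keep) if k]
        G, mu, sd = G[:, keep], mu[keep], sd[keep]
    Gz = (G - mu) / sd

    clin = _clinical_covariates(clinical)
    clin_names = list(clin.columns)
    X = np.hstack([Gz, clin.to_numpy(dtype=float)])
    names = genes + clin_names
    pf = np.array([1.0] * len(genes) + [0.0] * len(clin_names))
    y = Surv.from_arrays(events.astype(bool), times)

    def _fit(alpha_grid):
        return CoxnetSurvivalAnalysis(
            alphas=alpha_grid, l1_ratio=1.0, penalty_factor=pf,
            alpha_min_ratio=0.01, n_alphas=50, tol=1e-7, max_iter=200000,
        ).fit(X, y)

    path_model = _fit(alphas)
    grid = np.asarray(path_model.alphas_)

    if alphas is not None and len(grid) == 1:
        best_alpha = float(grid[0])
        cv_table = None
    else:
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        scores = np.zeros((n_folds, len(grid)))
        for f, (tr, te) in enumerate(kf.split(X)):
            if events[te].sum() == 0 or events[tr].sum() == 0:
                scores[f, :] = np.nan
                continue
            m = CoxnetSurvivalAnalysis(
                alphas=grid, l1_ratio=1.0, penalty_factor=pf,
                tol=1e-7, max_iter=200000).fit(X[tr], y[tr])
            coefs = m.coef_  # (p, n_alphas)
            for a in range(coefs.shape[1]):
                ll_te, _, _ = _breslow_quantities(coefs[:, a], X[te], times[te], events[te])
                scores[f, a] = ll_te
        mean_scores = np.nanmean(scores, axis=0)
        best = int(np.nanargmax(mean_scores))
        best_alpha = float(grid[best])
        cv_table = pd.DataFrame({"alpha": grid, "cv_loglik": mean_scores})

    coef_z = path_model.coef_[:, int(np.argmin(np.abs(np.asarray(path_model.alphas_) - best_alpha)))]
    # back to the original gene scale
    coef = coef_z.copy()
    coef[:len(genes)] = coef_z[:len(genes)] / sd
    ll, _, _ = _breslow_quantities(coef_z, X, times, events)

    summary = pd.DataFrame({
        "coef": coef,
        "se": np.nan,
        "hr": np.exp(coef),
        "hr_ci_low": np.nan,
        "hr_ci_high": np.nan,
        "p": np.nan,
    }, index=names)
    penalized = pd.Series(pf > 0, index=names)
    return PenalizedCoxFit(summary, float(ll), True, {"n_events": n_events},
                           lambda_=best_alpha, penalized=penalized, cv_path=cv_table)


def prognostic_index(covariates: pd.DataFrame, fit: CoxFit,
                     use: list | None = None) -> PIResult:
    """PI per sample = sum of beta_i * x_i over the fit's nonzero covariates.

    ``use`` restricts the sum to a covariate subset (e.g. genes only).
    Samples are split at the median PI; ties go to the low-risk group.
    """
    chosen = [c for c in fit.nonzero if use is None or c in set(use)]
    missing = [c for c in chosen if c not in covariates.columns]
    if missing:
        raise ValidationError(f"missing covariates for PI: {missing}")
    if chosen:
        pi = covariates[chosen].to_numpy(dtype=float) @ fit.coefficients[chosen].to_numpy()
    else:
        pi = np.zeros(len(covariates))
    if not np.all(np.isfinite(pi)):
        raise ValidationError("non-finite prognostic index")
    med = float(np.median(pi))
    group = np.where(pi > med, "high", "low")
    table = pd.DataFrame({"pi": pi, "risk_group": group}, index=covariates.index)
    return PIResult(table, med)


def logrank(groups, times, events, reference=None) -> SurvivalComparison:
    """Two-sample log-rank test plus the group hazard ratio.

    The HR is exp(beta) from a one-covariate Cox fit on the indicator of
    the non-reference group; ``reference`` defaults to the
    lexicographically smaller label.  A group with zero events raises a
    flag but the statistic stays defined.
    """
    groups = pd.Series(list(groups))
    times, events = _check_surv(times, events)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 non-empty groups, got {labels}")
    if reference is None:
        reference = labels[0]
    if reference not in labels:
        raise ValidationError(f"reference {reference!r} is not one of {labels}")
    other = labels[1] if reference == labels[0] else labels[0]
    mask = (groups == other).to_numpy()
    flags = {}
    for lab in labels:
        if events[(groups == lab).to_numpy()].sum() == 0:
            flags["zero_event_group"] = lab
    res = _ll_logrank(times[~mask], times[mask],
                      event_observed_A=events[~mask], event_observed_B=events[mask])
    ind = pd.DataFrame({"group": mask.astype(float)})
    try:
        cx = fit_cox(ind, times, events)
        row = cx.summary.loc["group"]
        hr, lo, hi = row["hr"], row["hr_ci_low"], row["hr_ci_high"]
        if cx.flags.get("separation"):
            flags["separation"] = True
    except ValidationError:
        hr = lo = hi = np.nan
    return SurvivalComparison(float(res.test_statistic), float(res.p_value),
                              float(hr), float(lo), float(hi), flags)


def per_gene_cox(gene_matrix: pd.DataFrame, clinical: pd.DataFrame,
                 p_cutoff: float = 0.05) -> pd.DataFrame:
    """One Cox model per gene (gene + age + type); flags gene p <= cutoff.

    Per-gene failures are recorded in the ``error`` column without
    aborting the sweep.
    """
    clinical = validate_clinical(clinical.reset_index(drop=True))
    if len(gene_matrix) != len(clinical):
        raise ValidationError("gene matrix rows must align with clinical samples")
    clin = _clinical_covariates(clinical)
    rows = []
    for g in gene_matrix.columns:
        cov = pd.concat([gene_matrix[[g]].reset_index(drop=True), clin], axis=1)
        try:
            fit = fit_cox(cov, clinical["os_days"], clinical["event"])
            row = fit.summary.loc[g]
            rows.append((g, row["coef"], row["hr"], row["p"],
                         bool(row["p"] <= p_cutoff), ""))
        except (ValidationError, np.linalg.LinAlgError) as exc:
            rows.append((g, np.nan, np.nan, np.nan, False, str(exc)))
    return pd.DataFrame(rows, columns=["gene_id", "coef", "hr", "p", "flagged", "error"])


def report_embedding(expr: ExpressionMatrix, method: str = "pca", k: int = 2):
    """Validation-style unsupervised views of signature expression.

    ``method='hierarchical'`` cuts an average-linkage, correlation-
    distance dendrogram of the samples into ``k`` clusters and returns
    integer labels; ``method='pca'`` returns the first two principal-
    component scores of the centered signature expression per sample.
    """
    if expr.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    X = expr.values.T  # samples x genes
    if method == "hierarchical":
        if np.any(X.std(axis=1) == 0):
            raise ValidationError("constant sample profile; correlation distance undefined")
        Z = linkage(X, method="average", metric="correlation")
        labels = fcluster(Z, t=k, criterion="maxclust")
        return pd.Series(labels, index=expr.sample_ids, name="cluster")
    if method == "pca":
        Xc = X - X.mean(axis=0, keepdims=True)
        if np.allclose(Xc, 0):
            raise ValidationError("constant matrix has no principal components")
        u, s, _ = np.linalg.svd(Xc, full_matrices=False)
        scores = u[:, :2] * s[:2]
        return pd.DataFrame(scores, index=expr.sample_ids, columns=["PC1", "PC2"])
    raise ValidationError("method must be 'hierarchical' or 'pca'")
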