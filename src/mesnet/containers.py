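"""In-memory containers shared by all pipeline stages.

The common currency is :class:`ExpressionMatrix` (genes x samples,
log-scale normalized values).  Regulatory priors are a TF x gene motif
matrix and a TF x TF protein-protein interaction matrix; inferred
networks are TF x gene weight matrices in z-score-like units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "MotifPrior",
    "PPIMatrix",
    "RegulatoryNetwork",
    "validate_clinical",
    "CLINICAL_COLUMNS",
]


def _check_unique(ids, what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what} ids: {sorted(set(dups))[:10]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Log-scale normalized expression, genes on rows, samples on columns."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])

    def drop_sample(self, sample_id) -> "ExpressionMatrix":
        keep = [s for s in self.sample_ids if s != sample_id]
        if len(keep) == len(self.sample_ids):
            raise ValidationError(f"sample {sample_id!r} not present")
        return self.subset_samples(keep)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:10]}")
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[idx, :])


@dataclass
class GeneSetCollection:
    """Ordered, named gene sets (GMT semantics); set names unique, sets non-empty."""

    names: list
    members: dict  # name -> list of gene ids (deduplicated, order preserving)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        self.names = _check_unique(self.names, "gene-set")
        for name in self.names:
            if not self.members.get(name):
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name) -> list:
        return self.members[name]

    def items(self):
        return ((n, self.members[n]) for n in self.names)


@dataclass
class MotifPrior:
    """Sequence-motif regulatory prior: nonnegative TF x gene weights (1 = motif present)."""

    tf_ids: list
    gene_ids: list
    weights: np.ndarray

    def __post_init__(self):
        self.tf_ids = _check_unique(self.tf_ids, "tf")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValidationError("motif weight matrix shape inconsistent with id lists")
        if np.any(self.weights < 0):
            raise ValidationError("motif prior weights must be nonnegative")


@dataclass
class PPIMatrix:
    """Symmetric nonnegative TF x TF interaction matrix with unit diagonal."""

    tf_ids: list
    weights: np.ndarray

    def __post_init__(self):
        self.tf_ids = _check_unique(self.tf_ids, "tf")
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.tf_ids)
        if self.weights.shape != (n, n):
            raise ValidationError("PPI matrix must be square over the TF ids")
        if np.any(self.weights < 0):
            raise ValidationError("PPI weights must be nonnegative")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValidationError("PPI matrix must be symmetric")
        if not np.allclose(np.diag(self.weights), 1.0, atol=1e-12):
            raise ValidationError("PPI matrix diagonal must be 1")

    @classmethod
    def identity(cls, tf_ids) -> "PPIMatrix":
        return cls(list(tf_ids), np.eye(len(tf_ids)))


@dataclass
class RegulatoryNetwork:
    """Inferred TF -> gene network; weights are z-score-like edge confidences."""

    tf_ids: list
    gene_ids: list
    W: np.ndarray
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        self.tf_ids = _check_unique(self.tf_ids, "tf")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValidationError("network weight matrix shape inconsistent with id lists")
        if not np.all(np.isfinite(self.W)):
            raise ValidationError("network weights contain non-finite values")

    def to_edge_frame(self) -> pd.DataFrame:
        tf_col = np.repeat(self.tf_ids, len(self.gene_ids))
        gene_col = np.tile(self.gene_ids, len(self.tf_ids))
        return pd.DataFrame({"tf": tf_col, "gene": gene_col, "weight": self.W.ravel()})


CLINICAL_COLUMNS = ["sample_id", "age_years", "type", "os_days", "event"]


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table (sample_id, age_years, type, os_days, event)."""
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns: {missing}")
    _check_unique(df["sample_id"], "clinical sample")
    if not set(pd.unique(df["event"])) <= {0, 1}:
        raise ValidationError("event must be binary 0/1")
    if (df["os_days"] < 0).any():
        raise ValidationError("os_days must be nonnegative")
    if (df["age_years"] <= 0).any():
        raise ValidationError("age_years must be positive")
    return df
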