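"""Readers and writers for every external format the pipeline touches.

All tabular files are tab-separated UTF-8 with '.' decimals and no
quoting; gene and sample ids are opaque strings.  Formats:

* expression TSV — first column gene ids, header row sample ids, numeric body
* clinical TSV — columns sample_id, age_years, type, os_days, event
* GMT — name, description, tab-separated members
* motif prior / PPI — 3-column edge list (source, target, weight)
* networks — wide TSV (TF rows, gene columns) or long edge-list TSV

Every reader/writer pair is a lossless round trip on valid input.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    CLINICAL_COLUMNS,
    ExpressionMatrix,
    GeneSetCollection,
    MotifPrior,
    PPIMatrix,
    RegulatoryNetwork,
    validate_clinical,
)
from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "read_expression", "write_expression", "normalize_counts", "size_factors",
    "read_clinical", "write_clinical",
    "read_gene_sets", "write_gene_sets",
    "read_motif_prior", "write_motif_prior",
    "read_ppi", "write_ppi",
    "write_network", "read_network",
]


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV into an :class:`ExpressionMatrix`.

    Ids are preserved in file order; duplicate gene or sample ids are
    rejected, and any non-numeric cell raises a parse error naming its
    row and column.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except OSError as exc:
        raise ParseError(f"cannot read expression file {path}: {exc}") from exc
    if df.columns.has_duplicates:
        raise ValidationError(f"duplicate sample ids in {path}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids in {path}: {dups[:10]}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = df.index[(bad | df[col].isna()).to_numpy()][0]
            raise ParseError(
                f"non-numeric or missing value at gene {row!r}, sample {col!r} in {path}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factor per sample (column).

    The ratio is count / geometric-row-mean; genes containing any zero
    are excluded from the median.  When every gene contains a zero the
    estimate falls back to library-size ratios with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValidationError("counts must be nonnegative")
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValidationError("need at least 2 samples to estimate size factors")
    all_positive = np.all(counts > 0, axis=1)
    if all_positive.any():
        log_counts = np.log(counts[all_positive, :])
        log_geo_mean = log_counts.mean(axis=1, keepdims=True)
        return np.exp(np.median(log_counts - log_geo_mean, axis=0))
    log.warning("every gene contains a zero count; falling back to library-size ratios")
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        raise ValidationError("empty sample column; cannot normalize")
    return lib / np.exp(np.mean(np.log(lib)))


def normalize_counts(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize a nonnegative count matrix to log2 scale.

    Output is log2(count / size_factor + 1) with median-of-ratios size
    factors — a deterministic variance-flattening transform that
    preserves the rank structure the downstream stages consume.
    """
    sf = size_factors(raw.values)
    values = np.log2(np.asarray(raw.values, dtype=float) / sf + 1.0)
    return ExpressionMatrix(list(raw.gene_ids), list(raw.sample_ids), values)


def read_clinical(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "type": str})
    except OSError as exc:
        raise ParseError(f"cannot read clinical file {path}: {exc}") from exc
    return validate_clinical(df[CLINICAL_COLUMNS])


def write_clinical(df: pd.DataFrame, path) -> None:
    validate_clinical(df)[CLINICAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file; duplicate members within a set are dropped with a warning."""
    names, members, descriptions = [], {}, {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, genes = parts[0], parts[1], parts[2:]
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                log.warning("gene set %r: %d duplicate members dropped",
                            name, len(genes) - len(deduped))
            names.append(name)
            members[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(names, members, descriptions)


def write_gene_sets(sets: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets.names:
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sets.members[name]]) + "\n")


def _read_edge_list(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=0,
                         names=["source", "target", "weight"],
                         dtype={"source": str, "target": str})
    except OSError as exc:
        raise ParseError(f"cannot read edge list {path}: {exc}") from exc
    df["weight"] = pd.to_numeric(df["weight"], errors="raise")
    return df


def read_motif_prior(path) -> MotifPrior:
    """Read a 3-column (tf, gene, weight) TSV into a dense TF x gene prior."""
    df = _read_edge_list(path)
    tfs = list(dict.fromkeys(df["source"]))
    genes = list(dict.fromkeys(df["target"]))
    w = np.zeros((len(tfs), len(genes)))
    ti = {t: i for i, t in enumerate(tfs)}
    gi = {g: i for i, g in enumerate(genes)}
    for s, t, v in df.itertuples(index=False):
        w[ti[s], gi[t]] = v
    return MotifPrior(tfs, genes, w)


def write_motif_prior(prior: MotifPrior, path, keep_zeros: bool = False) -> None:
    rows = []
    for i, tf in enumerate(prior.tf_ids):
        for j, g in enumerate(prior.gene_ids):
            if keep_zeros or prior.weights[i, j] != 0:
                rows.append((tf, g, prior.weights[i, j]))
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_ppi(path) -> PPIMatrix:
    """Read a 3-column (tf, tf, weight) TSV; symmetrized, unit diagonal enforced."""
    df = _read_edge_list(path)
    tfs = list(dict.fromkeys(list(df["source"]) + list(df["target"])))
    w = np.eye(len(tfs))
    ti = {t: i for i, t in enumerate(tfs)}
    for s, t, v in df.itertuples(index=False):
        w[ti[s], ti[t]] = v
        w[ti[t], ti[s]] = v
    np.fill_diagonal(w, 1.0)
    return PPIMatrix(tfs, w)


def write_ppi(ppi: PPIMatrix, path) -> None:
    rows = []
    n = len(ppi.tf_ids)
    for i in range(n):
        for j in range(i, n):
            if ppi.weights[i, j] != 0:
                rows.append((ppi.tf_ids[i], ppi.tf_ids[j], ppi.weights[i, j]))
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def write_network(net: RegulatoryNetwork, path) -> None:
    """Write a network as a wide TSV (TF rows, gene columns)."""
    pd.DataFrame(net.W, index=net.tf_ids, columns=net.gene_ids).to_csv(
        path, sep="\t", index_label="tf", float_format="%.17g")


def read_network(path) -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RegulatoryNetwork(list(df.index), list(df.columns), df.to_numpy(dtype=float))
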