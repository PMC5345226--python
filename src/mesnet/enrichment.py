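"""Over-representation analysis and prognostic candidate-set assembly.

ORA is the hypergeometric upper tail: with a universe of N genes of
which K belong to a set, and a query of n genes hitting k of them,
p = P[X >= k] for X ~ Hypergeometric(N, K, n).  "Top" pathways are
those at raw p <= the configured cutoff (BH q is reported alongside).
The candidate set for survival modeling is a pathway's genes expanded
with every TF that retains at least one filtered edge into them in
either phenotype.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .containers import GeneSetCollection
from .diffexpr import bh_adjust
from .diffnet import FilteredNetworkPair
from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = ["ora", "candidate_set", "CandidateSet"]


def ora(query, universe, sets: GeneSetCollection, enrich_p: float = 0.005) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe before testing; the query
    must be contained in the universe.  Returns one row per set with
    k, K, N, n, p, q and a ``top`` flag (raw p <= enrich_p), sorted by
    ascending p.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe must be non-empty")
    query = set(query)
    if not query <= universe:
        raise ValidationError("query genes must be contained in the universe")
    n_univ, n_query = len(universe), len(query)
    rows = []
    for name, members in sets.items():
        in_univ = set(members) & universe
        k = len(in_univ & query)
        K = len(in_univ)
        # upper tail P[X >= k]
        p = float(stats.hypergeom.sf(k - 1, n_univ, K, n_query)) if K else 1.0
        rows.append((name, k, K, n_univ, n_query, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["set_name", "k", "K", "N", "n", "p"])
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    table["top"] = table["p"] <= enrich_p
    return table.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)


class CandidateSet:
    """Pathway genes plus the TFs that regulate them in the filtered networks."""

    def __init__(self, pathway_genes, regulating_tfs):
        self.pathway_genes = sorted(dict.fromkeys(pathway_genes))
        self.regulating_tfs = sorted(dict.fromkeys(regulating_tfs))
        # pathway genes first, then TFs, deduplicated, each block alphabetical
        seen = set(self.pathway_genes)
        self.union = list(self.pathway_genes) + [t for t in self.regulating_tfs
                                                 if t not in seen]

    def __len__(self) -> int:
        return len(self.union)


def candidate_set(pathway_genes, filtered: FilteredNetworkPair) -> CandidateSet:
    """Expand a pathway's genes with the TFs targeting them.

    A TF qualifies when it has at least one retained edge (unique to
    either phenotype or shared) into a pathway gene.  Pathway genes
    absent from the network's gene axis contribute no regulators but
    stay in the union (logged).
    """
    genes = list(dict.fromkeys(pathway_genes))
    retained = filtered.retained
    network_genes = set(retained["gene"]) if len(retained) else set()
    absent = [g for g in genes if g not in network_genes]
    if absent:
        log.info("candidate_set: %d pathway genes have no retained edges: %s",
                 len(absent), absent[:10])
    if len(retained):
        tfs = retained.loc[retained["gene"].isin(set(genes)), "tf"].unique().tolist()
    else:
        tfs = []
    return CandidateSet(genes, tfs)
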