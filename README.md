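# mesnet

Condition-specific regulatory-network comparison and prognostic-signature
extraction for tumor expression cohorts, built around the mesenchymal
signature (MS) in gliomas.

Low-grade gliomas and glioblastomas differ sharply in outcome, and part of
that difference tracks a mesenchymal expression program associated with
invasion, stemness, and treatment resistance. `mesnet` is for
computational biologists who want to ask, from expression matrices plus a
motif prior: *which TF→gene regulation is specific to the high-MS
phenotype, and which of the rewired genes predict survival?* It
implements the full chain as a tested, seedable library with a thin CLI:

1. **Stratify** samples by a signature *metagene score* (mean expression
   of a signature gene list) into quartile-tail cohorts — at 275 samples
   and fraction 0.25, exactly 69 per cohort.
2. **Rank** genes by Welch-test differential expression
   (|log2FC| ≥ 1, BH q ≤ 0.05).
3. **Infer** a TF→gene network per cohort by message passing between
   motif, PPI, and co-expression evidence, using the continuous Tanimoto
   kernel `T(x,y) = x·y / √(‖x‖² + ‖y‖² − |x·y|)` and the update
   `W ← (1−α)W + α(R+A)/2` with responsibility `R = T(P, W)` and
   availability `A = T(W, C)`.
4. **Compare** the networks with leave-one-out jackknife ensembles:
   per-edge Welch t-tests with BH FDR, the |Δw| / −log10 FDR filter
   (with a permutation-null calibration of the |Δw| cutoff), unique/shared
   subnetwork extraction, and differential weighted *indegree* per gene.
5. **Enrich** the rewired genes against GMT gene sets (hypergeometric
   upper tail) and assemble the candidate set: pathway genes + their
   regulating TFs.
6. **Extract** a sparse prognostic signature with an L1-penalized Cox
   model (age and type unpenalized, λ by 5-fold cross-validated partial
   likelihood), compute each sample's *prognostic index*
   `PI = Σᵢ β̂ᵢ xᵢ`, and test the median-split risk groups by log-rank
   and Cox hazard ratio.

A synthetic-data module generates two-cohort studies with planted
regulatory edges, a shifted signature metagene, and proportional-hazards
survival with known coefficients, so every stage is testable end to end
without any data download. See `docs/methods.md` for the models,
assumptions, and limitations.

## Worked example

Run the whole pipeline on a simulated study (10 TFs × 50 genes, 30
samples per condition, seed 1):

```bash
mesnet run-all --seed 1 --out-dir demo --n-samples 30
```

prints (reformatted):

```json
{
 "cohort_sizes": {"EXCLUDED": 30, "LOW_MS": 15, "HIGH_MS": 15},
 "n_deg": 11,
 "filtered_counts": {"unique_low": 0, "unique_high": 0, "shared": 4},
 "n_differential_genes": 4,
 "candidate_set_size": 5,
 "signature": ["G0017", "G0021", "G0036", "G0049", "TF001"],
 "logrank_p": 1.58e-14,
 "risk_group_hr": 17.2
}
```

Reading this: the 60 simulated samples were split into quartile cohorts
of 15; 11 genes passed the differential-expression filter; after
jackknife edge tests and the calibrated |Δw| filter, 4 edges distinguish
the two networks and 4 genes show differential indegree; expanding them
with their regulating TFs gives a 5-member candidate set; the penalized
Cox fit keeps 5 covariates as the signature, and the prognostic-index
median split separates survival sharply (log-rank p ≈ 1.6e-14, high- vs
low-risk hazard ratio ≈ 17 — large here because the study is small and
the planted effects are clean).

Each stage is also available separately (`mesnet simulate | cohorts |
deg | panda | diffnet | enrich | survival`), and everything the CLI does
is a one-line call into the library:

```python
from mesnet import synthetic, cohorts
truth, motif, ppi = synthetic.generate_truth(seed=1)
low, high = synthetic.simulate_expression(truth, n_samples_per_condition=69, seed=2)
scores = cohorts.metagene_score(low, truth.signature_genes)
```

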