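"""Run configuration: every threshold the pipeline applies, in one place.

Defaults are the published operating point of the analysis: quartile
cohorts, |log2FC| >= 1 with BH FDR <= 0.05 for differential expression,
edge filtering at |delta weight| >= 1 and -log10(FDR) > 25, differential
indegree at raw p <= 0.05, and pathway enrichment at p <= 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml

from .errors import ValidationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    fraction: float = 0.25          # cohort tail fraction
    lfc_threshold: float = 1.0      # |log2FC| cutoff for DEGs
    deg_fdr: float = 0.05           # BH FDR cutoff for DEGs
    alpha: float = 0.1              # message-passing learning rate
    tol: float = 1e-3               # convergence on mean |dW|
    max_iter: int = 200
    min_delta_w: float = 1.0        # edge filter: |mean_high - mean_low|
    min_neglog10_fdr: float = 25.0  # edge filter: -log10 BH FDR (strict >)
    indegree_p: float = 0.05        # raw p cutoff for differential indegree
    enrich_p: float = 0.005         # raw p cutoff for "top" pathways
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fraction <= 0.5):
            raise ValidationError("fraction must be in (0, 0.5]")
        for name in ("lfc_threshold", "deg_fdr", "tol", "min_delta_w",
                     "min_neglog10_fdr", "indegree_p", "enrich_p"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 < self.alpha <= 1):
            raise ValidationError("alpha must be in (0, 1]")
        if self.max_iter < 0:
            raise ValidationError("max_iter must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
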