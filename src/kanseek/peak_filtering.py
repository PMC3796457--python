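"""Reduce a called-region set to the analysis set by fold-enrichment thresholds.

The default policy keeps a region if *any* replicate reaches three-fold
enrichment; printed target rows such as enrichment pairs (1.8, 6.5) rule
out an all-replicates rule.  An optional FDR ceiling can be applied on top
(off by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from kanseek.errors import ConfigError, ValidationError
from kanseek.io_formats import BindingRegion

FOLD_RULES = ("any_replicate", "all_replicates", "mean")


@dataclass(frozen=True)
class FilterPolicy:
    """Fold-enrichment (and optional FDR) thresholding policy."""

    min_fold: float = 3.0
    fold_rule: str = "any_replicate"
    max_fdr: float | None = None

    def __post_init__(self) -> None:
        if not (self.min_fold > 0):
            raise ConfigError(f"min_fold must be > 0, got {self.min_fold}")
        if self.fold_rule not in FOLD_RULES:
            raise ConfigError(f"fold_rule must be one of {FOLD_RULES}, got {self.fold_rule!r}")


def _passes_fold(enrichment: Sequence[float], policy: FilterPolicy) -> bool:
    if policy.fold_rule == "any_replicate":
        return max(enrichment) >= policy.min_fold
    if policy.fold_rule == "all_replicates":
        return min(enrichment) >= policy.min_fold
    return sum(enrichment) / len(enrichment) >= policy.min_fold


def filter_regions(regions: Sequence[BindingRegion], policy: FilterPolicy | None = None) -> list[BindingRegion]:
    """Return the subset of ``regions`` passing ``policy``, preserving order."""
    policy = policy or FilterPolicy()
    kept: list[BindingRegion] = []
    for region in regions:
        if len(region.enrichment) == 0:
            raise ValidationError(f"region {region.region_id}: empty enrichment list")
        if any(math.isnan(e) for e in region.enrichment):
            raise ValidationError(f"region {region.region_id}: NaN enrichment")
        ok = _passes_fold(region.enrichment, policy)
        if ok and policy.max_fdr is not None:
            ok = min(region.fdr) <= policy.max_fdr
        if ok:
            kept.append(region)
    return kept
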