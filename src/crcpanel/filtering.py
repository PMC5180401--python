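"""Tumor-only somatic filtering.

Without a matched normal, a tumor variant call is kept as putatively somatic
when it (1) is rare in population databases (every populated database
frequency <= 1% by default), (2) clears the allelic-fraction calling floor
(AF >= 10% by default), and (3) looks somatic rather than germline
heterozygous under a two-component allele-fraction model:

- germline het component: Beta density centered at AF 0.5;
- somatic component: Beta density centered at purity/2 with a broad spread.

Classification is by the log density ratio against a configurable threshold.
A manual-review override file (variant key -> forced label) can force
individual calls either way; automated filtering cannot replace pathologist
review, only record its verdicts.

Copy-number calls are kept only as gains (fold change strictly > 2.5) or
losses (strictly < 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import CopyNumberRecord, VariantRecord

__all__ = [
    "GermlineModelConfig",
    "FilterConfig",
    "FilteredCallset",
    "filter_population",
    "classify_germline_somatic",
    "apply_filters",
    "variant_key",
]


@dataclass(frozen=True)
class GermlineModelConfig:
    """Two-component allele-fraction model for germline-vs-somatic calls."""

    het_center: float = 0.5
    het_sd: float = 0.07
    purity_prior: float = 0.6
    somatic_sd: float = 0.15
    decision_threshold: float = 0.0  # log-odds above which a call is somatic

    def __post_init__(self) -> None:
        if not 0.0 < self.het_center < 1.0:
            raise ValueError("het_center must be in (0, 1)")
        if self.het_sd <= 0 or self.somatic_sd <= 0:
            raise ValueError("component spreads must be positive")
        if not 0.0 < self.purity_prior <= 1.0:
            raise ValueError("purity_prior must be in (0, 1]")


@dataclass(frozen=True)
class FilterConfig:
    pop_af_max: float = 0.01
    min_allelic_fraction: float = 0.10
    cnv_gain_min: float = 2.5
    cnv_loss_max: float = 0.5
    germline_model: GermlineModelConfig = field(default_factory=GermlineModelConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.pop_af_max < 1.0:
            raise ValueError("pop_af_max must be in (0, 1)")
        if not 0.0 <= self.min_allelic_fraction < 1.0:
            raise ValueError("min_allelic_fraction must be in [0, 1)")
        if not self.cnv_loss_max < 1.0 < self.cnv_gain_min:
            raise ValueError("need cnv_loss_max < 1 < cnv_gain_min")


def filter_population(
    variants: Sequence[VariantRecord], config: FilterConfig
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split variants into (kept, deprioritized) by population allele frequency.

    A variant is deprioritized iff any populated database frequency exceeds
    ``pop_af_max`` (strictly).  Variants with no population data are kept.
    The partition is exhaustive and disjoint.
    """
    kept, deprioritized = [], []
    for v in variants:
        if v.pop_af and any(af > config.pop_af_max for af in v.pop_af.values()):
            deprioritized.append(v)
        else:
            kept.append(v)
    return kept, deprioritized


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched Beta(alpha, beta); spread capped to stay a valid Beta."""
    var = min(sd * sd, mean * (1 - mean) * 0.99)
    nu = mean * (1 - mean) / var - 1.0
    return max(mean * nu, 1e-3), max((1 - mean) * nu, 1e-3)


def _log_beta_pdf(x: float, a: float, b: float) -> float:
    if not 0.0 < x < 1.0:
        x = min(max(x, 1e-9), 1 - 1e-9)
    return (
        (a - 1) * math.log(x)
        + (b - 1) * math.log1p(-x)
        - (math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b))
    )


def classify_germline_somatic(
    variant: VariantRecord, model: GermlineModelConfig
) -> tuple[str, float | None]:
    """Label a variant ``somatic`` / ``likely_germline`` by allele fraction.

    Returns ``(label, log_odds)``; a variant without an allelic fraction is
    passed through as ``("unscored", None)``.  Deterministic for a fixed
    configuration.
    """
    if variant.allelic_fraction is None:
        return "unscored", None
    af = variant.allelic_fraction
    a_g, b_g = _beta_params(model.het_center, model.het_sd)
    a_s, b_s = _beta_params(model.purity_prior / 2.0, model.somatic_sd)
    log_odds = _log_beta_pdf(af, a_s, b_s) - _log_beta_pdf(af, a_g, b_g)
    label = "somatic" if log_odds > model.decision_threshold else "likely_germline"
    return label, log_odds


def variant_key(v: VariantRecord) -> tuple[str, str, int, str, str]:
    return (v.donor_id, v.chrom, v.pos, v.ref, v.alt)


@dataclass
class FilteredCallset:
    """Output of the composed filter: surviving calls plus full bookkeeping."""

    variants: list[VariantRecord]
    cnv_gains: list[CopyNumberRecord]
    cnv_losses: list[CopyNumberRecord]
    removals: list[tuple[VariantRecord, str]]
    counts: dict[str, int]


def apply_filters(
    variants: Sequence[VariantRecord],
    cnvs: Sequence[CopyNumberRecord] = (),
    config: FilterConfig | None = None,
    overrides: Mapping[tuple, str] | None = None,
) -> FilteredCallset:
    """Compose the tumor-only filters: population -> AF floor -> germline model.

    ``overrides`` maps :func:`variant_key` tuples to a forced label
    (``"somatic"`` or ``"likely_germline"``), standing in for manual
    molecular-pathologist review.  Every removal is recorded with its reason;
    removal counts by reason sum to ``len(variants) - len(kept)``.
    """
    config = config or FilterConfig()
    overrides = overrides or {}
    counts = {"population_af": 0, "af_floor": 0, "likely_germline": 0}
    removals: list[tuple[VariantRecord, str]] = []
    kept: list[VariantRecord] = []

    pop_kept, deprioritized = filter_population(variants, config)
    for v in deprioritized:
        if overrides.get(variant_key(v)) == "somatic":
            pop_kept.append(v)
            continue
        counts["population_af"] += 1
        removals.append((v, "population_af"))

    for v in pop_kept:
        forced = overrides.get(variant_key(v))
        if forced == "somatic":
            kept.append(v)
            continue
        if forced == "likely_germline":
            counts["likely_germline"] += 1
            removals.append((v, "likely_germline"))
            continue
        if v.allelic_fraction is not None and v.allelic_fraction < config.min_allelic_fraction:
            counts["af_floor"] += 1
            removals.append((v, "af_floor"))
            continue
        label, _ = classify_germline_somatic(v, config.germline_model)
        if label == "likely_germline":
            counts["likely_germline"] += 1
            removals.append((v, "likely_germline"))
        else:  # somatic or unscored calls survive
            kept.append(v)

    gains = [c for c in cnvs if c.fold_change > config.cnv_gain_min]
    losses = [c for c in cnvs if c.fold_change < config.cnv_loss_max]
    return FilteredCallset(kept, gains, losses, removals, counts)
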