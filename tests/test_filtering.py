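import math

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_snv
from crcpanel.filtering import (
    FilterConfig,
    GermlineModelConfig,
    apply_filters,
    classify_germline_somatic,
    filter_population,
    variant_key,
)
from crcpanel.io import CopyNumberRecord, VariantClass


def test_population_filter_strict_one_percent():
    config = FilterConfig()
    common = make_snv(pos=1, pop_af={"dbSNP": 0.05})
    boundary = make_snv(pos=2, pop_af={"dbSNP": 0.01})  # exactly 1%: kept
    nodata = make_snv(pos=3)
    kept, deprioritized = filter_population([common, boundary, nodata], config)
    assert deprioritized == [common]
    assert kept == [boundary, nodata]


def test_population_filter_any_database_triggers():
    v = make_snv(pop_af={"dbSNP": 0.001, "ExAC": 0.02})
    kept, deprioritized = filter_population([v], FilterConfig())
    assert deprioritized == [v]


def test_germline_model_labels():
    model = GermlineModelConfig()
    label, score = classify_germline_somatic(make_snv(af=0.50), model)
    assert label == "likely_germline" and score < 0
    label, score = classify_germline_somatic(
        make_snv(af=0.12), GermlineModelConfig(purity_prior=0.4)
    )
    assert label == "somatic" and score > 0
    label, score = classify_germline_somatic(make_snv(af=None), model)
    assert label == "unscored" and score is None


def test_germline_log_odds_matches_direct_density_computation():
    """The score is the log ratio of the somatic and germline-het Beta
    densities, checked against an independent scipy evaluation."""
    from scipy.stats import beta as beta_dist

    model = GermlineModelConfig(purity_prior=0.4)

    def moments(mean, sd):
        var = min(sd * sd, mean * (1 - mean) * 0.99)
        nu = mean * (1 - mean) / var - 1
        return mean * nu, (1 - mean) * nu

    af = 0.12
    a_g, b_g = moments(model.het_center, model.het_sd)
    a_s, b_s = moments(model.purity_prior / 2, model.somatic_sd)
    expected = beta_dist.logpdf(af, a_s, b_s) - beta_dist.logpdf(af, a_g, b_g)
    _, score = classify_germline_somatic(make_snv(af=af), model)
    assert math.isclose(score, expected, rel_tol=1e-9)


def _six_variant_fixture():
    return [
        make_snv(pos=1, pop_af={"dbSNP": 0.05}),                       # population
        make_snv(pos=2, af=0.05),                                      # AF floor
        make_snv(pos=3, af=0.50),                                      # het-like
        make_snv(pos=4, af=0.25),                                      # somatic-like
        make_snv(pos=5, af=0.30, vclass=VariantClass.SILENT),          # silent survives here
        make_snv(pos=6, af=0.30),                                      # clean missense
    ]


def test_apply_filters_hand_traced_composition():
    result = apply_filters(_six_variant_fixture())
    assert len(result.variants) == 3
    assert {v.pos for v in result.variants} == {4, 5, 6}
    assert result.counts == {"population_af": 1, "af_floor": 1, "likely_germline": 1}


def test_apply_filters_is_idempotent_and_counts_reconcile():
    variants = _six_variant_fixture()
    once = apply_filters(variants)
    twice = apply_filters(once.variants)
    assert twice.variants == once.variants
    assert sum(once.counts.values()) == len(variants) - len(once.variants)


def test_cnv_thresholds_strict():
    cnvs = [
        CopyNumberRecord("D1", "ERBB2", 2.5),   # not a gain (strict >)
        CopyNumberRecord("D1", "MYC", 2.6),
        CopyNumberRecord("D1", "SMAD4", 0.5),   # not a loss (strict <)
        CopyNumberRecord("D1", "PTEN", 0.4),
    ]
    result = apply_filters([], cnvs)
    assert [c.gene for c in result.cnv_gains] == ["MYC"]
    assert [c.gene for c in result.cnv_losses] == ["PTEN"]


def test_override_forces_labels():
    germline_like = make_snv(pos=3, af=0.50)
    overrides = {variant_key(germline_like): "somatic"}
    result = apply_filters([germline_like], overrides=overrides)
    assert result.variants == [germline_like]
    somatic_like = make_snv(pos=4, af=0.25)
    overrides = {variant_key(somatic_like): "likely_germline"}
    result = apply_filters([somatic_like], overrides=overrides)
    assert result.variants == []


def test_empty_input():
    result = apply_filters([])
    assert result.variants == [] and sum(result.counts.values()) == 0


@settings(max_examples=50, deadline=None)
@given(
    afs=st.lists(
        st.one_of(st.none(), st.floats(0.0, 1.0, allow_nan=False)),
        min_size=0, max_size=12,
    ),
    pop=st.lists(
        st.one_of(st.none(), st.floats(0.0, 0.2, allow_nan=False)),
        min_size=0, max_size=12,
    ),
)
def test_filter_partition_properties(afs, pop):
    """Partition exhaustive+disjoint; raising pop_af_max never shrinks kept set."""
    variants = [
        make_snv(pos=i + 1, af=af, pop_af={"dbSNP": p} if p is not None else None)
        for i, (af, p) in enumerate(zip(afs, pop))
    ]
    tight = FilterConfig(pop_af_max=0.01)
    loose = FilterConfig(pop_af_max=0.10)
    kept_t, dep_t = filter_population(variants, tight)
    assert len(kept_t) + len(dep_t) == len(variants)
    assert set(map(variant_key, kept_t)).isdisjoint(map(variant_key, dep_t))
    kept_l, _ = filter_population(variants, loose)
    assert set(map(variant_key, kept_t)) <= set(map(variant_key, kept_l))
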