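import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import fisher_two_tailed_enumeration, normal_approx_required_n
from conftest import make_snv
from crcpanel.association import (
    Cohort,
    ContingencyTable2x2,
    DichotomizationRules,
    benjamini_hochberg,
    cluster_associations,
    fisher_exact_2x2,
    fisher_power,
    gene_associations,
    pathway_alteration_summary,
    predict_required_n,
)
from crcpanel.io import ClinicalRecord, VariantClass


def test_balanced_table_p_one():
    p, odds = fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5))
    assert p == 1.0 and odds == 1.0


def test_perfect_separation_exact_p():
    p, odds = fisher_exact_2x2(ContingencyTable2x2(10, 0, 0, 10))
    assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)
    assert odds == float("inf")


def test_zero_margin_degenerate():
    p, odds = fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4))
    assert p == 1.0 and math.isnan(odds)


@settings(max_examples=200, deadline=None)
@given(
    a=st.integers(0, 15), b=st.integers(0, 15),
    c=st.integers(0, 15), d=st.integers(0, 15),
)
def test_fisher_matches_enumeration_and_scipy(a, b, c, d):
    if a + b + c + d == 0:
        return
    table = ContingencyTable2x2(a, b, c, d)
    p, _ = fisher_exact_2x2(table)
    assert p == pytest.approx(fisher_two_tailed_enumeration(a, b, c, d), abs=1e-9)
    from scipy.stats import fisher_exact as scipy_fisher
    if min(a + b, c + d, a + c, b + d) > 0:
        assert p == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], abs=1e-9)


def _clinical_fixture():
    records = []
    for i in range(30):
        records.append(ClinicalRecord(
            donor_id=f"D{i}",
            sex="M" if i % 2 else "F",
            site="colon",
            side="left" if i < 15 else "right",
            M="M1" if i < 10 else "M0",
            N="N1" if i % 3 == 0 else "N0",
            stage="IV" if i < 10 else "II",
        ))
    return records


def test_dichotomization_rules_and_missing():
    rules = DichotomizationRules()
    rec = ClinicalRecord(donor_id="x", grade="G3", T="T2", N=None)
    assert rules.is_aggressive(rec, "grade") is True
    assert rules.is_aggressive(rec, "T") is False
    assert rules.is_aggressive(rec, "N") is None


def test_cluster_associations_extreme_and_null():
    clinical = _clinical_fixture()
    labels = {f"D{i}": (1 if i < 10 else 2) for i in range(30)}
    results = cluster_associations(labels, clinical)
    by_key = {(r.unit, r.category): r for r in results}
    extreme = by_key[("1", "M")]  # cluster 1 all M1, cluster 2 all M0
    assert extreme.odds_ratio == float("inf")
    assert extreme.p_value == pytest.approx(
        fisher_two_tailed_enumeration(10, 0, 0, 20), abs=1e-12
    )
    null = by_key[("1", "site")]  # everyone colon -> zero margin
    assert null.p_value == 1.0


def test_cluster_associations_skips_empty_and_excludes_missing():
    clinical = _clinical_fixture()[:4]
    labels = {"D0": 1, "D1": 1, "D2": 2, "D3": 2, "GHOST": 3}
    results = cluster_associations(labels, clinical)
    assert all(r.unit != "3" for r in results)


def test_power_null_case_close_to_alpha():
    table = ContingencyTable2x2(10, 10, 10, 10)  # identical group probabilities
    est = fisher_power(table, n=80, alpha=0.05, n_sims=1000, seed=0)
    # Fisher is conservative; power should sit at or below alpha within 3 MC SE
    assert est.power <= 0.05 + 3 * max(est.mc_se, 0.007)


def test_power_large_effect_and_determinism():
    table = ContingencyTable2x2(18, 2, 2, 18)  # 0.9 vs 0.1
    est = fisher_power(table, n=100, alpha=0.05, n_sims=500, seed=1)
    assert est.power > 0.95
    again = fisher_power(table, n=100, alpha=0.05, n_sims=500, seed=1)
    assert est.power == again.power


def test_power_monotone_in_n():
    table = ContingencyTable2x2(12, 8, 6, 14)
    powers = [fisher_power(table, n, n_sims=400, seed=3).power
              for n in (40, 80, 120, 160, 200)]
    se = math.sqrt(0.25 / 400)
    assert all(b >= a - 2 * se for a, b in zip(powers, powers[1:]))


def test_predict_required_n_extremes():
    huge = ContingencyTable2x2(19, 1, 1, 19)
    res = predict_required_n(huge, n_grid=range(20, 101, 10), n_sims=300, seed=0)
    assert res.n_required == 20
    null = ContingencyTable2x2(10, 10, 10, 10)
    res = predict_required_n(null, n_grid=range(20, 101, 10), n_sims=300, seed=0)
    assert res.n_required is None


def test_predict_required_n_matches_normal_approximation():
    """Moderate effect: simulated Fisher requirement within one 10-donor grid
    step of the closed-form two-proportion approximation."""
    table = ContingencyTable2x2(15, 15, 6, 24)  # 0.5 vs 0.2, equal arms
    res = predict_required_n(table, n_sims=1000, seed=5)
    approx = normal_approx_required_n(0.5, 0.2, 0.5)
    grid_approx = 10 * math.ceil(approx / 10)
    assert res.n_required is not None
    assert abs(res.n_required - grid_approx) <= 10


def _gene_fixture():
    clinical = []
    profiles = {}
    for i in range(40):
        aggressive = i < 20
        clinical.append(ClinicalRecord(
            donor_id=f"D{i}",
            M="M1" if aggressive else "M0",
            N="N1" if aggressive else "N0",
        ))
        genes = set()
        if aggressive:
            genes.add("BADGENE")
        else:
            genes.add("GOODGENE")
        if i % 2:
            genes.add("NEUTRAL")
        profiles[f"D{i}"] = genes
    return profiles, clinical


def test_gene_associations_pseudonumbers_and_clustering():
    profiles, clinical = _gene_fixture()
    result = gene_associations(profiles, clinical)
    assert set(result.significant_genes) == {"BADGENE", "GOODGENE"}
    assert result.log_odds.loc["BADGENE", "M"] == 4.0     # +inf clamped
    assert result.log_odds.loc["GOODGENE", "M"] == -4.0   # -inf clamped
    assert np.isfinite(result.log_odds.to_numpy()).all()
    assert result.gene_clusters["BADGENE"] != result.gene_clusters["GOODGENE"]
    assert "NEUTRAL" not in result.significant_genes


def test_pathway_counts_unique_donors_and_fisher():
    pathways = {"WNT": ("APC", "RNF43"), "EMPTY": ("ZZZ",)}
    v1 = [make_snv(donor=f"A{i}", gene="APC", pos=i) for i in range(40)]
    v1 += [make_snv(donor="A0", gene="RNF43", pos=99)]  # same donor twice: counts once
    v2 = [make_snv(donor=f"B{i}", gene="APC", pos=i) for i in range(10)]
    cohorts = [
        Cohort("J", v1, [], [f"A{i}" for i in range(100)]),
        Cohort("US", v2, [], [f"B{i}" for i in range(100)]),
    ]
    summary, tests = pathway_alteration_summary(cohorts, pathways)
    j_wnt = summary[(summary.cohort == "J") & (summary.pathway == "WNT")].iloc[0]
    assert j_wnt["n_altered"] == 40
    wnt_p = tests[tests.pathway == "WNT"].iloc[0]["p_value"]
    assert wnt_p == pytest.approx(fisher_two_tailed_enumeration(40, 60, 10, 90), rel=1e-9)
    assert wnt_p < 0.001
    empty = tests[tests.pathway == "EMPTY"].iloc[0]
    assert empty["p_value"] == 1.0


def test_pathway_counts_idempotent_under_duplicates():
    pathways = {"WNT": ("APC",)}
    base = [make_snv(donor="A1", gene="APC")]
    cohorts_once = [
        Cohort("x", base, [], ["A1", "A2"]),
        Cohort("y", [], [], ["B1"]),
    ]
    cohorts_dup = [
        Cohort("x", base * 3, [], ["A1", "A2"]),
        Cohort("y", [], [], ["B1"]),
    ]
    s1, _ = pathway_alteration_summary(cohorts_once, pathways)
    s2, _ = pathway_alteration_summary(cohorts_dup, pathways)
    assert s1.equals(s2)


def test_benjamini_hochberg_monotone():
    p = [0.001, 0.01, 0.02, 0.8]
    adj = benjamini_hochberg(p)
    assert (np.diff(adj[np.argsort(p)]) >= 0).all()
    assert (adj >= p).all()
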