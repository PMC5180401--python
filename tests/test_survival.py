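import numpy as np
import pytest

from crcpanel.io import ClinicalRecord, SurvivalRecord
from crcpanel.survival import (
    filter_stage4_chain,
    km_estimate,
    logrank_test,
    waterfall_data,
)


def test_km_all_censored_stays_at_one():
    curve = km_estimate([5, 8, 12], [False, False, False])
    assert (curve.survival == 1.0).all()
    assert curve.n_events == 0


def test_km_no_censoring_equals_empirical_survival():
    curve = km_estimate([1, 2, 3], [True, True, True])
    assert curve.survival_at(1) == pytest.approx(2 / 3)
    assert curve.survival_at(2) == pytest.approx(1 / 3)
    assert curve.survival_at(3) == pytest.approx(0.0)


def test_km_textbook_interleaved_censoring():
    # events at 1 and 3; censored at 2, 4, 5, 6
    times = [1, 2, 3, 4, 5, 6]
    events = [True, False, True, False, False, False]
    curve = km_estimate(times, events)
    assert curve.survival_at(1) == pytest.approx(5 / 6)
    assert curve.survival_at(3) == pytest.approx(5 / 6 * 3 / 4)
    assert (np.diff(curve.survival) <= 0).all()
    with pytest.raises(ValueError):
        km_estimate([], [])


def test_logrank_identical_groups():
    times = [3.0, 5.0, 7.0, 9.0]
    events = [True, True, False, True]
    result = logrank_test({"a": (times, events), "b": (times, events)})
    assert result.statistic == pytest.approx(0.0, abs=1e-12)
    assert result.p_value == pytest.approx(1.0)
    assert result.df == 1
    with pytest.raises(ValueError):
        logrank_test({"a": (times, events)})


def test_logrank_invariant_to_relabeling_and_time_rescaling(rng):
    g1 = (list(rng.exponential(100, 20)), list(rng.random(20) < 0.8))
    g2 = (list(rng.exponential(300, 20)), list(rng.random(20) < 0.8))
    base = logrank_test({"a": g1, "b": g2})
    swapped = logrank_test({"b": g2, "a": g1})
    assert base.statistic == pytest.approx(swapped.statistic)
    scaled = logrank_test({
        "a": ([t * 7.0 for t in g1[0]], g1[1]),
        "b": ([t * 7.0 for t in g2[0]], g2[1]),
    })
    assert base.statistic == pytest.approx(scaled.statistic)


def test_logrank_detects_planted_hazard_ratio(rng):
    hits = 0
    for _ in range(20):
        g1 = (list(rng.exponential(300, 50)), [True] * 50)
        g2 = (list(rng.exponential(100, 50)), [True] * 50)
        if logrank_test({"slow": g1, "fast": g2}).p_value < 0.05:
            hits += 1
    assert hits >= 18  # hazard ratio 3, n=50/arm: high power


def _chain_fixture():
    """Stage-IV cohort engineered to the 46 -> 39 -> 33 exclusion arithmetic."""
    survival, clinical, labels = [], [], {}
    idx = 0

    def add(n, stage="IV", anti_egfr=True, resection=False, early=False, cluster=1):
        nonlocal idx
        for _ in range(n):
            donor = f"S{idx:03d}"
            survival.append(SurvivalRecord(
                donor_id=donor, pfs_days=100 + idx, event=True,
                anti_egfr=anti_egfr, surgical_resection=resection,
                progressed_before_first_assessment=early,
                best_response_pct=None if early else -10.0 - idx,
            ))
            clinical.append(ClinicalRecord(donor_id=donor, stage=stage))
            labels[donor] = cluster
            idx += 1

    add(30, cluster=1)                      # clean anti-EGFR donors
    add(7, resection=True, cluster=1)       # excluded: surgical resection
    add(6, early=True, cluster=2)           # excluded from waterfall
    add(3, cluster=3)                       # will be singleton-cluster donors
    labels[survival[-1].donor_id] = 5
    labels[survival[-2].donor_id] = 6
    labels[survival[-3].donor_id] = 7
    add(58, stage="III", cluster=1)         # non-stage-IV background
    add(10, anti_egfr=False, cluster=1)     # stage IV, never on anti-EGFR
    return survival, clinical, labels


def test_exclusion_chain_arithmetic():
    survival, clinical, labels = _chain_fixture()
    sets = filter_stage4_chain(survival, clinical, labels)
    assert sets.trace.counts() == [46, 39, 36, 33]
    assert len(sets.pfs_set) == 39
    assert len(sets.km_set) == 36  # three singleton-cluster donors dropped
    assert len(sets.waterfall_set) == 33


def test_chain_no_exclusions_identity():
    survival = [SurvivalRecord(donor_id="a", pfs_days=10, event=True, anti_egfr=True)]
    clinical = [ClinicalRecord(donor_id="a", stage="IV")]
    sets = filter_stage4_chain(survival, clinical)
    assert sets.pfs_set == survival and sets.waterfall_set == survival


def test_chain_double_failure_excluded_once():
    rec = SurvivalRecord(
        donor_id="a", pfs_days=10, event=True, anti_egfr=True,
        surgical_resection=True, progressed_before_first_assessment=True,
    )
    clinical = [ClinicalRecord(donor_id="a", stage="IV")]
    sets = filter_stage4_chain([rec], clinical)
    # fails resection first; never reaches the early-progression step
    assert sets.trace.counts() == [1, 0, 0]
    assert sets.pfs_set == [] and sets.waterfall_set == []


def test_waterfall_sorted_with_ties_and_missing():
    responses = {"d1": 10.0, "d2": -30.0, "d3": -80.0, "d4": 10.0, "d5": None}
    df = waterfall_data(responses, labels={"d1": 1, "d2": 2, "d3": 1, "d4": 2})
    assert list(df["best_response_pct"]) == [10.0, 10.0, -30.0, -80.0]
    assert list(df["donor_id"][:2]) == ["d1", "d4"]  # stable tie order by id
    assert "d5" not in set(df["donor_id"])
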