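"""Stage-IV outcome analysis: cohort exclusion chain, Kaplan-Meier
estimation, log-rank comparison, and waterfall-plot data.

Progression-free survival is the interval from diagnosis of metastatic
disease to documented progression, right-censored at last follow-up.
Kaplan-Meier estimation and the asymptotic chi-square log-rank test are
delegated to lifelines; a label-permutation variant of the log-rank test is
available for very small groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .io import ClinicalRecord, SurvivalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "km_estimate",
    "logrank_test",
    "LogrankResult",
    "CohortFilterTrace",
    "filter_stage4_chain",
    "StageIVSets",
    "waterfall_data",
]


@dataclass
class KMCurve:
    """Product-limit survival curve."""

    times: np.ndarray      # event times (increasing), starting at 0
    survival: np.ndarray   # S(t) at each time, starts at 1, nonincreasing
    at_risk: np.ndarray    # risk-set size just before each time
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored donors leave the risk set without a survival step.  Without
    censoring the curve equals one minus the empirical CDF.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("empty survival input")
    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    table = fitter.event_table
    grid = table.index.to_numpy(dtype=float)
    surv = fitter.survival_function_["KM_estimate"].to_numpy()
    at_risk = table["at_risk"].to_numpy()
    if grid[0] != 0.0:
        grid = np.insert(grid, 0, 0.0)
        surv = np.insert(surv, 0, 1.0)
        at_risk = np.insert(at_risk, 0, len(times))
    return KMCurve(grid, surv, at_risk, int(events.sum()))


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(
    groups: Mapping[str, tuple[Sequence[float], Sequence[bool]]],
    permutation: bool = False,
    n_permutations: int = 2000,
    seed: int = 0,
) -> LogrankResult:
    """Log-rank comparison of two or more survival groups.

    Default p value is from the asymptotic chi-square with (groups - 1)
    degrees of freedom.  ``permutation=True`` instead permutes group labels
    (recommended only for tiny groups).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for name, (ts, evs) in groups.items():
        times.extend(float(t) for t in ts)
        events.extend(bool(e) for e in evs)
        labels.extend([name] * len(list(ts)))
    times = np.asarray(times)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    result = multivariate_logrank_test(times, labels, events)
    stat = float(result.test_statistic)
    df = len(groups) - 1
    if not permutation:
        return LogrankResult(stat, df, float(result.p_value))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        perm_stat = float(multivariate_logrank_test(times, perm, events).test_statistic)
        hits += perm_stat >= stat
    return LogrankResult(stat, df, (hits + 1) / (n_permutations + 1))


@dataclass
class CohortFilterTrace:
    """Counts (strictly nonincreasing) at each exclusion step, with reasons."""

    steps: list[tuple[str, int]]

    def counts(self) -> list[int]:
        return [n for _, n in self.steps]


@dataclass
class StageIVSets:
    pfs_set: list[SurvivalRecord]
    waterfall_set: list[SurvivalRecord]
    km_set: list[SurvivalRecord]
    trace: CohortFilterTrace


def filter_stage4_chain(
    survival: Sequence[SurvivalRecord],
    clinical: Sequence[ClinicalRecord],
    labels: Mapping[str, int | str] | None = None,
) -> StageIVSets:
    """Apply the Stage-IV anti-EGFR exclusion chain and record every step.

    Chain: Stage IV donors on anti-EGFR therapy -> drop surgical resections
    (the PFS analysis set) -> drop donors progressing before the first
    response assessment (the waterfall set).  The Kaplan-Meier set starts
    from the PFS set and additionally drops donors who are the only member
    of their cluster (no group to compare).  A donor failing several
    criteria is excluded once, under the first matching reason.
    """
    stage = {c.donor_id: c.stage for c in clinical}
    stage4 = [r for r in survival if stage.get(r.donor_id) == "IV"]
    treated = [r for r in stage4 if r.anti_egfr]
    steps = [("stage IV on anti-EGFR therapy", len(treated))]
    pfs_set = [r for r in treated if not r.surgical_resection]
    steps.append(("excluding surgical resection (PFS set)", len(pfs_set)))
    km_set = list(pfs_set)
    if labels is not None:
        sizes: dict[object, int] = {}
        for r in pfs_set:
            if r.donor_id in labels:
                sizes[labels[r.donor_id]] = sizes.get(labels[r.donor_id], 0) + 1
        km_set = [
            r for r in pfs_set
            if r.donor_id in labels and sizes[labels[r.donor_id]] > 1
        ]
        steps.append(("excluding singleton-cluster donors (KM set)", len(km_set)))
    waterfall_set = [r for r in pfs_set if not r.progressed_before_first_assessment]
    steps.append(
        ("excluding progression before first assessment (waterfall set)", len(waterfall_set))
    )
    trace = CohortFilterTrace(steps)
    # every derived set shrinks its parent: treated >= pfs >= km, waterfall
    assert len(treated) >= len(pfs_set) >= max(len(km_set), len(waterfall_set))
    return StageIVSets(pfs_set, waterfall_set, km_set, trace)


def waterfall_data(
    responses: Mapping[str, float | None],
    labels: Mapping[str, int | str] | None = None,
) -> pd.DataFrame:
    """Donors sorted by best response (descending), with cluster annotation.

    Pure sort + join; response percentages are inputs, not computed here.
    Donors without an assessed best response are excluded with a warning;
    ties keep a stable order by donor id.
    """
    rows = []
    for donor in sorted(responses):
        value = responses[donor]
        if value is None:
            logger.warning("donor %s has no best-response assessment; excluded", donor)
            continue
        rows.append({
            "donor_id": donor,
            "best_response_pct": float(value),
            "cluster": labels.get(donor) if labels else None,
        })
    df = pd.DataFrame(rows, columns=["donor_id", "best_response_pct", "cluster"])
    return df.sort_values(
        by=["best_response_pct", "donor_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
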