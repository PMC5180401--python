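"""Independent reference implementations used only to validate the package.

These deliberately share no code with the implementation: exact integer
arithmetic for the Fisher test, a dictionary-based naive agglomeration for
the Lance-Williams recurrences, and plain-loop recomputations of the
clustering-stability indices.
"""

from __future__ import annotations

from math import comb, sqrt

import numpy as np


def fisher_two_tailed_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher p by exhaustive enumeration with integer weights.

    With margins fixed, table probabilities are proportional to the integer
    C(r1, k) * C(r2, c1 - k); the two-tailed p sums every table whose weight
    is <= the observed table's.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    numerator = sum(w for w in weights.values() if w <= w_obs)
    return numerator / comb(n, c1)


# ---------------------------------------------------------------------------
# Naive agglomeration (dictionary of frozensets, O(n^3))
# ---------------------------------------------------------------------------

def _lw_update(method, d_iv, d_jv, d_ij, ni, nj, nv):
    if method == "single":
        return min(d_iv, d_jv)
    if method == "complete":
        return max(d_iv, d_jv)
    if method == "average":
        return (ni * d_iv + nj * d_jv) / (ni + nj)
    if method == "mcquitty":
        return (d_iv + d_jv) / 2.0
    if method == "median":
        return d_iv / 2.0 + d_jv / 2.0 - d_ij / 4.0
    if method == "centroid":
        s = ni + nj
        return (ni * d_iv + nj * d_jv) / s - (ni * nj * d_ij) / (s * s)
    if method in ("ward.D", "ward.D2"):
        s = ni + nj + nv
        return ((ni + nv) * d_iv + (nj + nv) * d_jv - nv * d_ij) / s
    raise ValueError(method)


def naive_agglomerate(D: np.ndarray, method: str):
    """Reference agglomeration: returns (merge list, partitions per cut level).

    merge list entries are (left representative, right representative,
    height); partitions[k] is a list of frozensets for the k-cluster cut.
    Ties in the minimum distance break on the smallest (left, right)
    representative pair; ward.D2 squares the input and reports square-root
    heights.
    """
    n = D.shape[0]
    squared = method == "ward.D2"
    clusters: dict[frozenset, int] = {frozenset([i]): 1 for i in range(n)}
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            v = float(D[i, j])
            dist[frozenset([frozenset([i]), frozenset([j])])] = v * v if squared else v
    merges = []
    partitions = {n: [frozenset([i]) for i in range(n)]}
    members = list(clusters)
    while len(members) > 1:
        best = None
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                ca, cb = members[x], members[y]
                d = dist[frozenset([ca, cb])]
                key = (d,) + tuple(sorted((min(ca), min(cb))))
                if best is None or key < best[0]:
                    best = (key, ca, cb)
        (d, left, right), ca, cb = best
        if min(cb) < min(ca):
            ca, cb = cb, ca
        merged = ca | cb
        merges.append((min(ca), min(cb), sqrt(d) if squared else d))
        ni, nj = clusters[ca], clusters[cb]
        new_members = [m for m in members if m not in (ca, cb)]
        for cv in new_members:
            newd = _lw_update(
                method,
                dist[frozenset([ca, cv])],
                dist[frozenset([cb, cv])],
                d,
                ni,
                nj,
                clusters[cv],
            )
            dist[frozenset([merged, cv])] = newd
        clusters[merged] = ni + nj
        members = new_members + [merged]
        partitions[len(members)] = list(members)
    return merges, partitions


# ---------------------------------------------------------------------------
# Stability indices by definition (plain loops)
# ---------------------------------------------------------------------------

def stability_by_definition(X, cluster_fn, metric_fn, k):
    """APN/AD/ADM/FOM recomputed step by step from their definitions.

    ``cluster_fn(data) -> labels`` and ``metric_fn(x, y) -> float`` are
    supplied by the caller so this stays independent of the implementation's
    internals.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    full = cluster_fn(X)
    apn_terms, ad_terms, adm_terms, fom_cols = [], [], [], []
    for col in range(m):
        Xd = np.delete(X, col, axis=1)
        dele = cluster_fn(Xd)
        for i in range(n):
            set_full = [j for j in range(n) if full[j] == full[i]]
            set_dele = [j for j in range(n) if dele[j] == dele[i]]
            inter = len(set(set_full) & set(set_dele))
            apn_terms.append(1.0 - inter / len(set_full))
            total = 0.0
            for x in set_full:
                for y in set_dele:
                    total += metric_fn(X[x], X[y])
            ad_terms.append(total / (len(set_full) * len(set_dele)))
            mean_full = X[set_full].mean(axis=0)
            mean_dele = X[set_dele].mean(axis=0)
            adm_terms.append(sqrt(float(((mean_full - mean_dele) ** 2).sum())))
        ss = 0.0
        for cluster in set(dele):
            idx = [j for j in range(n) if dele[j] == cluster]
            mu = X[idx, col].mean()
            for j in idx:
                ss += (X[j, col] - mu) ** 2
        fom_cols.append(sqrt(ss / n) * sqrt(n / (n - k)))
    return (
        float(np.mean(apn_terms)),
        float(np.mean(ad_terms)),
        float(np.mean(adm_terms)),
        float(np.mean(fom_cols)),
    )


def normal_approx_required_n(p1: float, p2: float, frac1: float,
                             alpha: float = 0.05, power: float = 0.8) -> float:
    """Two-proportion normal-approximation total sample size for given power."""
    from scipy.stats import norm

    z_a = norm.ppf(1 - alpha / 2)
    z_b = norm.ppf(power)
    pbar = frac1 * p1 + (1 - frac1) * p2
    # per-"unit" variance with allocation frac1 : 1-frac1
    se0 = sqrt(pbar * (1 - pbar) * (1 / frac1 + 1 / (1 - frac1)))
    se1 = sqrt(p1 * (1 - p1) / frac1 + p2 * (1 - p2) / (1 - frac1))
    return ((z_a * se0 + z_b * se1) / abs(p1 - p2)) ** 2
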