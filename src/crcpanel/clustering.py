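"""Donor-similarity construction, hierarchical clustering, and stability-based
model selection.

Donor similarity: with ``c_ij`` the number of mutated genes shared by donors
i and j (after merging KRAS/NRAS into RAS), each matrix entry is
``1 / (c_ij + 1)`` — a value in (0, 1], equal to 1 exactly when the pair
shares no mutated gene.  The clustered objects are the ROWS of this matrix
(each donor's similarity profile is its feature vector).

Agglomeration uses Lance-Williams updates with the standard coefficient set
for the eight linkage dialects (ward.D applies the Ward coefficients to the
input dissimilarities; ward.D2 to their squares, reporting square-root
heights).  Ties in the minimum merge distance break deterministically on the
lowest (left, right) representative pair — dendrograms are therefore
reproducible, though not bit-identical to other implementations' internal
orderings.

Stability is scored by the delete-one-column protocol (APN, AD, ADM, FOM;
lower = more stable) and model selection ranks every
(distance, linkage, k) combination by rank-sum over the four indices,
breaking ties by the number of clusters with more than five donors, then by
smaller k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import distance as _ssd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "SimilarityMatrix",
    "ClusteringResult",
    "StabilityScores",
    "build_similarity",
    "pairwise_distance",
    "hierarchical_cluster",
    "stability_scores",
    "model_select",
    "ModelSelection",
    "annotate_therapy",
    "DEFAULT_THERAPY_MAP",
    "DISTANCES",
    "LINKAGES",
]

DISTANCES = ("euclidean", "maximum", "manhattan", "canberra", "minkowski")
LINKAGES = ("ward.D", "ward.D2", "single", "complete", "average", "mcquitty",
            "median", "centroid")

_SCIPY_METRIC = {
    "euclidean": "euclidean",
    "maximum": "chebyshev",
    "manhattan": "cityblock",
    "canberra": "canberra",
    "minkowski": "minkowski",
}


@dataclass(frozen=True)
class GeneSet:
    """An ordered gene list with a symbol-merge map (default folds KRAS and
    NRAS into the single symbol RAS)."""

    name: str
    genes: tuple[str, ...]
    merge_map: Mapping[str, str] = field(
        default_factory=lambda: {"KRAS": "RAS", "NRAS": "RAS"}
    )

    def merged_genes(self) -> tuple[str, ...]:
        out: list[str] = []
        for g in self.genes:
            m = self.merge_map.get(g, g)
            if m not in out:
                out.append(m)
        return tuple(out)

    def apply(self, genes: set[str]) -> set[str]:
        """Merge symbols and restrict a donor's mutated-gene set to this set."""
        merged = {self.merge_map.get(g, g) for g in genes}
        return merged & set(self.merged_genes())


@dataclass
class SimilarityMatrix:
    donors: list[str]
    values: np.ndarray  # N x N, entries 1/(c_ij + 1) in (0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.donors)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be N x N")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.donors, columns=self.donors)


def build_similarity(
    profiles: Mapping[str, set[str]], gene_set: GeneSet
) -> SimilarityMatrix:
    """Donor-by-donor similarity 1/(c_ij + 1) from mutated-gene profiles.

    ``c_ij`` counts shared mutated genes within the gene set after the merge
    map is applied; the diagonal uses ``c_ii = |genes(i)|``.
    """
    donors = list(profiles)
    if not donors:
        raise ValueError("no donors supplied")
    restricted = [gene_set.apply(set(profiles[d])) for d in donors]
    n = len(donors)
    values = np.empty((n, n))
    for i in range(n):
        values[i, i] = 1.0 / (len(restricted[i]) + 1)
        for j in range(i + 1, n):
            c = len(restricted[i] & restricted[j])
            values[i, j] = values[j, i] = 1.0 / (c + 1)
    return SimilarityMatrix(donors, values)


def pairwise_distance(
    rows: np.ndarray, method: str = "euclidean", p: float = 2.0
) -> np.ndarray:
    """N x N distance matrix between row vectors.

    Methods mirror the common R dialect: euclidean, maximum (Chebyshev),
    manhattan, canberra (0/0 terms contribute 0), minkowski (default
    exponent p=2, which duplicates euclidean).
    """
    if method not in _SCIPY_METRIC:
        raise ValueError(f"unknown distance {method!r}; choose from {DISTANCES}")
    rows = np.asarray(rows, dtype=float)
    kwargs = {"p": p} if method == "minkowski" else {}
    return _ssd.squareform(_ssd.pdist(rows, metric=_SCIPY_METRIC[method], **kwargs))


@dataclass
class ClusteringResult:
    labels: np.ndarray            # length N, cluster ids 1..k
    merge_history: list[tuple[int, int, float]]  # (left rep, right rep, height)
    params: tuple[str, str, int]  # (distance, linkage, k)
    donors: list[str] | None = None

    def labels_by_donor(self) -> dict[str, int]:
        if self.donors is None:
            raise ValueError("no donor names attached")
        return {d: int(l) for d, l in zip(self.donors, self.labels)}

    def cluster_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


def _lw_coefficients(linkage: str, ni: int, nj: int, nv: int):
    """Lance-Williams (alpha_i, alpha_j, beta, gamma) for merging i+j vs v."""
    if linkage == "single":
        return 0.5, 0.5, 0.0, -0.5
    if linkage == "complete":
        return 0.5, 0.5, 0.0, 0.5
    if linkage == "average":
        return ni / (ni + nj), nj / (ni + nj), 0.0, 0.0
    if linkage == "mcquitty":
        return 0.5, 0.5, 0.0, 0.0
    if linkage == "median":
        return 0.5, 0.5, -0.25, 0.0
    if linkage == "centroid":
        s = ni + nj
        return ni / s, nj / s, -(ni * nj) / (s * s), 0.0
    if linkage in ("ward.D", "ward.D2"):
        s = ni + nj + nv
        return (ni + nv) / s, (nj + nv) / s, -nv / s, 0.0
    raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")


def hierarchical_cluster(
    dist: np.ndarray, linkage: str, k: int, donors: Sequence[str] | None = None,
    distance_name: str = "euclidean",
) -> ClusteringResult:
    """Agglomerative clustering of a distance matrix, cut at k clusters.

    ward.D runs the Ward update on the dissimilarities as given; ward.D2 on
    their squares (heights reported on the original scale).  Ties in the
    minimum merge distance break on the lowest (left, right) pair of cluster
    representatives (a cluster's representative is its smallest original
    row index).
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside [2, {n}]")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")

    squared = linkage == "ward.D2"
    work = D.astype(float) ** 2 if squared else D.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    # the merged cluster always lands on the lower row index, so a cluster's
    # row index IS its representative (smallest original member); row-major
    # argmin over the upper triangle then realizes the (left, right) tie-break
    tril = np.tril_indices(n)
    size = np.ones(n, dtype=float)
    alive = np.ones(n, dtype=bool)
    merges: list[tuple[int, int, float]] = []
    merge_members: list[tuple[int, int]] = []  # (row kept, row absorbed)
    ward = linkage in ("ward.D", "ward.D2")

    for _ in range(n - 1):
        M = work.copy()
        M[tril] = np.inf
        a, b = divmod(int(np.argmin(M)), n)
        d = work[a, b]
        height = float(np.sqrt(d)) if squared else float(d)
        merges.append((a, b, height))
        merge_members.append((a, b))
        ni, nj = size[a], size[b]
        others = alive.copy()
        others[a] = others[b] = False
        row_a, row_b = work[a, others], work[b, others]
        if ward:
            s = ni + nj + size[others]
            new_vals = ((ni + size[others]) * row_a + (nj + size[others]) * row_b
                        - size[others] * d) / s
        else:
            ai, aj, beta, gamma = _lw_coefficients(linkage, int(ni), int(nj), 1)
            new_vals = ai * row_a + aj * row_b + beta * d + gamma * np.abs(row_a - row_b)
        new_row = np.full(n, np.inf)
        new_row[others] = new_vals
        work[a, :] = new_row
        work[:, a] = new_row
        work[b, :] = np.inf
        work[:, b] = np.inf
        size[a] = ni + nj
        alive[b] = False

    # cut: apply the first n-k merges with union-find over original indices
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in merge_members[: n - k]:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    labels = np.zeros(n, dtype=int)
    next_id = 0
    seen: dict[int, int] = {}
    for i in range(n):
        root = find(i)
        if root not in seen:
            next_id += 1
            seen[root] = next_id
        labels[i] = seen[root]
    return ClusteringResult(
        labels=labels,
        merge_history=merges,
        params=(distance_name, linkage, k),
        donors=list(donors) if donors is not None else None,
    )


# ---------------------------------------------------------------------------
# Stability (delete-one-column protocol)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityScores:
    apn: float
    ad: float
    adm: float
    fom: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.apn <= 1.0 + 1e-12:
            raise ValueError("APN must lie in [0, 1]")


def _cluster_rows(
    X: np.ndarray, distance: str, linkage: str, k: int, p: float
) -> np.ndarray:
    return hierarchical_cluster(
        pairwise_distance(X, distance, p=p), linkage, k, distance_name=distance
    ).labels


def stability_scores(
    X: np.ndarray, distance: str, linkage: str, k: int, p: float = 2.0
) -> StabilityScores:
    """APN / AD / ADM / FOM for one (distance, linkage, k) setting.

    For each feature column removed in turn, the data are reclustered and
    compared to the full-data clustering:

    - APN: average proportion of each observation's full-data cluster that it
      no longer shares a cluster with after the deletion (0 = perfectly
      stable);
    - AD: average distance (chosen metric, full data) between the observation's
      full-data cluster and its deleted-column cluster;
    - ADM: average Euclidean distance between the full-data centroids of those
      two clusters;
    - FOM: root mean intra-cluster variance of the removed column under the
      deleted-column clustering, with the sqrt(n/(n-k)) adjustment.

    Lower values mean higher stability.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("need at least 2 feature columns")
    full = _cluster_rows(X, distance, linkage, k, p)
    D_full = pairwise_distance(X, distance, p=p)
    full_ids, full_inv = np.unique(full, return_inverse=True)
    members_full = [np.flatnonzero(full_inv == c) for c in range(len(full_ids))]
    cent_full = np.vstack([X[idx].mean(axis=0) for idx in members_full])

    apn_sum = ad_sum = adm_sum = 0.0
    fom_vals = []
    for col in range(m):
        Xd = np.delete(X, col, axis=1)
        deleted = _cluster_rows(Xd, distance, linkage, k, p)
        del_ids, del_inv = np.unique(deleted, return_inverse=True)
        members_del = [np.flatnonzero(del_inv == c) for c in range(len(del_ids))]
        cent_del = np.vstack([X[idx].mean(axis=0) for idx in members_del])
        # contingency N[c, c'] = donors in full cluster c and deleted cluster c'
        N = np.zeros((len(full_ids), len(del_ids)))
        np.add.at(N, (full_inv, del_inv), 1.0)
        full_sizes = N.sum(axis=1)
        apn_sum += float((N * (1.0 - N / full_sizes[:, None])).sum())
        mean_d = np.array([
            [D_full[np.ix_(cf, cd)].mean() for cd in members_del]
            for cf in members_full
        ])
        ad_sum += float((N * mean_d).sum())
        cent_dist = np.sqrt(
            ((cent_full[:, None, :] - cent_del[None, :, :]) ** 2).sum(axis=2)
        )
        adm_sum += float((N * cent_dist).sum())
        col_means = np.array([X[idx, col].mean() for idx in members_del])
        sq = float(((X[:, col] - col_means[del_inv]) ** 2).sum())
        fom_vals.append(np.sqrt(sq / n) * np.sqrt(n / (n - k)))
    denom = n * m
    return StabilityScores(
        apn=apn_sum / denom,
        ad=ad_sum / denom,
        adm=adm_sum / denom,
        fom=float(np.mean(fom_vals)),
    )


@dataclass
class ModelSelection:
    selected: tuple[str, str, int]   # (distance, linkage, k)
    grid: pd.DataFrame               # distance, linkage, k, apn, ad, adm, fom, rank_sum
    per_index_best: dict[str, tuple[str, str, int]]


def model_select(
    X: np.ndarray,
    k_range: Sequence[int],
    distances: Sequence[str] = DISTANCES,
    linkages: Sequence[str] = LINKAGES,
    p: float = 2.0,
    min_cluster_size: int = 5,
) -> ModelSelection:
    """Grid-evaluate clustering stability and pick the most stable setting.

    Every (distance, linkage, k) combination is scored with
    :func:`stability_scores`.  The candidate set is the argmin setting of
    each of the four indices (ties resolved toward more clusters with more
    than ``min_cluster_size`` donors, then smaller k).  Candidates are then
    ordered by rank-sum of the four indices within the candidate set; the
    winner is the lowest rank-sum, with the same tie-breaks.  This mirrors
    the practice of extracting each stability index's best setting and
    choosing the consensus among them: AD and FOM decrease almost
    monotonically with k, so a whole-grid rank-sum would systematically
    drift to the largest k, whereas the per-index extraction lets the
    non-overlap indices (APN, ADM) veto unstable over-splits.
    """
    X = np.asarray(X, dtype=float)
    if len(k_range) == 0 or len(distances) == 0 or len(linkages) == 0:
        raise ValueError("empty model-selection grid")
    if np.allclose(X, X[0], atol=1e-12):
        raise ValueError("no structure: all rows identical")
    rows = []
    for dist_name in distances:
        for linkage in linkages:
            for k in k_range:
                scores = stability_scores(X, dist_name, linkage, k, p=p)
                full = _cluster_rows(X, dist_name, linkage, k, p)
                _, counts = np.unique(full, return_counts=True)
                rows.append({
                    "distance": dist_name, "linkage": linkage, "k": k,
                    "apn": scores.apn, "ad": scores.ad,
                    "adm": scores.adm, "fom": scores.fom,
                    "n_big_clusters": int((counts > min_cluster_size).sum()),
                })
    grid = pd.DataFrame(rows)
    from scipy.stats import rankdata

    indices = ("apn", "ad", "adm", "fom")
    per_index_best = {}
    candidate_rows = []
    for index in indices:
        row = grid.sort_values(
            by=[index, "n_big_clusters", "k"], ascending=[True, False, True],
            kind="mergesort",
        ).index[0]
        candidate_rows.append(row)
        r = grid.loc[row]
        per_index_best[index] = (r["distance"], r["linkage"], int(r["k"]))
    candidates = grid.loc[sorted(set(candidate_rows))].copy()
    rank_sum = np.zeros(len(candidates))
    for index in indices:
        rank_sum += rankdata(candidates[index].to_numpy(), method="average")
    candidates["rank_sum"] = rank_sum
    grid = grid.merge(
        candidates[["distance", "linkage", "k", "rank_sum"]],
        on=["distance", "linkage", "k"], how="left",
    )
    best = candidates.sort_values(
        by=["rank_sum", "n_big_clusters", "k"],
        ascending=[True, False, True],
        kind="mergesort",
    ).iloc[0]
    return ModelSelection(
        selected=(best["distance"], best["linkage"], int(best["k"])),
        grid=grid,
        per_index_best=per_index_best,
    )


# ---------------------------------------------------------------------------
# Cluster -> therapy annotation
# ---------------------------------------------------------------------------

#: driver tag -> recommended therapy (editable; defaults mirror the standard
#: actionable-CRC playbook: all-wild-type tumors get anti-EGFR antibodies,
#: RAS-mutant tumors chemotherapy + Bevacizumab, driver-defined clusters a
#: matched agent, hypermutated tumors checkpoint blockade)
DEFAULT_THERAPY_MAP = {
    "all_wt": "anti-EGFR (Cetuximab/Panitumumab)",
    "RAS": "chemotherapy + Bevacizumab",
    "BRAF": "BRAF/MEK inhibitor combination",
    "RNF43": "anti-EGFR + BRAF/MEK inhibitor combination",
    "ERBB2": "anti-HER2 (Trastuzumab) combination",
    "PIK3CA": "PI3K-pathway inhibitor combination",
    "PTEN": "PI3K/AKT-pathway inhibitor combination",
    "hypermutated": "immune checkpoint inhibitor",
}


def annotate_therapy(
    labels: Mapping[str, int | str],
    cluster_driver_map: Mapping[int | str, str],
    therapy_map: Mapping[str, str] = DEFAULT_THERAPY_MAP,
) -> dict[str, str]:
    """Map donors to therapy recommendations via their cluster's driver tag.

    ``cluster_driver_map`` maps cluster id -> driver tag (a key of
    ``therapy_map``).  Clusters without a mapping yield ``"unclassified"``
    with a warning.
    """
    out = {}
    warned: set = set()
    for donor, cluster in labels.items():
        driver = cluster_driver_map.get(cluster)
        therapy = therapy_map.get(driver) if driver is not None else None
        if therapy is None:
            if cluster not in warned:
                logger.warning("cluster %r has no therapy mapping", cluster)
                warned.add(cluster)
            therapy = "unclassified"
        out[donor] = therapy
    return out
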