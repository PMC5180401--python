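import numpy as np
import pytest

from _oracles import naive_agglomerate, stability_by_definition
from crcpanel.clustering import (
    DEFAULT_THERAPY_MAP,
    DISTANCES,
    LINKAGES,
    GeneSet,
    annotate_therapy,
    build_similarity,
    hierarchical_cluster,
    model_select,
    pairwise_distance,
    stability_scores,
)
from crcpanel.simulate import planted_cluster_profiles


def _partition_from_labels(labels):
    groups = {}
    for i, l in enumerate(labels):
        groups.setdefault(l, set()).add(i)
    return {frozenset(g) for g in groups.values()}


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def test_similarity_values_from_shared_gene_counts():
    gs = GeneSet("g", ("RAS", "TP53", "APC", "PTEN"))
    profiles = {
        "a": {"KRAS", "TP53", "APC"},
        "b": {"NRAS"},            # merges to RAS: shares RAS with a
        "c": {"PTEN"},            # shares nothing with a
        "d": {"KRAS", "TP53", "APC"},
    }
    sim = build_similarity(profiles, gs)
    i = {d: k for k, d in enumerate(sim.donors)}
    assert sim.values[i["a"], i["c"]] == 1.0          # 0 shared
    assert sim.values[i["a"], i["b"]] == 0.5          # KRAS/NRAS -> RAS
    assert sim.values[i["a"], i["d"]] == 0.25         # 3 shared
    assert sim.values[i["a"], i["a"]] == 1.0 / 4.0    # diagonal: |genes|=3 -> 1/4


def test_similarity_invariant_under_donor_reordering(rng):
    profiles, _ = planted_cluster_profiles(1)
    gs = GeneSet("g", tuple(sorted({g for s in profiles.values() for g in s})))
    sim = build_similarity(profiles, gs)
    order = list(profiles)
    rng.shuffle(order)
    shuffled = build_similarity({d: profiles[d] for d in order}, gs)
    perm = [shuffled.donors.index(d) for d in sim.donors]
    np.testing.assert_allclose(sim.values, shuffled.values[np.ix_(perm, perm)])


def test_similarity_strictly_decreases_with_shared_genes():
    gs = GeneSet("g", ("A", "B", "C", "D"), merge_map={})
    for c in range(4):
        shared = set(list("ABCD")[:c])
        sim = build_similarity({"x": shared | {"A"} if c else set(), "y": shared}, gs)
        expected = 1.0 / (len(shared & (shared | {"A"})) + 1) if c else 1.0
        assert sim.values[0, 1] == expected
    with pytest.raises(ValueError):
        build_similarity({}, gs)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_distance_textbook_values():
    rows = np.array([[0.0, 0.0], [3.0, 4.0]])
    assert pairwise_distance(rows, "euclidean")[0, 1] == 5.0
    rows = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert pairwise_distance(rows, "manhattan")[0, 1] == 2.0
    assert pairwise_distance(rows, "maximum")[0, 1] == 1.0
    same = np.ones((3, 4))
    assert (pairwise_distance(same, "canberra") == 0).all()
    np.testing.assert_allclose(
        pairwise_distance(rows, "minkowski", p=2), pairwise_distance(rows, "euclidean")
    )


def test_canberra_zero_over_zero_contributes_nothing():
    rows = np.array([[0.0, 1.0], [0.0, 3.0]])
    assert pairwise_distance(rows, "canberra")[0, 1] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def test_separated_groups_recovered_by_all_linkages(rng):
    X = np.vstack([rng.normal(0, 0.1, (5, 3)), rng.normal(10, 0.1, (6, 3))])
    D = pairwise_distance(X, "euclidean")
    expected = {frozenset(range(5)), frozenset(range(5, 11))}
    for linkage in LINKAGES:
        result = hierarchical_cluster(D, linkage, 2)
        assert _partition_from_labels(result.labels) == expected


def test_k_equals_n_and_validation(rng):
    X = rng.random((5, 2))
    D = pairwise_distance(X, "euclidean")
    result = hierarchical_cluster(D, "ward.D", 5)
    assert len(set(result.labels)) == 5
    with pytest.raises(ValueError):
        hierarchical_cluster(D[:4], "ward.D", 2)
    with pytest.raises(ValueError):
        hierarchical_cluster(np.triu(D), "ward.D", 2)
    with pytest.raises(ValueError):
        hierarchical_cluster(D, "nonsense", 2)


def test_heights_nondecreasing_for_monotone_linkages(rng):
    X = rng.random((12, 4))
    D = pairwise_distance(X, "euclidean")
    for linkage in ("ward.D", "ward.D2", "single", "complete", "average"):
        heights = [h for _, _, h in hierarchical_cluster(D, linkage, 2).merge_history]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))


def test_merge_history_matches_naive_oracle_all_linkages(rng):
    """Property sweep: the array implementation and an independent
    dictionary-based naive agglomeration agree merge-for-merge."""
    for trial in range(24):
        n = int(rng.integers(3, 9))
        X = rng.random((n, 3))
        metric = DISTANCES[trial % len(DISTANCES)]
        D = pairwise_distance(X, metric)
        for linkage in LINKAGES:
            mine = hierarchical_cluster(D, linkage, 2)
            oracle_merges, oracle_parts = naive_agglomerate(D, linkage)
            np.testing.assert_allclose(
                [m[2] for m in mine.merge_history],
                [m[2] for m in oracle_merges],
                rtol=1e-9, atol=1e-12,
            )
            for k in range(2, n + 1):
                labels = hierarchical_cluster(D, linkage, k).labels
                assert _partition_from_labels(labels) == set(oracle_parts[k])


def test_scipy_cross_check_shared_linkages(rng):
    from scipy.cluster.hierarchy import linkage as scipy_linkage
    from scipy.spatial.distance import squareform

    X = rng.random((15, 4))
    D = pairwise_distance(X, "euclidean")
    for mine_name, scipy_name in [
        ("single", "single"), ("complete", "complete"),
        ("average", "average"), ("mcquitty", "weighted"), ("ward.D2", "ward"),
    ]:
        heights = sorted(h for _, _, h in hierarchical_cluster(D, mine_name, 2).merge_history)
        Z = scipy_linkage(squareform(D, checks=False), method=scipy_name)
        np.testing.assert_allclose(heights, sorted(Z[:, 2]), rtol=1e-9)


# ---------------------------------------------------------------------------
# stability + model selection
# ---------------------------------------------------------------------------

def test_stability_matches_definitional_recomputation(rng):
    X = rng.random((10, 4))
    for distance, linkage, k in [("euclidean", "ward.D", 3), ("manhattan", "average", 2)]:
        scores = stability_scores(X, distance, linkage, k)

        def cluster_fn(data):
            return hierarchical_cluster(pairwise_distance(data, distance), linkage, k).labels

        def metric_fn(x, y):
            return float(pairwise_distance(np.vstack([x, y]), distance)[0, 1])

        apn, ad, adm, fom = stability_by_definition(X, cluster_fn, metric_fn, k)
        assert scores.apn == pytest.approx(apn, abs=1e-10)
        assert scores.ad == pytest.approx(ad, abs=1e-10)
        assert scores.adm == pytest.approx(adm, abs=1e-10)
        assert scores.fom == pytest.approx(fom, abs=1e-10)


def test_stability_zero_on_deletion_invariant_data():
    # two far blocks identical in every column: removing any column cannot
    # change the 2-cluster structure
    X = np.vstack([np.zeros((5, 4)), np.full((5, 4), 50.0)])
    scores = stability_scores(X, "euclidean", "ward.D", 2)
    assert scores.apn == 0.0 and scores.adm == 0.0
    with pytest.raises(ValueError):
        stability_scores(X[:, :1], "euclidean", "ward.D", 2)


def test_model_select_grid_of_one_and_degenerate():
    rng = np.random.default_rng(2)
    X = rng.random((8, 3))
    sel = model_select(X, [2], ["euclidean"], ["ward.D"])
    assert sel.selected == ("euclidean", "ward.D", 2)
    with pytest.raises(ValueError):
        model_select(np.ones((6, 3)), [2], ["euclidean"], ["ward.D"])
    with pytest.raises(ValueError):
        model_select(X, [], ["euclidean"], ["ward.D"])


def test_model_select_recovers_planted_k():
    profiles, _ = planted_cluster_profiles(0)
    gs = GeneSet("g", tuple(sorted({g for s in profiles.values() for g in s})))
    sim = build_similarity(profiles, gs)
    sel = model_select(
        sim.values, [2, 3, 4, 5, 6],
        ("euclidean", "manhattan"), ("ward.D", "complete", "average"),
    )
    assert sel.selected[2] == 3


# ---------------------------------------------------------------------------
# therapy annotation
# ---------------------------------------------------------------------------

def test_annotate_therapy_lookup_and_unclassified():
    labels = {"D1": 1, "D2": 2, "D3": "hypermutated", "D4": 9}
    cluster_map = {1: "all_wt", 2: "RAS", "hypermutated": "hypermutated"}
    out = annotate_therapy(labels, cluster_map)
    assert out["D1"] == DEFAULT_THERAPY_MAP["all_wt"]
    assert "Bevacizumab" in out["D2"]
    assert "checkpoint" in out["D3"]
    assert out["D4"] == "unclassified"
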