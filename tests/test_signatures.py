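import numpy as np
import pytest

from conftest import make_indel, make_snv
from crcpanel.signatures import (
    CHANNELS_96,
    ContextMatrix,
    build_context_matrix,
    classify_96,
    channel_to_snv,
    cosine_similarity,
    deconvolve,
    extract_signatures,
    read_catalog,
    reference_catalog,
    write_catalog,
)


def test_channel_order_and_pole_context():
    assert len(CHANNELS_96) == len(set(CHANNELS_96)) == 96
    assert CHANNELS_96[0] == "A[C>A]A"
    # the POLE ultra-hypermutator channel: C>A at TpCpT
    v = make_snv(ref="C", alt="A", context3="TCT")
    assert CHANNELS_96[classify_96(v)] == "T[C>A]T"


def test_purine_folding_is_reverse_complement():
    pyr = make_snv(ref="C", alt="A", context3="TCT")
    pur = make_snv(ref="G", alt="T", context3="AGA")
    assert classify_96(pyr) == classify_96(pur)


def test_classify_is_bijective_on_canonical_pairs():
    seen = set()
    for channel in range(96):
        ref, alt, ctx = channel_to_snv(channel)
        v = make_snv(ref=ref, alt=alt, context3=ctx)
        assert classify_96(v) == channel
        seen.add(channel)
    assert len(seen) == 96


def test_unclassifiable_variants_counted():
    variants = [
        make_snv(pos=1, ref="C", alt="T", context3="ACA"),
        make_snv(pos=2),                 # no context
        make_indel(pos=3),               # indel
    ]
    ctx = build_context_matrix(variants)
    assert ctx.counts.sum() == 1
    assert ctx.n_unclassifiable == 2


def test_context_matrix_row_sums_are_classifiable_counts():
    variants = [
        make_snv(donor="D1", pos=i, ref="C", alt="T", context3="ACA") for i in range(5)
    ] + [make_snv(donor="D2", pos=9, ref="T", alt="G", context3="ATA")]
    ctx = build_context_matrix(variants)
    assert list(ctx.counts.sum(axis=1)) == [5, 1]


def test_catalog_round_trip(tmp_path):
    catalog = reference_catalog()
    path = tmp_path / "catalog.tsv"
    write_catalog(catalog, path)
    back = read_catalog(path)
    assert back.names == catalog.names
    np.testing.assert_allclose(back.matrix, catalog.matrix, atol=1e-12)


def test_nmf_recovers_rank1_factorization():
    catalog = reference_catalog()
    sig = catalog["pole_exo"]
    exposures = np.array([500.0, 1500.0, 4000.0])
    V = np.outer(exposures, sig)
    ctx = ContextMatrix(["a", "b", "c"], np.round(V * 4).astype(int))
    res = extract_signatures(ctx, k=1, n_restarts=3, seed=0)
    assert cosine_similarity(res.signatures[:, 0], sig) > 0.999


def test_nmf_recovers_two_disjoint_signatures(rng):
    """Planted-factor recovery: disjoint-support signatures with some
    near-pure donors (pure donors make the factorization identifiable)."""
    s1 = np.zeros(96); s1[:48] = rng.random(48); s1 /= s1.sum()
    s2 = np.zeros(96); s2[48:] = rng.random(48); s2 /= s2.sum()
    pure1 = np.column_stack([rng.integers(500, 2000, 4), np.zeros(4)])
    pure2 = np.column_stack([np.zeros(4), rng.integers(500, 2000, 4)])
    mixed = rng.integers(200, 2000, size=(4, 2))
    E = np.vstack([pure1, pure2, mixed]).astype(float)
    V = np.round(E @ np.vstack([s1, s2])).astype(int)
    res = extract_signatures(ContextMatrix([f"d{i}" for i in range(12)], V),
                             k=2, n_restarts=4, seed=1)
    sims = np.array([[cosine_similarity(res.signatures[:, i], s) for s in (s1, s2)]
                     for i in range(2)])
    best = max(sims[0, 0] + sims[1, 1], sims[0, 1] + sims[1, 0]) / 2
    assert best > 0.99  # recovered up to column permutation


def test_nmf_deterministic_and_objective_nonincreasing():
    rng = np.random.default_rng(3)
    V = rng.integers(0, 30, size=(8, 96))
    ctx = ContextMatrix([f"d{i}" for i in range(8)], V)
    r1 = extract_signatures(ctx, k=2, n_restarts=2, seed=7)
    r2 = extract_signatures(ctx, k=2, n_restarts=2, seed=7)
    np.testing.assert_array_equal(r1.signatures, r2.signatures)
    trace = np.array(r1.objective_trace)
    assert (np.diff(trace[::10]) <= 1e-8 * np.maximum(np.abs(trace[::10][:-1]), 1.0)).all()


def test_nmf_input_validation():
    ctx = ContextMatrix(["a"], np.zeros((1, 96), dtype=int))
    with pytest.raises(ValueError):
        extract_signatures(ctx, k=1)
    with pytest.raises(ValueError):
        extract_signatures(ContextMatrix(["a"], np.ones((1, 96), dtype=int)), k=2)


def test_deconvolve_pure_signature():
    catalog = reference_catalog()
    counts = np.round(catalog["mmr_deficient"] * 10000)
    res = deconvolve(counts, catalog)
    assert res.weights["mmr_deficient"] > 0.95
    assert res.reconstruction_error < 1e-4
    assert abs(sum(res.weights.values()) + res.unassigned - 1.0) < 1e-6


def test_deconvolve_floor_zeroes_trace_components():
    catalog = reference_catalog()
    profile = 0.97 * catalog["clock_cpg"] + 0.03 * catalog["pole_exo"]
    res = deconvolve(np.round(profile * 100000), catalog, weight_floor=0.06)
    assert res.weights["pole_exo"] == 0.0
    assert res.weights["clock_cpg"] > 0.9


def test_deconvolve_sampled_mixture_recovers_weights():
    catalog = reference_catalog()
    mix = 0.7 * catalog["clock_cpg"] + 0.3 * catalog["pole_exo"]
    rng = np.random.default_rng(17)
    counts = rng.multinomial(5000, mix)
    res = deconvolve(counts, catalog)
    assert abs(res.weights["clock_cpg"] - 0.7) < 0.05
    assert abs(res.weights["pole_exo"] - 0.3) < 0.05


def test_deconvolve_beats_single_signature_fits():
    catalog = reference_catalog()
    mix = 0.5 * catalog["flat"] + 0.5 * catalog["apobec_like"]
    counts = np.round(mix * 20000)
    res = deconvolve(counts, catalog)
    profile = counts / counts.sum()
    for j in range(catalog.matrix.shape[1]):
        single = profile - catalog.matrix[:, j]
        assert res.reconstruction_error <= single @ single + 1e-12
    with pytest.raises(ValueError):
        deconvolve(np.zeros(96), catalog)
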