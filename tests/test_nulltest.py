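"""Doublet-null construction: mixing identities, sampling, distances, verdict."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from doubletnull import normalize_log10k
from doubletnull.features import HVGResult
from doubletnull.nulltest import (
    DoubletSimConfig,
    HybridDoubletTest,
    SimulatedDoubletSet,
    distance_report,
    mix_profiles,
    sample_negative_control,
    simulate_doublets,
    verdict,
)

from conftest import make_adata

vecs = arrays(np.float64, 6, elements=st.floats(0, 8, allow_nan=False))


def test_mix_profiles_trivial_values():
    assert mix_profiles(np.zeros(3), np.zeros(3)) == pytest.approx(np.zeros(3))
    a = np.array([np.log(11.0)])
    assert mix_profiles(a, np.zeros(1))[0] == pytest.approx(np.log(6.0), abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(a=vecs, b=vecs)
def test_mix_profiles_commutative_idempotent_and_exact_inverse(a, b):
    assert np.allclose(mix_profiles(a, b), mix_profiles(b, a), atol=1e-12)
    assert np.allclose(mix_profiles(a, a), a, atol=1e-12)
    # exact inversion of the log1p convention
    assert np.allclose(np.log1p(np.expm1(a)), a, atol=1e-12)


def test_mix_profiles_length_mismatch():
    with pytest.raises(ValueError, match="shapes differ"):
        mix_profiles(np.zeros(3), np.zeros(4))


def _toy_norm(n_a=4, n_b=4, n_q=3, n_other=6, n_genes=12, seed=0):
    rng = np.random.default_rng(seed)
    n = n_a + n_b + n_q + n_other
    X = rng.poisson(3.0, size=(n, n_genes)) + 1  # no zero-total cells
    clusters = ["A"] * n_a + ["B"] * n_b + ["Q"] * n_q + ["other"] * n_other
    adata = make_adata(X, clusters=clusters)
    norm = normalize_log10k(adata)
    hvg = list(norm.var_names)
    labels = norm.obs["cluster"].astype(str)
    return norm, labels, hvg


def test_simulate_doublets_seeded_and_restricted_to_hvg():
    norm, labels, hvg = _toy_norm()
    cfg = DoubletSimConfig("A", "B", "Q", n_pairs=40, n_negative=5, seed=9)
    s1 = simulate_doublets(norm, labels, hvg[:5], cfg)
    s2 = simulate_doublets(norm, labels, hvg[:5], cfg)
    assert s1.pair_indices == s2.pair_indices
    assert np.array_equal(s1.profiles, s2.profiles)
    assert s1.profiles.shape == (40, 5)


def test_simulate_doublets_single_cell_parents_give_identical_profiles():
    norm, labels, hvg = _toy_norm(n_a=1, n_b=1)
    # bypass the >=2-cell generator constraint: clusters of size 1 by construction
    cfg = DoubletSimConfig("A", "B", "Q", n_pairs=50, n_negative=5, seed=1)
    s = simulate_doublets(norm, labels, hvg, cfg)
    assert np.allclose(s.profiles, s.profiles[0])


def test_simulate_doublets_empty_parent_named():
    norm, labels, hvg = _toy_norm()
    cfg = DoubletSimConfig("A", "missing", "Q", seed=1)
    with pytest.raises(ValueError, match="missing"):
        simulate_doublets(norm, labels, hvg, cfg)


def test_simulated_profile_mean_matches_exhaustive_pair_mean():
    """Sampled-pair mean profile converges to the all-pairs brute-force mean."""
    norm, labels, hvg = _toy_norm(n_a=10, n_b=10, seed=3)
    cfg = DoubletSimConfig("A", "B", "Q", n_pairs=5000, n_negative=5, seed=3)
    s = simulate_doublets(norm, labels, hvg, cfg)
    X = np.asarray(norm.X.todense())
    A = X[(labels == "A").to_numpy()]
    B = X[(labels == "B").to_numpy()]
    brute = np.array([mix_profiles(a, b) for a in A for b in B]).mean(axis=0)
    assert np.allclose(s.profiles.mean(axis=0), brute, atol=0.05)


def test_negative_control_pool_exact_and_seeded():
    norm, labels, hvg = _toy_norm(n_other=6)
    cfg = DoubletSimConfig("A", "B", "Q", n_pairs=5, n_negative=6, seed=4)
    neg1 = sample_negative_control(labels, cfg)
    neg2 = sample_negative_control(labels, cfg)
    assert sorted(neg1) == sorted(labels.index[labels == "other"])
    assert list(neg1) == list(neg2)


def test_negative_control_small_pool_warns_and_replaces():
    norm, labels, hvg = _toy_norm(n_other=3)
    cfg = DoubletSimConfig("A", "B", "Q", n_pairs=5, n_negative=10, seed=4)
    with pytest.warns(UserWarning, match="replacement"):
        neg = sample_negative_control(labels, cfg)
    assert len(neg) == 10


def test_negative_control_empty_pool_rejected():
    norm, labels, hvg = _toy_norm(n_other=0)
    cfg = DoubletSimConfig("A", "B", "Q", n_pairs=5, n_negative=5, seed=4)
    with pytest.raises(ValueError, match="pool"):
        sample_negative_control(labels, cfg)


def test_distance_trivial_identities():
    from scipy.spatial.distance import cdist

    x = np.array([[1.0, 2.0, 3.0]])
    assert cdist(x, x)[0, 0] == 0.0
    y = x.copy()
    y[0, 1] += 0.7
    assert cdist(x, y)[0, 0] == pytest.approx(0.7)


def test_distance_report_matches_exhaustive_hand_computation():
    """4 query cells, tiny parents: summaries equal a brute-force all-pairs oracle."""
    norm, labels, hvg = _toy_norm(n_a=3, n_b=3, n_q=4, n_other=5, n_genes=8, seed=5)
    cfg = DoubletSimConfig("A", "B", "Q", n_pairs=7, n_negative=5, seed=6)
    rng = np.random.default_rng(6)
    sim = simulate_doublets(norm, labels, hvg, cfg, rng=rng)
    neg = sample_negative_control(labels, cfg, rng=rng)
    table = distance_report(norm, labels, hvg, sim, neg, cfg)

    X = np.asarray(norm.X.todense())
    names = list(norm.obs_names)
    Q = X[(labels == "Q").to_numpy()]

    def all_pairs(U, V):
        return np.array([np.sqrt(((u - v) ** 2).sum()) for u in U for v in V])

    qq = np.array(
        [np.sqrt(((Q[i] - Q[j]) ** 2).sum()) for i in range(len(Q)) for j in range(i + 1, len(Q))]
    )
    assert table.loc["query_vs_query", "mean"] == pytest.approx(qq.mean(), abs=1e-12)
    assert table.loc["query_vs_query", "n_pairs_evaluated"] == len(qq)

    A = X[(labels == "A").to_numpy()]
    d = all_pairs(Q, A)
    assert table.loc["query_vs_parent_a", "mean"] == pytest.approx(d.mean(), abs=1e-12)
    assert table.loc["query_vs_parent_a", "median"] == pytest.approx(np.median(d), abs=1e-12)
    assert table.loc["query_vs_parent_a", "p5"] == pytest.approx(np.percentile(d, 5), abs=1e-12)

    d = all_pairs(Q, sim.profiles)
    assert table.loc["query_vs_simulated_doublets", "mean"] == pytest.approx(d.mean(), abs=1e-12)

    N = X[[names.index(c) for c in neg]]
    d = all_pairs(Q, N)
    assert table.loc["query_vs_negative_control", "p95"] == pytest.approx(
        np.percentile(d, 95), abs=1e-12
    )


def test_distance_report_invariant_to_cell_and_gene_order():
    norm, labels, hvg = _toy_norm(seed=8)
    cfg = DoubletSimConfig("A", "B", "Q", n_pairs=20, n_negative=6, seed=8)
    sim = simulate_doublets(norm, labels, hvg, cfg)
    neg = sample_negative_control(labels, cfg)
    t1 = distance_report(norm, labels, hvg, sim, neg, cfg)

    rng = np.random.default_rng(0)
    cell_perm = rng.permutation(norm.n_obs)
    gene_perm = rng.permutation(len(hvg))
    norm_p = norm[cell_perm][:, gene_perm].copy()
    hvg_p = [hvg[g] for g in gene_perm]
    sim_p = SimulatedDoubletSet(sim.profiles[:, gene_perm], sim.pair_indices, sim.seed)
    t2 = distance_report(norm_p, labels, hvg_p, sim_p, neg, cfg)
    pd.testing.assert_frame_equal(t1, t2, check_exact=False, rtol=1e-12)


def test_verdict_rules_and_missing_comparison():
    def _report(sim, pa, pb, neg):
        return pd.DataFrame(
            {"mean": [sim, pa, pb, neg]},
            index=[
                "query_vs_simulated_doublets",
                "query_vs_parent_a",
                "query_vs_parent_b",
                "query_vs_negative_control",
            ],
        )

    v = verdict(_report(1.0, 2.0, 3.0, 4.0))
    assert v.is_doublet_like
    assert v.margins["query_vs_parent_a"] == pytest.approx(1.0)
    v = verdict(_report(2.5, 2.0, 3.0, 4.0))  # parent_a mean smallest
    assert not v.is_doublet_like
    with pytest.raises(ValueError, match="missing"):
        verdict(_report(1.0, 2.0, 3.0, 4.0).drop("query_vs_parent_b"))


def test_end_to_end_injected_doublet_detected(small_doublet_dataset):
    adata, labels, truth = small_doublet_dataset
    model = HybridDoubletTest.from_counts(
        adata, "c1", "c2", "doublet", n_hvg=300, n_pairs=800, n_negative=800
    )
    res = model.fit(seed=7)
    assert res.is_doublet_like
    assert all(m > 0 for m in res.margins.values())
    assert "doublet-like artifact" in res.summary()


def test_model_rejects_unknown_cluster(small_doublet_dataset):
    adata, labels, truth = small_doublet_dataset
    with pytest.raises(ValueError, match="not present"):
        HybridDoubletTest.from_counts(adata, "c1", "c2", "no_such_cluster", n_hvg=100)
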