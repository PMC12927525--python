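"""NB differential expression: oracle agreement, calibration, marker sharing."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import statsmodels.api as sm

from doubletnull.markers import (
    DEConfig,
    DEResult,
    NegativeBinomialMarkers,
    marker_sharing,
    nb_de,
)

from conftest import make_adata


def _nb_dataset(rng, n_in=200, n_out=200, G=60, fold_on=None, size=2.0, depth_sigma=0.4):
    """NB counts with per-cell depth; fold_on maps gene -> fold change in-group."""
    n = n_in + n_out
    depth = rng.lognormal(np.log(2000), depth_sigma, n)
    base = rng.lognormal(0, 1.0, G)
    base /= base.sum()
    rel = np.tile(base, (n, 1))
    if fold_on:
        for g, f in fold_on.items():
            rel[:n_in, g] *= f
    mu = depth[:, None] * rel
    Y = rng.negative_binomial(size, size / (size + np.maximum(mu, 1e-12)))
    adata = make_adata(Y, clusters=["in"] * n_in + ["out"] * n_out)
    labels = pd.Series(adata.obs["cluster"], index=adata.obs_names).astype(str)
    return adata, labels


def test_agrees_with_statsmodels_glm_oracle():
    """The vectorised IRLS equals statsmodels GLM (same NB model, same dispersion)."""
    from doubletnull.markers import _mom_dispersion, _nb_wald_vectorized

    rng = np.random.default_rng(0)
    adata, labels = _nb_dataset(rng, n_in=80, n_out=120, G=25, fold_on={3: 5.0, 7: 0.3})
    cfg = DEConfig(logfc_threshold=0.0, min_detect_fraction=0.0, alpha_adj=0.05)
    res = nb_de(adata, labels, "in", cfg)

    Y = np.asarray(adata.X.todense(), float)
    offset = np.log(Y.sum(axis=1))
    in_mask = (labels == "in").to_numpy()
    X = np.column_stack([np.ones(len(labels)), in_mask.astype(float)])
    tested = res.table[~res.table["flagged"]]
    alpha = _mom_dispersion(
        Y[:, [adata.var_names.get_loc(g) for g in res.table.index]], in_mask, np.exp(offset)
    )
    for g in tested.index[:10]:
        j = adata.var_names.get_loc(g)
        k = list(res.table.index).index(g)
        fit = sm.GLM(
            Y[:, j], X, family=sm.families.NegativeBinomial(alpha=alpha[k]), offset=offset
        ).fit()
        assert tested.loc[g, "coef"] == pytest.approx(fit.params[1], abs=1e-5)
        assert tested.loc[g, "p_value"] == pytest.approx(fit.pvalues[1], abs=1e-5)


def test_null_gene_logfc_converges():
    """No group effect, 2000 cells per group: |log_fc| stays tiny."""
    rng = np.random.default_rng(1)
    adata, labels = _nb_dataset(rng, n_in=2000, n_out=2000, G=30, size=5.0, depth_sigma=0.2)
    cfg = DEConfig(logfc_threshold=0.0, min_detect_fraction=0.0)
    res = nb_de(adata, labels, "in", cfg)
    expressed = res.table[res.table["pct_in"] > 0.3]
    assert (expressed["log_fc"].abs() < 0.05).all()


def test_large_effect_logfc_recovered():
    """Group means 10 vs 1: log_fc ~ ln(10) within 10% for a well-expressed gene."""
    rng = np.random.default_rng(2)
    n = 4000
    G = 200  # one boosted gene barely perturbs the library size
    depth = np.full(n, 2000.0)
    base = np.full(G, 1.0 / G)
    rel = np.tile(base, (n, 1))
    g = 5
    rel[: n // 2, g] *= 10.0
    size = 2.0
    mu = depth[:, None] * rel
    Y = rng.negative_binomial(size, size / (size + mu))
    adata = make_adata(Y)
    labels = pd.Series(["in"] * (n // 2) + ["out"] * (n // 2), index=adata.obs_names)
    res = nb_de(adata, labels, "in", DEConfig())
    assert res.table.loc["g5", "log_fc"] == pytest.approx(np.log(10.0), rel=0.10)
    assert res.table.loc["g5", "p_adjusted"] < 0.01


def test_label_swap_negates_logfc():
    rng = np.random.default_rng(3)
    adata, labels = _nb_dataset(rng, n_in=100, n_out=100, G=30, fold_on={4: 4.0})
    cfg = DEConfig(logfc_threshold=0.0, min_detect_fraction=0.0)
    fwd = nb_de(adata, labels, "in", cfg)
    swapped = labels.map({"in": "out", "out": "in"})
    rev = nb_de(adata, swapped, "in", cfg)
    common = fwd.table.index.intersection(rev.table.index)
    assert np.allclose(
        fwd.table.loc[common, "log_fc"], -rev.table.loc[common, "log_fc"], atol=1e-12
    )


def test_adjustment_methods():
    rng = np.random.default_rng(4)
    adata, labels = _nb_dataset(rng, n_in=60, n_out=60, G=40, fold_on={2: 6.0, 9: 6.0})
    bonf = nb_de(adata, labels, "in", DEConfig(adjust_method="bonferroni"))
    bh = nb_de(adata, labels, "in", DEConfig(adjust_method="bh"))
    t = bonf.table
    assert np.allclose(
        t["p_adjusted"], np.minimum(t["p_value"] * bonf.n_tested, 1.0), atol=1e-12
    )
    assert (t["p_adjusted"] >= t["p_value"] - 1e-15).all()
    # BH is monotone non-decreasing in p-value rank order
    b = bh.table.sort_values("p_value")
    assert (np.diff(b["p_adjusted"]) >= -1e-12).all()
    assert (bh.table["p_adjusted"] <= bonf.table["p_adjusted"] + 1e-12).all()


def test_prefilter_and_min_cells():
    rng = np.random.default_rng(5)
    adata, labels = _nb_dataset(rng, n_in=50, n_out=50, G=30)
    res = nb_de(adata, labels, "in", DEConfig(logfc_threshold=0.5))
    assert (res.table["log_fc"].abs() >= 0.5).all()
    tiny = labels.copy()
    tiny.iloc[:] = "out"
    tiny.iloc[:2] = "in"
    with pytest.raises(ValueError, match=">= 3 cells"):
        nb_de(adata, tiny, "in", DEConfig())


def _fake_de(cluster, genes, cfg):
    table = pd.DataFrame(
        {
            "log_fc": 1.0,
            "p_value": 1e-6,
            "p_adjusted": 1e-5,
            "pct_in": 0.9,
            "pct_out": 0.1,
            "flagged": False,
        },
        index=pd.Index(genes),
    )
    return DEResult(cluster=cluster, table=table, n_tested=len(genes), config=cfg)


def test_marker_sharing_subset_and_disjoint():
    cfg = DEConfig()
    q = _fake_de("q", ["g1", "g2", "g3"], cfg)
    a = _fake_de("a", ["g1", "g2", "g3", "g4"], cfg)
    b = _fake_de("b", ["g9"], cfg)
    rep = marker_sharing(q, a, b, cfg)
    assert rep.shared_fraction == 1.0
    assert rep.unique_to_query == set()

    rep = marker_sharing(q, _fake_de("a", ["x"], cfg), _fake_de("b", ["y"], cfg), cfg)
    assert rep.shared_fraction == 0.0
    assert rep.unique_to_query == {"g1", "g2", "g3"}

    rep = marker_sharing(_fake_de("q", [], cfg), a, b, cfg)
    assert np.isnan(rep.shared_fraction)


def test_doublet_cluster_markers_are_parent_shared(small_doublet_dataset):
    adata, labels, truth = small_doublet_dataset
    from doubletnull.preprocess import qc_filter

    filtered, _ = qc_filter(adata)
    model = NegativeBinomialMarkers(filtered)
    rep = model.sharing("doublet", "c1", "c2")
    assert len(rep.query_markers) > 0
    assert rep.shared_fraction >= 0.8
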