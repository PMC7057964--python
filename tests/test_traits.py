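"""Ordination, trait correlation estimators, colony F, candidate lists."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from colonynet import traits as traits_mod
from conftest import make_matrix


# -- PCA / LDA --------------------------------------------------------------

def test_pca_rank_one_matrix_single_component():
    u = np.array([1.0, 2.0, 3.0, 4.0])
    v = np.array([1.0, -1.0, 0.5])
    m = make_matrix(np.outer(u, v))
    scores, var = traits_mod.pca_samples(m, k=3)
    assert var[0] == pytest.approx(1.0)


def test_pca_variance_explained_monotone(small_sim):
    _, _, matrix, _ = small_sim
    scores, var = traits_mod.pca_samples(matrix, k=10)
    assert (np.diff(var) <= 1e-12).all()
    assert var.sum() <= 1.0 + 1e-9


def test_pca_clusters_by_colony_on_colony_fixture():
    """Strong colony effects put nestmates together in the first PCs."""
    from sklearn.metrics import silhouette_score
    rng = np.random.default_rng(2)
    n_g, per, k = 200, 8, 5
    eff = rng.normal(0, 1.5, size=(n_g, k))
    cidx = np.repeat(np.arange(k), per)
    vals = 5 + eff[:, cidx] + 0.3 * rng.normal(size=(n_g, per * k))
    m = make_matrix(vals, colonies=[f"C{c + 1}" for c in cidx])
    scores, _ = traits_mod.pca_samples(m, k=3)
    assert silhouette_score(scores, cidx) > 0


def test_lda_separable_colonies_and_axis_bound():
    rng = np.random.default_rng(3)
    k, per = 4, 6
    centers = rng.normal(0, 20, size=(k, 10))
    cidx = np.repeat(np.arange(k), per)
    X = centers[cidx] + 0.1 * rng.normal(size=(k * per, 10))
    scores = pd.DataFrame(X, index=[f"s{i}" for i in range(k * per)])
    labels = pd.Series([f"C{c}" for c in cidx], index=scores.index)
    proj, lda = traits_mod.lda_on_pcs(scores, labels)
    assert proj.shape[1] <= k - 1
    # leave-one-out accuracy on a perfectly separated fixture
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    hits = 0
    for i in range(len(X)):
        keep = np.arange(len(X)) != i
        model = LinearDiscriminantAnalysis().fit(X[keep], labels.to_numpy()[keep])
        hits += model.predict(X[[i]])[0] == labels.iloc[i]
    assert hits == len(X)


def test_lda_rejects_singleton_label():
    scores = pd.DataFrame(np.eye(3), index=["a", "b", "c"])
    labels = pd.Series(["C1", "C1", "C2"], index=scores.index)
    with pytest.raises(ValueError, match="single sample"):
        traits_mod.lda_on_pcs(scores, labels)


def test_lda_null_accuracy_near_chance():
    """With shuffled labels on structureless data, LDA classification sits
    near 1/n_colonies."""
    rng = np.random.default_rng(4)
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    k, per = 4, 10
    accs = []
    for rep in range(50):
        X = rng.normal(size=(k * per, 5))
        y = rng.permutation(np.repeat(np.arange(k), per))
        hits = 0
        for i in range(len(X)):
            keep = np.arange(len(X)) != i
            model = LinearDiscriminantAnalysis().fit(X[keep], y[keep])
            hits += model.predict(X[[i]])[0] == y[i]
        accs.append(hits / len(X))
    assert abs(np.mean(accs) - 1 / k) < 0.1


# -- sample distance network ------------------------------------------------

def test_sample_network_nestmate_fraction_one_when_identical_within_colony():
    rng = np.random.default_rng(5)
    profiles = rng.normal(size=(100, 3))
    cidx = np.repeat(np.arange(3), 4)
    vals = profiles[:, cidx] + 0.01 * rng.normal(size=(100, 12))
    m = make_matrix(vals, colonies=[f"C{c}" for c in cidx])
    g, frac, p = traits_mod.sample_distance_network(m, k_neighbors=3, n_perm=200, seed=0)
    assert isinstance(g, nx.Graph)
    assert frac == 1.0
    assert p < 0.05
    assert g.number_of_edges() <= 12 * 3  # undirected dedup can only shrink


def test_sample_network_null_fraction_matches_mixing():
    """With no colony structure, the nestmate edge fraction matches the
    chance rate of same-colony pairs."""
    rng = np.random.default_rng(6)
    fracs = []
    for rep in range(30):
        vals = rng.normal(size=(60, 20))
        cidx = np.repeat(np.arange(4), 5)
        m = make_matrix(vals, colonies=[f"C{c}" for c in cidx])
        _, frac, _ = traits_mod.sample_distance_network(m, k_neighbors=3, n_perm=10,
                                                        seed=rep)
        fracs.append(frac)
    expected = (5 - 1) / (20 - 1)  # same-colony share of possible partners
    assert np.mean(fracs) == pytest.approx(expected, abs=0.08)


def test_sample_network_rejects_large_k(small_sim):
    _, _, matrix, _ = small_sim
    with pytest.raises(ValueError):
        traits_mod.sample_distance_network(matrix, k_neighbors=matrix.n_samples)


# -- trait correlation estimators -------------------------------------------

def _colony_fixture(rng, n_g=50, k=6, per=5, within_sd=0.0):
    cidx = np.repeat(np.arange(k), per)
    colony_means = rng.normal(5, 1, size=(n_g, k))
    vals = colony_means[:, cidx] + within_sd * rng.normal(size=(n_g, k * per))
    colonies = [f"C{c + 1}" for c in cidx]
    m = make_matrix(vals, colonies=colonies)
    traits = pd.DataFrame({"humidity": rng.uniform(0, 3, k),
                           "da5ht": rng.uniform(0.5, 2, k)},
                          index=[f"C{c + 1}" for c in range(k)])
    return m, traits


def test_trait_vector_gene_gives_r_one():
    rng = np.random.default_rng(7)
    m, traits = _colony_fixture(rng, n_g=2)
    y = traits.loc[m.colonies(), "humidity"].to_numpy()
    vals = m.values.to_numpy().copy()
    vals[0] = y
    m2 = make_matrix(vals, colonies=list(m.colonies()))
    r = traits_mod.per_sample_trait_correlation(m2, traits, "humidity")
    assert r.iloc[0] == pytest.approx(1.0)


def test_estimators_agree_exactly_with_zero_within_colony_variance():
    """With balanced colonies and no nestmate variation, the per-sample and
    colony-mean estimators coincide gene by gene."""
    rng = np.random.default_rng(8)
    m, traits = _colony_fixture(rng, within_sd=0.0)
    rs = traits_mod.per_sample_trait_correlation(m, traits, "humidity")
    rc = traits_mod.colony_mean_trait_correlation(m, traits, "humidity")
    np.testing.assert_allclose(rs.to_numpy(), rc.to_numpy(), atol=1e-12)


def test_two_colonies_give_unit_colony_correlation():
    rng = np.random.default_rng(9)
    m, traits = _colony_fixture(rng, n_g=20, k=2)
    rc = traits_mod.colony_mean_trait_correlation(m, traits, "humidity")
    assert np.allclose(rc.abs().to_numpy(), 1.0)


def test_constant_gene_gives_missing_r():
    rng = np.random.default_rng(10)
    m, traits = _colony_fixture(rng, n_g=3)
    vals = m.values.to_numpy().copy()
    vals[1] = 7.0
    m2 = make_matrix(vals, colonies=list(m.colonies()))
    rs = traits_mod.per_sample_trait_correlation(m2, traits, "humidity")
    assert np.isnan(rs.iloc[1])


def test_null_correlations_symmetric_about_zero():
    rng = np.random.default_rng(11)
    k, per = 9, 10
    cidx = np.repeat(np.arange(k), per)
    vals = rng.normal(size=(5000, k * per))
    m = make_matrix(vals, colonies=[f"C{c + 1}" for c in cidx])
    traits = pd.DataFrame({"humidity": rng.uniform(0, 3, k),
                           "da5ht": rng.uniform(0.5, 2, k)},
                          index=[f"C{c + 1}" for c in range(k)])
    rs = traits_mod.per_sample_trait_correlation(m, traits, "humidity")
    assert abs(rs.mean()) < 0.02
    assert abs(stats.skew(rs)) < 0.2


def test_null_trait_correlation_p_uniform():
    """Under a complete null the per-gene correlation p-values are uniform."""
    rng = np.random.default_rng(12)
    k, per = 9, 10
    cidx = np.repeat(np.arange(k), per)
    y = rng.uniform(0, 3, k)[cidx]
    X = rng.normal(size=(500, k * per))
    ps = [stats.pearsonr(x, y).pvalue for x in X]
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_agreement_requires_pairs_and_matches_r_squared():
    rs = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
    r, r2, p = traits_mod.correlation_method_agreement(rs, rs * 2 + 0.05)
    assert r == pytest.approx(1.0)
    assert r2 == pytest.approx(r**2)
    with pytest.raises(ValueError):
        traits_mod.correlation_method_agreement(rs[:2], rs[:2])


# -- per-gene colony F ------------------------------------------------------

def test_colony_F_infinite_sentinel_for_colony_constant_genes():
    cidx = np.repeat(np.arange(3), 4)
    vals = np.array([[1.0, 2.0, 3.0]])[:, cidx]  # distinct colony constants
    m = make_matrix(vals, colonies=[f"C{c}" for c in cidx])
    out = traits_mod.per_gene_colony_F(m)
    assert np.isinf(out["F"].iloc[0])
    assert out["p"].iloc[0] == 0.0


def test_colony_F_null_moment_and_uniform_p():
    """Null F mean approximates df2/(df2-2); null p-values are uniform."""
    rng = np.random.default_rng(13)
    k, per = 5, 8
    cidx = np.repeat(np.arange(k), per)
    m = make_matrix(rng.normal(size=(1000, k * per)),
                    colonies=[f"C{c}" for c in cidx])
    out = traits_mod.per_gene_colony_F(m)
    df2 = k * per - k
    assert out["F"].mean() == pytest.approx(df2 / (df2 - 2), rel=0.1)
    assert stats.kstest(out["p"], "uniform").pvalue > 0.01


def test_colony_F_matches_scipy_oracle():
    rng = np.random.default_rng(14)
    k, per = 4, 6
    cidx = np.repeat(np.arange(k), per)
    vals = rng.normal(size=(10, k * per))
    m = make_matrix(vals, colonies=[f"C{c}" for c in cidx])
    out = traits_mod.per_gene_colony_F(m)
    for g in range(10):
        groups = [vals[g, cidx == c] for c in range(k)]
        F, p = stats.f_oneway(*groups)
        assert out["F"].iloc[g] == pytest.approx(F, rel=1e-10)
        assert out["p"].iloc[g] == pytest.approx(p, rel=1e-10)


# -- candidate list tests ---------------------------------------------------

def test_candidate_list_test_matches_t_distribution():
    rng = np.random.default_rng(15)
    r = pd.Series(rng.normal(0.3, 0.1, 13), index=[f"g{i}" for i in range(13)])
    t, df, p, mean_r = traits_mod.candidate_list_test(r, list(r.index))
    assert df == 12
    assert p == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-12)
    assert mean_r == pytest.approx(r.mean())


def test_candidate_list_symmetric_values_give_t_zero():
    r = pd.Series([-0.4, 0.4, -0.2, 0.2], index=list("abcd"))
    t, df, p, _ = traits_mod.candidate_list_test(r, list("abcd"))
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_candidate_list_requires_two_usable_genes():
    r = pd.Series([0.1, np.nan], index=["a", "b"])
    with pytest.raises(ValueError):
        traits_mod.candidate_list_test(r, ["a", "b"])


def test_planted_trait_genes_rank_by_abs_r(large_sim):
    """Planted humidity genes outrank null genes by |r_sample| (AUC >= 0.9)."""
    from sklearn.metrics import roc_auc_score
    _, traits, pp, truth = large_sim
    rs = traits_mod.per_sample_trait_correlation(pp, traits, "humidity")
    eff = truth.trait_effect["humidity"].reindex(rs.index).fillna(0.0)
    in_module = truth.module_label.reindex(rs.index) != "none"
    use = ~in_module  # compare planted background genes against pure noise genes
    labels = (eff[use] != 0).astype(int)
    auc = roc_auc_score(labels, rs[use].abs().fillna(0.0))
    assert auc >= 0.9
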