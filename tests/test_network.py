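"""Signed network: adjacency/TO oracles, tree cutting, eigengenes,
density permutation filter, quality Z, module-trait analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from colonynet import network
from colonynet.network import NetworkParams
from conftest import make_matrix


# -- adjacency --------------------------------------------------------------

def test_signed_adjacency_endpoints_and_midpoint():
    t = np.linspace(0, 1, 12)
    vals = np.vstack([t, t, -t, np.random.default_rng(0).normal(size=12)])
    m = make_matrix(vals)
    adj = network.signed_adjacency(m, beta=12)
    a = adj.to_numpy()
    assert a[0, 1] == pytest.approx(1.0)          # cor = +1
    assert a[0, 2] == pytest.approx(0.0, abs=1e-15)  # cor = -1
    assert np.allclose(np.diag(a), 0.0)
    assert ((a >= 0) & (a <= 1)).all()
    # cor = 0 -> 0.5**beta
    z = np.zeros((2, 50))
    rng = np.random.default_rng(1)
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    y -= np.polyval(np.polyfit(x, y, 1), x)  # orthogonalize -> cor exactly 0
    m2 = make_matrix(np.vstack([x, y]))
    a2 = network.signed_adjacency(m2, beta=12).to_numpy()
    assert a2[0, 1] == pytest.approx(0.5**12, rel=1e-9)


def test_adjacency_monotone_shrinkage_in_beta(small_sim):
    _, _, matrix, _ = small_sim
    sub = matrix.subset(genes=matrix.gene_ids[:40])
    a1 = network.signed_adjacency(sub, 2).to_numpy()
    a2 = network.signed_adjacency(sub, 6).to_numpy()
    off = ~np.eye(40, dtype=bool)
    assert (a2[off] <= a1[off] + 1e-12).all()


def test_adjacency_rejects_zero_variance_gene():
    vals = np.vstack([np.ones(10), np.random.default_rng(2).normal(size=10)])
    with pytest.raises(ValueError, match="zero-variance"):
        network.signed_adjacency(make_matrix(vals), 6)


# -- soft threshold ---------------------------------------------------------

def test_pick_soft_threshold_table_and_target(block_sim):
    _, _, pp, _ = block_sim
    sub = pp.subset(genes=pp.gene_ids[:250])
    beta, table = network.pick_soft_threshold(sub, candidate_betas=(2, 4, 6, 8, 10))
    assert len(table) == 5
    assert beta in (2, 4, 6, 8, 10)
    # chosen beta is the smallest reaching the target, else the argmax
    ok = table.index[table["signed_r2"] >= 0.8]
    expected = int(ok[0]) if len(ok) else int(table["signed_r2"].idxmax())
    assert beta == expected


# -- topological overlap ----------------------------------------------------

def _brute_force_to(a: np.ndarray) -> np.ndarray:
    """Independent double-loop evaluation of the TO formula."""
    n = a.shape[0]
    k = a.sum(axis=1)
    to = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            to[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return to


def test_to_fully_connected_triangle_is_one():
    a = np.ones((3, 3)) - np.eye(3)
    adj = pd.DataFrame(a, index=list("abc"), columns=list("abc"))
    to = network.topological_overlap(adj).to_numpy()
    assert np.allclose(to, 1.0)


def test_to_isolated_pair_is_zero():
    a = np.zeros((4, 4))
    adj = pd.DataFrame(a, index=list("abcd"), columns=list("abcd"))
    to = network.topological_overlap(adj).to_numpy()
    off = ~np.eye(4, dtype=bool)
    assert np.allclose(to[off], 0.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_to_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 1, size=(8, 8))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    adj = pd.DataFrame(a, index=[f"g{i}" for i in range(8)],
                       columns=[f"g{i}" for i in range(8)])
    to = network.topological_overlap(adj).to_numpy()
    np.testing.assert_allclose(to, _brute_force_to(a), atol=1e-12)


def test_to_rejects_negative_and_asymmetric():
    bad = pd.DataFrame(-np.ones((3, 3)) + np.eye(3))
    with pytest.raises(ValueError):
        network.topological_overlap(bad)


# -- clustering -------------------------------------------------------------

def _block_to(sizes, high=0.6, low=0.05, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    to = rng.uniform(low / 2, low, size=(n, n))
    start = 0
    for s in sizes:
        to[start:start + s, start:start + s] = rng.uniform(high, high + 0.2, (s, s))
        start += s
    to = (to + to.T) / 2
    np.fill_diagonal(to, 1.0)
    ids = [f"g{i}" for i in range(n)]
    return pd.DataFrame(to, index=ids, columns=ids)


def test_cluster_recovers_two_planted_blocks():
    to = _block_to([100, 100])
    modules = network.cluster_and_cut(to, min_module_size=40)
    truth = [0] * 100 + [1] * 100
    assert len(modules.module_names()) == 2
    assert adjusted_rand_score(truth, modules.labels) == 1.0
    assert all(s >= 40 for s in modules.sizes().values())


def test_cluster_small_input_all_grey():
    to = _block_to([10])
    with pytest.warns(UserWarning):
        modules = network.cluster_and_cut(to, min_module_size=50)
    assert set(modules.labels) == {network.GREY}


# -- eigengene / kME --------------------------------------------------------

def test_eigengene_identical_genes_gives_unit_kme():
    base = np.random.default_rng(3).normal(size=20)
    vals = np.tile(base, (5, 1)) + 1e-9 * np.random.default_rng(4).normal(size=(5, 20))
    m = make_matrix(vals)
    eig = network.module_eigengene(m, m.gene_ids)
    k = network.kme(m, eig)
    assert np.allclose(np.abs(k), 1.0, atol=1e-6)
    assert np.isclose(np.linalg.norm(eig), 1.0)


def test_eigengene_recovers_planted_factor():
    rng = np.random.default_rng(5)
    factor = rng.normal(size=30)
    load = np.abs(rng.normal(1, 0.3, size=40))
    vals = load[:, None] * factor[None, :] + 0.3 * rng.normal(size=(40, 30))
    m = make_matrix(vals)
    eig = network.module_eigengene(m, m.gene_ids)
    r = np.corrcoef(eig, factor)[0, 1]
    assert abs(r) > 0.95
    # sign orientation: mean member kME non-negative
    assert network.kme(m, eig).mean() >= 0


def test_eigengene_rejects_degenerate_modules():
    m = make_matrix(np.ones((3, 10)))
    with pytest.raises(ValueError):
        network.module_eigengene(m, m.gene_ids[:1])
    with pytest.raises(ValueError):
        network.module_eigengene(m, m.gene_ids)  # zero variance


# -- density and permutation test -------------------------------------------

def test_module_density_trivial_cases():
    to = _block_to([30])
    genes = to.index[:2]
    assert network.module_density(to, genes) == pytest.approx(
        float(to.iloc[0, 1]))
    const = pd.DataFrame(np.full((5, 5), 0.4), index=list("abcde"),
                         columns=list("abcde"))
    np.fill_diagonal(const.values, 1.0)
    assert network.module_density(const, list("abc")) == pytest.approx(0.4)
    with pytest.raises(ValueError):
        network.module_density(to, to.index[:1])


def test_density_permutation_constant_to_gives_zero():
    """On a constant TO every pseudo-module ties the observed density; the
    strict '>' makes p = 0."""
    const = pd.DataFrame(np.full((30, 30), 0.4))
    np.fill_diagonal(const.values, 1.0)
    const.index = const.columns = [f"g{i}" for i in range(30)]
    p = network.density_permutation_test(const, const.index[:10], n_pseudo=200, seed=0)
    assert p == 0.0


def test_density_permutation_planted_block_p_zero():
    to = _block_to([50, 150])
    p = network.density_permutation_test(to, to.index[:50], n_pseudo=2000, seed=1)
    assert p == 0.0


def test_density_permutation_null_calibrated():
    """For a random gene draw on an exchangeable TO, the permutation p is
    (discretely) uniform: one-sided KS detects no anticonservatism and the
    rejection rate stays at nominal."""
    rng = np.random.default_rng(7)
    n = 120
    base = rng.uniform(0.1, 0.3, size=(n, n))
    to = pd.DataFrame((base + base.T) / 2, index=[f"g{i}" for i in range(n)],
                      columns=[f"g{i}" for i in range(n)])
    np.fill_diagonal(to.values, 1.0)
    ps = []
    for d in range(100):
        draw = np.random.default_rng(500 + d).choice(to.index, 12, replace=False)
        ps.append(network.density_permutation_test(to, draw, n_pseudo=400,
                                                   seed=900 + d))
    assert stats.kstest(ps, "uniform", alternative="greater").pvalue > 0.01
    assert abs(np.mean(ps) - 0.5) < 0.1


def test_density_permutation_deterministic_under_seed():
    to = _block_to([40, 60])
    p1 = network.density_permutation_test(to, to.index[:20], 500, seed=3)
    p2 = network.density_permutation_test(to, to.index[:20], 500, seed=3)
    assert p1 == p2


# -- iterative filter -------------------------------------------------------

def test_density_filter_recovers_planted_modules(block_sim):
    """Planted modules survive the filter with high recall; noise genes are
    removed; the result is a fixed point."""
    _, _, pp, truth = block_sim
    params = NetworkParams(beta=6, min_module_size=40, n_pseudo=500, seed=0)
    modules, to = network.iterative_density_filter(pp, params)
    kept = modules.labels.index
    truth_kept = truth.module_label.reindex(kept)
    assert adjusted_rand_score(truth_kept, modules.labels) >= 0.8
    # recall of planted module genes
    planted = truth.module_label[truth.module_label != "none"].index
    recall = len(set(kept) & set(planted)) / len(planted)
    assert recall >= 0.9
    # noise genes removed
    noise = truth.module_label[truth.module_label == "none"].index
    leak = len(set(kept) & set(noise)) / len(noise)
    assert leak <= 0.2
    # fixed point: rerunning on the surviving genes changes nothing
    again, _ = network.iterative_density_filter(pp.subset(genes=kept), params)
    assert set(again.labels.index) == set(kept)
    assert adjusted_rand_score(again.labels.loc[kept], modules.labels.loc[kept]) == 1.0


def test_density_filter_all_noise_terminates_empty():
    rng = np.random.default_rng(8)
    m = make_matrix(rng.normal(size=(120, 40)))
    params = NetworkParams(beta=6, min_module_size=30, n_pseudo=300, seed=0)
    modules, to = network.iterative_density_filter(m, params)
    assert modules.module_names() == []
    assert any("emptied" in str(entry.get("note", "")) for entry in modules.filter_log)


# -- quality Z --------------------------------------------------------------

def test_quality_z_planted_block_exceeds_ten(block_sim):
    _, _, pp, _ = block_sim
    params = NetworkParams(beta=6, min_module_size=40, n_pseudo=500, seed=0)
    modules, to = network.iterative_density_filter(pp, params)
    z = network.module_quality_z(to, modules.labels,
                                 n_perm=100, seed=0)
    assert all(v > 10 for v in z.values())


def test_quality_z_random_labels_small():
    rng = np.random.default_rng(9)
    n = 100
    base = rng.uniform(0.1, 0.3, (n, n))
    to = pd.DataFrame((base + base.T) / 2, index=[f"g{i}" for i in range(n)],
                      columns=[f"g{i}" for i in range(n)])
    np.fill_diagonal(to.values, 1.0)
    small = 0
    for rep in range(20):
        labels = pd.Series(np.random.default_rng(rep).permutation(
            ["a"] * 50 + ["b"] * 50), index=to.index)
        z = network.module_quality_z(to, labels, n_perm=50, seed=rep)
        small += all(abs(v) < 3 for v in z.values())
    assert small / 20 >= 0.8


def test_quality_z_invariant_to_gene_order():
    to = _block_to([40, 40])
    labels = pd.Series(["a"] * 40 + ["b"] * 40, index=to.index)
    z1 = network.module_quality_z(to, labels, n_perm=80, seed=1)
    perm = np.random.default_rng(0).permutation(len(to))
    to2 = to.iloc[perm, perm]
    z2 = network.module_quality_z(to2, labels.loc[to2.index], n_perm=80, seed=1)
    for k in z1:
        assert z1[k] == pytest.approx(z2[k], rel=0.3)  # same scale, resampled


# -- module-trait and ME-colony analyses ------------------------------------

@pytest.fixture(scope="module")
def fitted_modules(block_sim):
    _, traits, pp, truth = block_sim
    params = NetworkParams(beta=6, min_module_size=40, n_pseudo=500, seed=0)
    modules, to = network.iterative_density_filter(pp, params)
    return traits, pp.subset(genes=modules.labels.index), modules


def test_module_trait_analysis_outputs(fitted_modules):
    traits, m, modules = fitted_modules
    trait_r = pd.DataFrame(
        {"r_sample_humidity": np.random.default_rng(0).uniform(-0.5, 0.5, m.n_genes),
         "r_sample_da5ht": np.random.default_rng(1).uniform(-0.5, 0.5, m.n_genes)},
        index=m.gene_ids)
    out = network.module_trait_analysis(modules, m, traits, trait_r=trait_r)
    me = out["me_trait"]
    assert set(me["module"]) == set(modules.module_names())
    assert me["r"].abs().max() <= 1.0
    assert {"slope", "p"} <= set(out["kme_trait_slope"].columns)


def test_me_trait_constant_trait_flagged_missing(fitted_modules):
    traits, m, modules = fitted_modules
    const = traits.copy()
    const["humidity"] = 1.0
    out = network.module_trait_analysis(modules, m, const)
    hum = out["me_trait"].query("trait == 'humidity'")
    assert hum["r"].isna().all()


def test_trait_linked_module_me_correlates_with_trait(large_sim):
    """The humidity-linked planted module's eigengene tracks the trait more
    strongly than the unlinked module's."""
    _, traits, pp, truth = large_sim
    labels = truth.module_label.reindex(pp.gene_ids).fillna("none")
    modules = network.ModuleSet(labels.replace({"none": network.GREY}))
    modules = network._attach_summaries(pp, modules)
    out = network.module_trait_analysis(modules, pp, traits)
    me = out["me_trait"].set_index(["module", "trait"])
    linked = abs(me.loc[("M1", "humidity"), "r"])
    unlinked = abs(me.loc[("M2", "humidity"), "r"])
    assert linked > unlinked
    assert linked > 0.5


def test_me_colony_comparison_shapes_and_power():
    """A colony-shifted eigengene yields ANOVA p < 0.01; the contrast table
    has C(C,2) rows per module."""
    rng = np.random.default_rng(11)
    k, per = 4, 8
    cidx = np.repeat(np.arange(k), per)
    samples = [f"s{i}" for i in range(k * per)]
    colonies = pd.Series([f"C{c}" for c in cidx], index=samples)
    shifts = np.array([0.0, 2.0, 0.0, 0.0])
    eig = shifts[cidx] + rng.normal(0, 1.0, k * per)
    eig /= np.linalg.norm(eig)
    modules = network.ModuleSet(
        pd.Series(["a"] * 10, index=[f"g{i}" for i in range(10)]),
        eigengenes=pd.DataFrame([eig], index=["a"], columns=samples))
    anova, contrasts = network.me_colony_comparison(modules, colonies)
    assert anova.loc["a", "p"] < 0.01
    assert len(contrasts) == k * (k - 1) // 2


def test_me_colony_comparison_null_calibrated():
    rng = np.random.default_rng(12)
    k, per = 4, 8
    cidx = np.repeat(np.arange(k), per)
    samples = [f"s{i}" for i in range(k * per)]
    colonies = pd.Series([f"C{c}" for c in cidx], index=samples)
    ps = []
    for rep in range(100):
        eig = rng.normal(size=k * per)
        modules = network.ModuleSet(
            pd.Series(["a"] * 5, index=[f"g{i}" for i in range(5)]),
            eigengenes=pd.DataFrame([eig], index=["a"], columns=samples))
        anova, _ = network.me_colony_comparison(modules, colonies)
        ps.append(anova.loc["a", "p"])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_dendrogram_newick_roundtrips_heights():
    """The Newick export reproduces the merge heights: each leaf's root
    distance equals the root merge height, and the topology parses."""
    import io as _io
    from Bio import Phylo
    to = _block_to([6, 6])
    dist = 1.0 - to.to_numpy()
    np.fill_diagonal(dist, 0.0)
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform
    Z = linkage(squareform(dist, checks=False), method="average")
    nwk = network.dendrogram_to_newick(Z, to.index)
    tree = Phylo.read(_io.StringIO(nwk), "newick")
    assert tree.count_terminals() == 12
    root_h = Z[-1, 2]
    for leaf in tree.get_terminals():
        assert tree.distance(tree.root, leaf) == pytest.approx(root_h, abs=1e-5)
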