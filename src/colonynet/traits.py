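"""Colony structure and expression-trait association statistics.

Covers sample ordination (PCA, LDA on retained PCs), a k-nearest-neighbor
sample distance network with a nestmate-edge permutation test, per-gene
Pearson correlation of expression with colony traits computed two ways
(per-sample with the colony trait replicated to nestmates, N = samples;
and on colony mean expression, N = colonies), their agreement, per-gene
one-way among/within-colony F statistics, and one-sample t tests on
candidate gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .matrix import ExpressionMatrix


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def pca_samples(m: ExpressionMatrix, k: int = 30) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on gene-centered log expression.

    Returns (scores: samples x k, variance_explained per component).
    ``k`` greater than the matrix rank is truncated.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = m.values.to_numpy(float).T  # samples x genes
    X = X - X.mean(axis=0)
    k_eff = max(1, min(k, X.shape[0] - 1, X.shape[1]))
    pca = PCA(n_components=k_eff, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=m.sample_ids, columns=cols),
        pca.explained_variance_ratio_,
    )


def lda_on_pcs(scores: pd.DataFrame, labels: pd.Series) -> tuple[pd.DataFrame, LinearDiscriminantAnalysis]:
    """Linear discriminant analysis of colony labels on PC scores.

    Returns per-sample projections on at most (n_labels - 1) discriminant
    axes, plus the fitted model.
    """
    labels = labels.loc[scores.index]
    counts = labels.value_counts()
    if (counts < 2).any():
        bad = counts.index[counts < 2].tolist()
        raise ValueError(f"labels with a single sample: {bad}")
    if counts.size < 2:
        raise ValueError("need at least 2 labels")
    lda = LinearDiscriminantAnalysis()
    proj = lda.fit_transform(scores.to_numpy(float), labels.to_numpy())
    cols = [f"LD{i + 1}" for i in range(proj.shape[1])]
    return pd.DataFrame(proj, index=scores.index, columns=cols), lda


def sample_distance_network(
    m: ExpressionMatrix,
    k_neighbors: int = 3,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[nx.Graph, float, float]:
    """k-nearest-neighbor sample graph under 1 - Pearson correlation.

    Each sample is linked to its ``k_neighbors`` most correlated samples;
    edges are undirected and deduplicated. Returns the graph, the fraction
    of edges joining nestmates (same colony), and a permutation p-value
    from shuffling colony labels over nodes.
    """
    if k_neighbors >= m.n_samples:
        raise ValueError("k_neighbors must be below n_samples")
    X = m.values.to_numpy(float).T
    cor = np.corrcoef(X)
    dist = 1.0 - cor
    np.fill_diagonal(dist, np.inf)
    g = nx.Graph()
    samples = list(m.sample_ids)
    colonies = m.colonies()
    g.add_nodes_from((s, {"colony": colonies[s]}) for s in samples)
    for i, s in enumerate(samples):
        for j in np.argsort(dist[i], kind="stable")[:k_neighbors]:
            g.add_edge(s, samples[j], distance=float(dist[i, j]))

    edges = list(g.edges())
    labels = colonies.to_numpy()
    idx = {s: i for i, s in enumerate(samples)}
    pairs = np.array([(idx[a], idx[b]) for a, b in edges])
    observed = float(np.mean(labels[pairs[:, 0]] == labels[pairs[:, 1]]))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if np.mean(perm[pairs[:, 0]] == perm[pairs[:, 1]]) >= observed:
            count += 1
    pval = (count + 1) / (n_perm + 1)
    return g, observed, pval


# ---------------------------------------------------------------------------
# expression-trait correlation
# ---------------------------------------------------------------------------

def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of every row of X against y; rows with zero variance NaN."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _trait_vector(m: ExpressionMatrix, traits: pd.DataFrame, trait: str) -> np.ndarray:
    colonies = m.colonies()
    missing = set(colonies) - set(traits.index)
    if missing:
        raise ValueError(f"traits missing colonies: {sorted(missing)}")
    return traits.loc[colonies, trait].to_numpy(float)


def per_sample_trait_correlation(
    m: ExpressionMatrix, traits: pd.DataFrame, trait: str
) -> pd.Series:
    """Per-gene Pearson r between expression and the colony trait
    replicated to every nestmate sample (one point per sample)."""
    y = _trait_vector(m, traits, trait)
    r = _pearson_rows(m.values.to_numpy(float), y)
    return pd.Series(r, index=m.gene_ids, name=f"r_sample_{trait}")


def colony_mean_trait_correlation(
    m: ExpressionMatrix, traits: pd.DataFrame, trait: str
) -> pd.Series:
    """Per-gene Pearson r between colony mean expression and the colony
    trait (one point per colony)."""
    _trait_vector(m, traits, trait)  # validates coverage
    means = m.values.T.groupby(m.colonies()).mean().T  # genes x colonies
    y = traits.loc[means.columns, trait].to_numpy(float)
    r = _pearson_rows(means.to_numpy(float), y)
    return pd.Series(r, index=m.gene_ids, name=f"r_colony_{trait}")


def correlation_method_agreement(
    r_sample: pd.Series, r_colony: pd.Series
) -> tuple[float, float, float]:
    """Agreement between the two trait-correlation estimators.

    Returns (Pearson r, R^2, two-sided p) over genes with both estimates.
    """
    df = pd.concat([r_sample, r_colony], axis=1).dropna()
    if len(df) < 3:
        raise ValueError("fewer than 3 complete pairs")
    res = stats.pearsonr(df.iloc[:, 0], df.iloc[:, 1])
    return float(res.statistic), float(res.statistic**2), float(res.pvalue)


def per_gene_colony_F(m: ExpressionMatrix) -> pd.DataFrame:
    """One-way ANOVA of expression across colonies, per gene.

    F = among-colony MS / within-colony MS with df = (k-1, N-k); genes
    with zero within-colony variance report F = +inf and p = 0.
    """
    colonies = m.colonies()
    groups = colonies.unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 colonies")
    sizes = colonies.value_counts()
    if (sizes < 2).any():
        raise ValueError("every colony needs at least 2 samples")
    X = m.values.to_numpy(float)
    N, k = m.n_samples, len(groups)
    grand = X.mean(axis=1)
    ss_among = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    for g in groups:
        idx = (colonies == g).to_numpy()
        sub = X[:, idx]
        mu = sub.mean(axis=1)
        ss_among += idx.sum() * (mu - grand) ** 2
        ss_within += ((sub - mu[:, None]) ** 2).sum(axis=1)
    df1, df2 = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_among / df1) / (ss_within / df2)
    F = np.where(ss_within == 0, np.inf, F)
    p = stats.f.sf(F, df1, df2)
    p = np.where(np.isinf(F), 0.0, p)
    return pd.DataFrame({"F": F, "p": p, "df1": df1, "df2": df2}, index=m.gene_ids)


def candidate_list_test(
    r_values: pd.Series, gene_list: list[str] | pd.Index
) -> tuple[float, int, float, float]:
    """Two-sided one-sample t test that a candidate list's mean trait
    correlation differs from zero.

    Returns (t, df, p_two_sided, mean_r); genes missing from ``r_values``
    or with missing r are dropped.
    """
    r = r_values.reindex(pd.Index(gene_list)).dropna()
    if len(r) < 2:
        raise ValueError("fewer than 2 usable genes in list")
    res = stats.ttest_1samp(r.to_numpy(float), 0.0)
    return float(res.statistic), int(len(r) - 1), float(res.pvalue), float(r.mean())


@dataclass
class TraitCorrelationTable:
    """Per gene x trait correlation summary used downstream."""

    table: pd.DataFrame  # columns: r_sample_<t>, r_colony_<t>, F, p_F

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def summary_coefficient(self, trait: str) -> pd.Series:
        """The per-trait summary coefficient: the per-sample estimator."""
        return self.table[f"r_sample_{trait}"]


def trait_correlation_table(
    m: ExpressionMatrix, traits: pd.DataFrame
) -> TraitCorrelationTable:
    """Assemble r_sample and r_colony for both traits plus the colony F."""
    pieces = []
    for trait in traits.columns:
        pieces.append(per_sample_trait_correlation(m, traits, trait))
        pieces.append(colony_mean_trait_correlation(m, traits, trait))
    anova = per_gene_colony_F(m)
    table = pd.concat(pieces, axis=1)
    table["F"] = anova["F"]
    table["p_F"] = anova["p"]
    return TraitCorrelationTable(table)
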