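"""Signed weighted coexpression network analysis.

Builds a signed adjacency ``((1 + cor)/2)**beta`` from per-gene Pearson
correlations, derives the topological overlap (TO) matrix, clusters genes
by average linkage on 1 - TO with a dynamic-height tree cut, and
summarizes modules by eigengenes (first principal component of the module
submatrix) and eigengene-based connectivity (kME). Module credibility is
assessed by comparing each module's density (mean within-module TO)
against pseudo-modules of matched size drawn at random from the network;
modules failing the density test are removed and the network rebuilt,
iterating until every module passes and no unassigned genes remain. A
label-permutation quality Z score is reported per surviving module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrix import ExpressionMatrix

MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)
GREY = "grey"


@dataclass
class NetworkParams:
    beta: int = 12
    min_module_size: int = 80
    n_pseudo: int = 10_000
    density_alpha: float = 0.01
    split_gap: float = 0.01
    kme_rescue: float = 0.6
    max_rounds: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.n_pseudo < 100:
            raise ValueError("n_pseudo must be >= 100")


@dataclass
class ModuleSet:
    """Module labels plus per-module summaries."""

    labels: pd.Series                      # gene -> color or "grey"
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # module x sample
    kme: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    density: dict[str, float] = field(default_factory=dict)
    density_p: dict[str, float] = field(default_factory=dict)
    quality_z: dict[str, float] = field(default_factory=dict)
    linkage_matrix: np.ndarray | None = None
    filter_log: list[dict] = field(default_factory=list)

    def module_names(self) -> list[str]:
        return [c for c in self.labels.unique() if c != GREY]

    def module_genes(self, name: str) -> pd.Index:
        return self.labels.index[self.labels == name]

    def sizes(self) -> dict[str, int]:
        return {c: int((self.labels == c).sum()) for c in self.module_names()}

    def summary(self) -> pd.DataFrame:
        names = sorted(self.module_names(), key=lambda c: -int((self.labels == c).sum()))
        return pd.DataFrame(
            {
                "size": [int((self.labels == c).sum()) for c in names],
                "density": [self.density.get(c, np.nan) for c in names],
                "density_p": [self.density_p.get(c, np.nan) for c in names],
                "quality_z": [self.quality_z.get(c, np.nan) for c in names],
            },
            index=pd.Index(names, name="module"),
        )


# ---------------------------------------------------------------------------
# adjacency and topological overlap
# ---------------------------------------------------------------------------

def signed_adjacency(m: ExpressionMatrix, beta: int) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + cor_ij) / 2) ** beta, zero diagonal.

    Negatively correlated gene pairs map near zero, so the network keeps
    only concordant coexpression.
    """
    X = m.values.to_numpy(float)
    if X.std(axis=1).min() == 0:
        bad = m.gene_ids[X.std(axis=1) == 0][:5].tolist()
        raise ValueError(f"zero-variance genes (filter upstream): {bad}")
    cor = np.corrcoef(X)
    if not np.isfinite(cor).all():
        i, j = np.argwhere(~np.isfinite(cor))[0]
        raise ValueError(f"non-finite correlation for pair ({m.gene_ids[i]}, {m.gene_ids[j]})")
    a = ((1.0 + np.clip(cor, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=m.gene_ids, columns=m.gene_ids)


def scale_free_fit(adjacency: pd.DataFrame, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of the connectivity distribution.

    Bins the per-gene connectivity k, regresses log10 p(k) on log10 k and
    returns (signed R^2, slope) where the R^2 is negated for a positive
    slope (scale-free networks have a falling tail).
    """
    k = adjacency.to_numpy(float).sum(axis=1)
    if np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity: all genes equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k > 0 and freq > 0:
            log_k.append(np.log10(mean_k))
            log_p.append(np.log10(freq))
    if len(log_k) < 3:
        raise ValueError("too few occupied connectivity bins")
    res = stats.linregress(log_k, log_p)
    r2 = float(res.rvalue**2)
    return (-r2 if res.slope > 0 else r2), float(res.slope)


def pick_soft_threshold(
    m: ExpressionMatrix,
    candidate_betas: tuple = (1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 18, 20),
    fit_target: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free topology criterion.

    Returns the smallest beta whose signed fit R^2 reaches ``fit_target``
    (falling back to the best-fitting beta), plus the full fit table.
    """
    if not candidate_betas:
        raise ValueError("empty candidate set")
    rows = []
    for beta in candidate_betas:
        adj = signed_adjacency(m, beta)
        r2, slope = scale_free_fit(adj)
        rows.append({"beta": beta, "signed_r2": r2, "slope": slope,
                     "mean_k": float(adj.to_numpy().sum(axis=1).mean())})
    table = pd.DataFrame(rows).set_index("beta")
    ok = table.index[table["signed_r2"] >= fit_target]
    beta = int(ok[0]) if len(ok) else int(table["signed_r2"].idxmax())
    return beta, table


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TO_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, TO_ii = 1; requires a symmetric, non-negative adjacency with
    zero diagonal.
    """
    a = adjacency.to_numpy(float)
    if (a < 0).any():
        raise ValueError("adjacency has negative entries")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency not symmetric")
    if not np.allclose(np.diag(a), 0.0):
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        to = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(to, 1.0)
    to = np.clip(to, 0.0, 1.0)
    return pd.DataFrame(to, index=adjacency.index, columns=adjacency.columns)


# ---------------------------------------------------------------------------
# clustering and tree cutting
# ---------------------------------------------------------------------------

def _persistent_branches(
    Z: np.ndarray, n: int, min_size: int, split_gap: float
) -> list[np.ndarray]:
    """Select dendrogram branches that behave like modules.

    A branch qualifies when it holds at least ``min_size`` leaves and
    persists -- stays unmerged -- over a height span greater than
    ``split_gap`` before its parent merge absorbs it. Genuine modules
    complete their internal merges low and then wait a long time before
    joining the rest of the tree; branches carved out of a structureless
    region are absorbed almost immediately. When a qualifying branch
    contains another qualifying branch the finer (descendant) one wins,
    which splits large branches showing real internal structure. The root
    is never a module (a module must be distinct from something).
    Returns leaf-index arrays for the selected branches.
    """
    n_internal = Z.shape[0]
    heights = Z[:, 2]
    sizes = Z[:, 3].astype(int)
    parent = np.full(2 * n - 1, -1)
    for i in range(n_internal):
        parent[int(Z[i, 0])] = n + i
        parent[int(Z[i, 1])] = n + i

    def persistence(node: int) -> float:
        p = parent[node]
        if p < 0:
            return 0.0  # root
        return float(heights[p - n] - heights[node - n])

    qualifying = [
        n + i for i in range(n_internal)
        if sizes[i] >= min_size and persistence(n + i) > split_gap
    ]
    # keep only the finest qualifying branches: drop ancestors of others
    ancestors: set[int] = set()
    for node in qualifying:
        p = parent[node]
        while p >= 0:
            ancestors.add(int(p))
            p = parent[p]
    selected = [node for node in qualifying if node not in ancestors]

    def leaves(node: int) -> np.ndarray:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend((int(Z[v - n, 0]), int(Z[v - n, 1])))
        return np.array(sorted(out))

    return [leaves(node) for node in selected]


def cluster_and_cut(
    to: pd.DataFrame,
    min_module_size: int = 80,
    split_gap: float = 0.01,
) -> ModuleSet:
    """Average-linkage clustering on 1 - TO with a persistence-based cut.

    Modules are the persistent dendrogram branches found by
    :func:`_persistent_branches`; everything else — including the whole
    network when no branch persists — is labeled grey. Surviving clusters
    are named by color in decreasing size order.
    """
    genes = to.index
    if len(genes) < min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes labeled grey")
        return ModuleSet(pd.Series(GREY, index=genes, name="module"))
    dist = 1.0 - to.to_numpy(float)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    groups = _persistent_branches(Z, len(genes), min_module_size, split_gap)
    groups.sort(key=len, reverse=True)
    labels = pd.Series(GREY, index=genes, name="module")
    for i, g in enumerate(groups):
        color = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
        labels.iloc[g] = color
    return ModuleSet(labels, linkage_matrix=Z)


def dendrogram_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Serialize a linkage matrix as a Newick string with branch lengths.

    Each branch length is the drop in merge height from parent to child
    (leaves extend down to height 0), so the tree reproduces the 1 - TO
    merge heights.
    """
    names = list(leaf_names)
    n = len(names)
    if Z.shape[0] != n - 1:
        raise ValueError("linkage matrix does not match the number of leaves")
    heights = Z[:, 2]

    def node_height(v: int) -> float:
        return 0.0 if v < n else float(heights[v - n])

    # bottom-up: children of internal node i always have smaller indices
    rep: dict[int, str] = {i: name for i, name in enumerate(names)}
    for i in range(n - 1):
        left, right = int(Z[i, 0]), int(Z[i, 1])
        h = float(heights[i])
        rep[n + i] = (f"({rep.pop(left)}:{h - node_height(left):.6g},"
                      f"{rep.pop(right)}:{h - node_height(right):.6g})")
    return rep[2 * n - 2] + ";"


# ---------------------------------------------------------------------------
# eigengenes and kME
# ---------------------------------------------------------------------------

def module_eigengene(m: ExpressionMatrix, module_genes) -> pd.Series:
    """First principal component of the standardized module submatrix.

    Returned as a unit-norm per-sample vector, sign-oriented so that the
    mean correlation of member genes with the eigengene is non-negative.
    """
    genes = pd.Index(module_genes)
    if len(genes) < 2:
        raise ValueError("module must have at least 2 genes")
    X = m.values.loc[genes].to_numpy(float)
    sd = X.std(axis=1)
    if (sd == 0).all():
        raise ValueError("zero-variance module")
    X = X[sd > 0]
    Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(Xs, full_matrices=False)
    eig = vt[0]
    member_cor = _row_correlations(X, eig)
    if np.nanmean(member_cor) < 0:
        eig = -eig
    return pd.Series(eig, index=m.sample_ids, name="ME")


def _row_correlations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def kme(m: ExpressionMatrix, eigengene: pd.Series) -> pd.Series:
    """Eigengene-based connectivity: each gene's Pearson correlation with
    the module eigengene."""
    r = _row_correlations(m.values.to_numpy(float), eigengene.loc[m.sample_ids].to_numpy())
    return pd.Series(r, index=m.gene_ids, name="kME")


# ---------------------------------------------------------------------------
# density and the permutation filter
# ---------------------------------------------------------------------------

def module_density(to: pd.DataFrame, module_genes) -> float:
    """Mean off-diagonal topological overlap within a module."""
    genes = pd.Index(module_genes)
    if len(genes) < 2:
        raise ValueError("module must have at least 2 genes")
    sub = to.loc[genes, genes].to_numpy(float)
    n = len(genes)
    return float((sub.sum() - np.trace(sub)) / (n * (n - 1)))


def density_permutation_test(
    to: pd.DataFrame, module_genes, n_pseudo: int = 10_000, seed: int = 0
) -> float:
    """Permutation p for module density against random pseudo-modules.

    p = #{pseudo-module density > observed} / n_pseudo, with pseudo-modules
    of matched size drawn uniformly without replacement from the network's
    genes. The strict '>' means a module as dense as every pseudo-module
    gets p = 0.
    """
    genes = pd.Index(module_genes)
    n_genes = to.shape[0]
    if len(genes) > n_genes:
        raise ValueError("module larger than the network")
    observed = module_density(to, genes)
    if len(genes) == n_genes:
        warnings.warn("module spans the whole network; p = 0 by convention")
        return 0.0
    rng = np.random.default_rng(seed)
    A = to.to_numpy(float)
    size = len(genes)
    count = 0
    for _ in range(n_pseudo):
        idx = rng.choice(n_genes, size=size, replace=False)
        sub = A[np.ix_(idx, idx)]
        dens = (sub.sum() - np.trace(sub)) / (size * (size - 1))
        if dens > observed:
            count += 1
    return count / n_pseudo


def rescue_grey_genes(
    m: ExpressionMatrix, modules: ModuleSet, kme_rescue: float = 0.6
) -> ModuleSet:
    """Assign unclustered genes to the module they best conform to.

    The dendrogram cut strands genes that merge late even when they belong
    to a module; mirroring the assignment stage of dynamic tree cutting,
    each grey gene joins the module whose eigengene it correlates with
    best, provided that kME reaches ``kme_rescue``. Genes below the bar
    stay grey.
    """
    names = modules.module_names()
    grey = modules.labels.index[modules.labels == GREY]
    if not names or len(grey) == 0:
        return modules
    eigs = {name: module_eigengene(m, modules.module_genes(name)) for name in names}
    sub = m.subset(genes=grey)
    kmat = pd.DataFrame({name: kme(sub, eig) for name, eig in eigs.items()})
    best = kmat.idxmax(axis=1)
    best_k = kmat.max(axis=1)
    labels = modules.labels.copy()
    take = best_k >= kme_rescue if kme_rescue > 0 else pd.Series(True, index=best.index)
    labels.loc[best.index[take]] = best[take]
    return ModuleSet(labels, linkage_matrix=modules.linkage_matrix)


def _attach_summaries(m: ExpressionMatrix, modules: ModuleSet) -> ModuleSet:
    """Compute eigengenes and own-module kME for every module."""
    eigs, kmes = {}, {}
    for name in modules.module_names():
        genes = modules.module_genes(name)
        eig = module_eigengene(m, genes)
        eigs[name] = eig
        sub = m.subset(genes=genes)
        kmes[name] = kme(sub, eig)
    modules.eigengenes = pd.DataFrame(eigs).T if eigs else pd.DataFrame()
    modules.kme = pd.concat(kmes.values()) if kmes else pd.Series(dtype=float)
    return modules


def iterative_density_filter(
    m: ExpressionMatrix, params: NetworkParams
) -> tuple[ModuleSet, pd.DataFrame | None]:
    """Build the network, test module densities, drop weak modules and
    grey genes, and rebuild until a fixed point.

    Returns the final ModuleSet (with eigengenes, kME, densities and p's
    attached) and the final TO matrix (None when no genes survive).
    """
    current = m
    log: list[dict] = []
    for round_no in range(1, params.max_rounds + 1):
        if current.n_genes < max(params.min_module_size, 3):
            empty = ModuleSet(pd.Series(dtype=object, name="module"))
            empty.filter_log = log + [{"round": round_no, "note": "network emptied"}]
            return empty, None
        adj = signed_adjacency(current, params.beta)
        to = topological_overlap(adj)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            modules = cluster_and_cut(to, params.min_module_size, params.split_gap)
            if modules.module_names():
                modules = rescue_grey_genes(current, modules, params.kme_rescue)
        names = modules.module_names()
        for name in names:
            genes = modules.module_genes(name)
            modules.density[name] = module_density(to, genes)
            modules.density_p[name] = density_permutation_test(
                to, genes, params.n_pseudo, seed=params.seed + round_no)
        failing = [n for n in names if modules.density_p[n] > params.density_alpha]
        grey = modules.labels.index[modules.labels == GREY]
        log.append({"round": round_no, "n_genes": current.n_genes,
                    "n_modules": len(names), "n_failing": len(failing),
                    "n_grey": len(grey)})
        straggler_cap = max(5, int(0.02 * current.n_genes))
        if not failing and names:
            if 0 < len(grey) <= straggler_cap:
                # every module is credible and only a small grey tail is
                # left: absorb the stragglers into their best-conforming
                # module rather than looping on a shrinking tail, so the
                # surviving gene set is a fixed point
                modules = rescue_grey_genes(current, modules, kme_rescue=0.0)
                for name in modules.module_names():
                    genes = modules.module_genes(name)
                    modules.density[name] = module_density(to, genes)
                    modules.density_p[name] = density_permutation_test(
                        to, genes, params.n_pseudo, seed=params.seed + round_no)
                log[-1]["n_grey_absorbed"] = len(grey)
            # terminate by dropping the remaining unassigned genes: the
            # pseudo-module null is defined against the background, so the
            # network is not re-derived from module genes alone
            keep_genes = modules.labels.index[modules.labels != GREY]
            log[-1]["n_grey_dropped"] = int(current.n_genes - len(keep_genes))
            modules.labels = modules.labels.loc[keep_genes]
            modules = _attach_summaries(current.subset(genes=keep_genes), modules)
            modules.filter_log = log
            return modules, to
        drop = set(grey)
        for n in failing:
            drop.update(modules.module_genes(n))
        keep = [g for g in current.gene_ids if g not in drop]
        if not names or not keep:
            empty = ModuleSet(pd.Series(dtype=object, name="module"))
            empty.filter_log = log + [{"round": round_no + 1, "note": "network emptied"}]
            return empty, None
        if len(keep) == current.n_genes:
            # nothing to drop but some module failed: no further progress
            modules = _attach_summaries(current, modules)
            modules.filter_log = log
            return modules, to
        current = current.subset(genes=keep, stage=f"density_filter_round{round_no}")
    raise RuntimeError(f"density filter did not converge; log: {log}")


def module_quality_z(
    to: pd.DataFrame, labels: pd.Series, n_perm: int = 200, seed: int = 0
) -> dict[str, float]:
    """Label-permutation quality Z per module.

    Z = (observed density - mean permuted density) / SD permuted density,
    permuting the gene-to-module assignment while keeping module sizes.
    Z > 10 is read as strong evidence of a dense, distinct module. Genes
    of the network absent from ``labels`` count as unassigned background.
    """
    labels = labels.reindex(to.index).fillna(GREY)
    names = [c for c in labels.unique() if c != GREY]
    rng = np.random.default_rng(seed)
    A = to.to_numpy(float)
    lab_arr = labels.to_numpy()
    out = {}

    def densities(arr) -> dict[str, float]:
        d = {}
        for name in names:
            idx = np.where(arr == name)[0]
            sub = A[np.ix_(idx, idx)]
            d[name] = (sub.sum() - np.trace(sub)) / (len(idx) * (len(idx) - 1))
        return d

    obs = densities(lab_arr)
    perm = {name: np.empty(n_perm) for name in names}
    for b in range(n_perm):
        shuffled = rng.permutation(lab_arr)
        d = densities(shuffled)
        for name in names:
            perm[name][b] = d[name]
    for name in names:
        sd = perm[name].std()
        out[name] = float((obs[name] - perm[name].mean()) / sd) if sd > 0 else np.inf
    return out


# ---------------------------------------------------------------------------
# module-trait and module-colony analyses
# ---------------------------------------------------------------------------

def module_trait_analysis(
    modules: ModuleSet,
    m: ExpressionMatrix,
    traits: pd.DataFrame,
    trait_r: pd.DataFrame | None = None,
    dnds_decile: pd.Series | None = None,
) -> dict:
    """Relate modules to colony traits.

    Returns a dict with: ``me_trait`` (per module x trait: Pearson r and p
    of the eigengene against the trait replicated to samples),
    ``kme_trait_slope`` (per module x trait: slope and p of member |trait
    r| on kME, when ``trait_r`` columns ``r_sample_<trait>`` are given),
    and ``module_constraint_regression`` (across modules: mean trait r
    regressed on mean dN/dS decile, when ``dnds_decile`` is given).
    """
    colonies = m.colonies()
    missing = set(colonies) - set(traits.index)
    if missing:
        raise ValueError(f"missing trait values for colonies: {sorted(missing)}")
    rows = []
    for name in modules.module_names():
        eig = modules.eigengenes.loc[name, m.sample_ids].to_numpy(float)
        for trait in traits.columns:
            y = traits.loc[colonies, trait].to_numpy(float)
            if np.std(y) == 0:
                rows.append({"module": name, "trait": trait, "r": np.nan, "p": np.nan})
                continue
            res = stats.pearsonr(eig, y)
            rows.append({"module": name, "trait": trait,
                         "r": float(res.statistic), "p": float(res.pvalue)})
    out = {"me_trait": pd.DataFrame(rows)}

    if trait_r is not None:
        srows = []
        for name in modules.module_names():
            genes = modules.module_genes(name)
            k = modules.kme.loc[genes]
            for trait in traits.columns:
                col = f"r_sample_{trait}"
                if col not in trait_r.columns:
                    continue
                y = trait_r.loc[genes, col].abs()
                ok = k.notna() & y.notna()
                if ok.sum() < 3:
                    continue
                res = stats.linregress(k[ok], y[ok])
                srows.append({"module": name, "trait": trait,
                              "slope": float(res.slope), "p": float(res.pvalue),
                              "r": float(res.rvalue)})
        out["kme_trait_slope"] = pd.DataFrame(srows)

    if dnds_decile is not None and trait_r is not None:
        crows = []
        for name in modules.module_names():
            genes = modules.module_genes(name)
            dec = dnds_decile.reindex(genes).dropna()
            row = {"module": name, "mean_decile": float(dec.mean()) if len(dec) else np.nan}
            for trait in traits.columns:
                col = f"r_sample_{trait}"
                if col in trait_r.columns:
                    row[f"mean_r_{trait}"] = float(trait_r.loc[genes, col].mean())
            crows.append(row)
        cm = pd.DataFrame(crows).dropna()
        reg = {}
        for trait in traits.columns:
            col = f"mean_r_{trait}"
            if col in cm.columns and len(cm) >= 3:
                res = stats.linregress(cm["mean_decile"], cm[col])
                reg[trait] = {"slope": float(res.slope), "r2": float(res.rvalue**2),
                              "p": float(res.pvalue), "n": int(len(cm))}
        out["module_constraint_table"] = cm
        out["module_constraint_regression"] = reg
    return out


def me_colony_comparison(
    modules: ModuleSet, colonies: pd.Series, correction: str = "fdr_bh"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare module eigengene expression across colonies.

    Returns (per-module one-way ANOVA table, pairwise Welch-t contrast
    table with the configured multiple-testing correction). Singleton
    colonies are excluded with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    counts = colonies.value_counts()
    keep = counts.index[counts >= 2]
    if len(keep) < len(counts):
        warnings.warn(f"excluding singleton colonies: {sorted(set(counts.index) - set(keep))}")
    if len(keep) < 2:
        raise ValueError("need at least 2 colonies with >= 2 samples")
    use = colonies[colonies.isin(keep)]
    anova_rows, contrast_rows = [], []
    for name in modules.module_names():
        eig = modules.eigengenes.loc[name, use.index]
        groups = [eig[use == c].to_numpy(float) for c in keep]
        F, p = stats.f_oneway(*groups)
        anova_rows.append({"module": name, "F": float(F), "p": float(p)})
        for i in range(len(keep)):
            for j in range(i + 1, len(keep)):
                t, pp = stats.ttest_ind(groups[i], groups[j], equal_var=False)
                contrast_rows.append({"module": name, "colony_a": keep[i],
                                      "colony_b": keep[j], "t": float(t),
                                      "p": float(pp)})
    anova = pd.DataFrame(anova_rows).set_index("module")
    contrasts = pd.DataFrame(contrast_rows)
    if len(contrasts):
        contrasts["p_adj"] = multipletests(contrasts["p"], method=correction)[1]
    return anova, contrasts
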