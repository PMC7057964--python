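"""Sliding-threshold omnibus gene-set enrichment.

For a per-gene ranking (typically a trait-correlation coefficient), a
Fisher's exact (hypergeometric) enrichment test is run at a descending
grid of top-fraction cutoffs (default 50%, 45%, ..., 5%) and the per-
threshold p-values are combined with Fisher's method into a single
omnibus chi-square statistic per term, with df = 2 x number of
thresholds. Terms with fewer than ``min_annotated`` genes in the universe
are excluded; Benjamini-Hochberg correction is applied across terms.

Because the nested thresholds make the per-threshold p-values positively
dependent, the chi-square reference for the combined statistic is
anticonservative in general; an empirical permutation omnibus p is
available as a clearly-labeled alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.049, -0.05), 2))


def read_annotations(path) -> dict[str, set[str]]:
    """Read a two-column gene<TAB>term file into a term -> gene-set map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
    return {t: set(g) for t, g in df.groupby("term")["gene"].apply(list).items()}


def fisher_enrichment(
    selected: set[str], term_genes: set[str], universe: set[str]
) -> tuple[float, float]:
    """One-sided (enrichment) Fisher's exact test for a term in a selection.

    The 2x2 table is {selected&term, selected-term, term-selected,
    neither}; the p-value is the hypergeometric upper tail of the overlap.
    Returns (odds_ratio, p).
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe:
        raise ValueError("selected genes outside the universe")
    term = term_genes & universe
    if not term:
        raise ValueError("term has no genes in the universe")
    a = len(selected & term)
    b = len(selected) - a
    c = len(term) - a
    d = len(universe) - a - b - c
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    # P(X >= a) for X ~ Hypergeom(N=|universe|, K=|term|, n=|selected|)
    p = float(stats.hypergeom.sf(a - 1, len(universe), len(term), len(selected)))
    return odds, min(p, 1.0)


def fisher_combine(pvalues: list[float]) -> tuple[float, int, float]:
    """Fisher's method: X2 = -2 sum(ln p), df = 2k, upper-tail chi-square p."""
    p = np.asarray(pvalues, float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = float(-2.0 * np.log(p).sum())
    df = 2 * len(p)
    return x2, df, float(stats.chi2.sf(x2, df))


@dataclass
class OmnibusResult:
    """Per-term sliding-threshold enrichment results."""

    table: pd.DataFrame  # term, n_annotated, X2, df, p_omnibus, p_corrected
    per_threshold: pd.DataFrame  # term x threshold p-values
    thresholds: tuple = field(default_factory=tuple)
    correction: str = "fdr_bh"

    def significant(self, alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["p_corrected"] < alpha]


def _select_top(ranking: pd.Series, fraction: float, direction: str) -> set[str]:
    """Top (or bottom) fraction of genes by score; ties at the cut are all
    included, so the selection is deterministic and rank-stable."""
    scores = ranking.sort_values(ascending=(direction == "bottom"), kind="stable")
    n = int(np.ceil(fraction * len(scores)))
    cut = scores.iloc[n - 1]
    if direction == "top":
        sel = scores.index[scores >= cut]
    else:
        sel = scores.index[scores <= cut]
    return set(sel)


def omnibus_enrichment(
    ranking: pd.Series,
    annotation: dict[str, set[str]],
    thresholds: tuple = DEFAULT_THRESHOLDS,
    direction: str = "top",
    min_annotated: int = 10,
    correction: str = "fdr_bh",
) -> OmnibusResult:
    """Combine per-threshold enrichment p-values into an omnibus p per term.

    ``ranking`` must cover the gene universe with no missing scores;
    ``thresholds`` are strictly decreasing fractions in (0, 1].
    """
    if ranking.isna().any():
        raise ValueError("ranking contains missing scores")
    th = tuple(float(t) for t in thresholds)
    if any(not 0 < t <= 1 for t in th) or any(a <= b for a, b in zip(th, th[1:])):
        raise ValueError("thresholds must be strictly decreasing fractions in (0, 1]")
    if direction not in ("top", "bottom"):
        raise ValueError("direction must be 'top' or 'bottom'")
    universe = set(ranking.index)

    terms, dropped = {}, 0
    for term, genes in annotation.items():
        inside = genes & universe
        dropped += len(genes) - len(inside)
        if len(inside) >= min_annotated:
            terms[term] = inside
    selections = [_select_top(ranking, t, direction) for t in th]

    rows, pmat = [], {}
    for term, genes in sorted(terms.items()):
        ps = [fisher_enrichment(sel, genes, universe)[1] for sel in selections]
        x2, df, p = fisher_combine(ps)
        rows.append({"term": term, "n_annotated": len(genes),
                     "X2": x2, "df": df, "p_omnibus": p})
        pmat[term] = ps
    if not rows:
        table = pd.DataFrame(
            columns=["n_annotated", "X2", "df", "p_omnibus", "p_corrected"])
        return OmnibusResult(table, pd.DataFrame(columns=list(th)), th, correction)
    table = pd.DataFrame(rows).set_index("term")
    table["p_corrected"] = multipletests(table["p_omnibus"], method=correction)[1]
    per_threshold = pd.DataFrame(pmat, index=list(th)).T
    return OmnibusResult(table, per_threshold, th, correction)


def permutation_omnibus_p(
    ranking: pd.Series,
    term_genes: set[str],
    thresholds: tuple = DEFAULT_THRESHOLDS,
    direction: str = "top",
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical omnibus p for one term: the combined X2 is recomputed on
    permuted gene scores, sidestepping the chi-square independence
    assumption across nested thresholds."""
    universe = set(ranking.index)
    genes = term_genes & universe
    selections = [_select_top(ranking, t, direction) for t in thresholds]
    obs = fisher_combine(
        [fisher_enrichment(sel, genes, universe)[1] for sel in selections])[0]
    rng = np.random.default_rng(seed)
    vals = ranking.to_numpy(float)
    idx = ranking.index
    count = 0
    for _ in range(n_perm):
        perm = pd.Series(rng.permutation(vals), index=idx)
        sels = [_select_top(perm, t, direction) for t in thresholds]
        x2 = fisher_combine(
            [fisher_enrichment(s, genes, universe)[1] for s in sels])[0]
        if x2 >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)
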