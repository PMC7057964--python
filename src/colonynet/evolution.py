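"""Evolutionary-constraint integration.

Consumes a per-species dN/dS table, recodes each species' values into
deciles (1 = most constrained tenth, 10 = least), joins expression
covariates, and tests how coding-sequence constraint relates to trait
correlation and coexpression centrality: a Gaussian identity-link GLM of
the decile response on |trait r|, kME, median TPM and expression SD (an
ordinal-logit alternative is available), one-sample t tests of module
mean deciles against the genomic mean, an in-module vs background
two-sample t test, and per-species decile-on-kME slopes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def decile_recode(values: pd.Series) -> pd.Series:
    """Recode values into deciles 1-10 by rank.

    Bins have near-equal size (within one of n/10); ties that would span a
    bin edge all take the lower decile, and later bins absorb the slack.
    Missing values stay missing. Invariant under any strictly monotone
    transform of the input.
    """
    v = values.dropna()
    if len(v) < 10:
        raise ValueError(f"need at least 10 non-missing values, got {len(v)}")
    order = np.argsort(v.to_numpy(), kind="stable")
    n = len(v)
    # provisional decile by position, then ties collapse to the group min
    provisional = np.empty(n, int)
    provisional[order] = np.floor(np.arange(n) * 10 / n).astype(int) + 1
    prov = pd.Series(provisional, index=v.index)
    dec = prov.groupby(v).transform("min")
    out = pd.Series(np.nan, index=values.index, name="decile")
    out.loc[dec.index] = dec.astype(float)
    return out


def build_dnds_table(
    dnds: pd.DataFrame,
    median_tpm: pd.Series | None = None,
    expr_sd: pd.Series | None = None,
    trait_r: pd.DataFrame | None = None,
    kme: pd.Series | None = None,
    module_label: pd.Series | None = None,
) -> pd.DataFrame:
    """Join per-species deciles with expression covariates.

    Adds ``decile_<species>`` per species and ``decile`` (the cross-species
    per-gene mean decile used as the aggregate constraint measure), plus
    any supplied covariates aligned on gene id.
    """
    table = dnds.copy()
    dec_cols = []
    for sp in dnds.columns:
        col = f"decile_{sp}"
        table[col] = decile_recode(dnds[sp])
        dec_cols.append(col)
    table["decile"] = table[dec_cols].mean(axis=1)
    for name, series in [("median_tpm", median_tpm), ("expr_sd", expr_sd), ("kme", kme)]:
        if series is not None:
            table[name] = series.reindex(table.index)
    if trait_r is not None:
        for col in trait_r.columns:
            if col.startswith("r_sample_"):
                table[f"abs_{col}"] = trait_r[col].abs().reindex(table.index)
    if module_label is not None:
        table["module"] = module_label.reindex(table.index).fillna("none")
    return table


def constraint_glm(
    table: pd.DataFrame,
    response: str = "decile",
    predictors: tuple = ("abs_r_sample_humidity", "abs_r_sample_da5ht",
                         "kme", "median_tpm", "expr_sd"),
    family: str = "gaussian",
    condition_max: float = 1e8,
) -> pd.DataFrame:
    """GLM of the constraint decile on trait correlation and centrality.

    Predictors are standardized before fitting so coefficients are per-SD.
    ``family='gaussian'`` (default) fits an identity-link Gaussian model;
    ``family='ordinal'`` fits a proportional-odds logit on the rounded
    decile for sensitivity analysis. Returns a coefficient table with
    estimate, SE, t/z and two-sided p per predictor.
    """
    cols = [c for c in predictors if c in table.columns]
    if not cols:
        raise ValueError("no requested predictors present in the table")
    data = table[[response, *cols]].dropna()
    if len(data) < 30:
        raise ValueError(f"need >= 30 complete rows, got {len(data)}")
    y = data[response].to_numpy(float)
    if np.std(y) == 0:
        raise ValueError("constant response")
    X = data[cols].to_numpy(float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"constant predictors: {bad}")
    Xs = (X - X.mean(axis=0)) / sd
    cond = np.linalg.cond(Xs.T @ Xs)
    if cond > condition_max:
        raise ValueError(f"predictors nearly collinear (condition {cond:.2e}): {cols}")

    if family == "gaussian":
        model = sm.GLM(y, sm.add_constant(Xs), family=sm.families.Gaussian())
        res = model.fit()
        frame = pd.DataFrame(
            {"estimate": res.params, "se": res.bse, "stat": res.tvalues, "p": res.pvalues},
            index=["const", *cols],
        )
    elif family == "ordinal":
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        model = OrderedModel(np.round(y).astype(int), Xs, distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", disp=False)
        frame = pd.DataFrame(
            {"estimate": res.params[: len(cols)], "se": res.bse[: len(cols)],
             "stat": res.tvalues[: len(cols)], "p": res.pvalues[: len(cols)]},
            index=cols,
        )
    else:
        raise ValueError(f"unknown family {family!r}")
    frame.index.name = "predictor"
    return frame


def module_constraint_test(
    table: pd.DataFrame, module_label: str, min_genes: int = 3
) -> dict:
    """One-sample t test of a module's deciles against the genomic mean.

    The reference is the mean decile over all decile-bearing genes (not a
    fixed 5.5, which ties and missingness can shift). ``direction`` is
    'increased_constraint' for a mean below the genomic mean (lower
    dN/dS), 'decreased_constraint' above it.
    """
    dec = table["decile"].dropna()
    members = dec[table.loc[dec.index, "module"] == module_label]
    if len(members) < min_genes:
        warnings.warn(f"module {module_label} has < {min_genes} decile-bearing genes; skipped")
        return {"module": module_label, "n": int(len(members)), "skipped": True}
    genomic_mean = float(dec.mean())
    mean_dec = float(members.mean())
    if members.std(ddof=1) == 0:
        # degenerate module: identical deciles
        t_stat = 0.0 if mean_dec == genomic_mean else np.inf * np.sign(mean_dec - genomic_mean)
        res = type("R", (), {"statistic": t_stat,
                             "pvalue": 1.0 if t_stat == 0 else 0.0})
    else:
        res = stats.ttest_1samp(members.to_numpy(float), genomic_mean)
    return {
        "module": module_label,
        "n": int(len(members)),
        "mean_decile": mean_dec,
        "genomic_mean": genomic_mean,
        "t": float(res.statistic),
        "df": int(len(members) - 1),
        "p": float(res.pvalue),
        "direction": ("increased_constraint" if mean_dec < genomic_mean
                      else "decreased_constraint"),
        "skipped": False,
    }


def in_module_vs_background_test(table: pd.DataFrame) -> dict:
    """Two-sample t test of deciles: genes in any module vs unassigned.

    A negative t (module mean below background) indicates modules are
    enriched for constrained, low-dN/dS genes.
    """
    dec = table["decile"].dropna()
    in_mod = table.loc[dec.index, "module"] != "none"
    a, b = dec[in_mod], dec[~in_mod]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need >= 3 decile-bearing genes")
    res = stats.ttest_ind(a.to_numpy(float), b.to_numpy(float), equal_var=False)
    return {
        "t": float(res.statistic), "p": float(res.pvalue),
        "mean_in_module": float(a.mean()), "mean_background": float(b.mean()),
        "n_in_module": int(len(a)), "n_background": int(len(b)),
        "direction": ("modules_more_constrained" if a.mean() < b.mean()
                      else "modules_less_constrained"),
    }


def per_species_centrality_slope(
    table: pd.DataFrame, species: list[str] | None = None, min_genes: int = 30
) -> pd.DataFrame:
    """Per-species linear slope of the dN/dS decile on kME.

    A negative slope means more central genes are more constrained in that
    species; the sign-consistency count summarizes cross-species agreement.
    """
    if "kme" not in table.columns:
        raise ValueError("table lacks a kme column")
    if species is None:
        species = [c.removeprefix("decile_") for c in table.columns
                   if c.startswith("decile_")]
    rows = []
    for sp in species:
        sub = table[[f"decile_{sp}", "kme"]].dropna()
        if len(sub) < min_genes:
            continue
        res = stats.linregress(sub["kme"], sub[f"decile_{sp}"])
        rows.append({"species": sp, "slope": float(res.slope),
                     "p": float(res.pvalue), "n": int(len(sub))})
    if not rows:
        return pd.DataFrame(columns=["slope", "p", "n"],
                            index=pd.Index([], name="species"))
    return pd.DataFrame(rows).set_index("species")
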