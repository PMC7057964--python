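"""Expression preprocessing: TPM conversion, gene filtering, log transform,
iterative outlier masking/removal, quantile normalization and batch
adjustment.

The canonical stage order is counts -> TPM -> gene filter -> log2 ->
iterative outlier loop -> quantile normalization -> batch adjustment; each
stage stamps its name into the matrix provenance. Defaults follow the
field's usual choices: genes are dropped when they have zero variance,
median TPM < 0.5, or zeros in more than one third of samples; expression
values more than 3 SD from their gene mean are masked; samples whose mean
inter-sample correlation sits more than 2 SD from the overall mean are
removed, iterating to a fixed point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, FilterReport


def counts_to_tpm(counts: ExpressionMatrix, gene_lengths: pd.Series) -> ExpressionMatrix:
    """Convert raw counts to transcripts per million.

    TPM_g = 1e6 * (c_g / l_g) / sum_h (c_h / l_h), per sample; columns of
    the result sum to 1e6.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected counts, got {counts.unit}")
    lengths = gene_lengths.reindex(counts.gene_ids)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = lengths.index[lengths.isna() | (lengths <= 0)][:5].tolist()
        raise ValueError(f"missing or non-positive gene lengths, e.g. {bad}")
    rate = counts.values.to_numpy(float) / lengths.to_numpy(float)[:, None]
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        raise ValueError(f"all-zero samples: {list(counts.sample_ids[zero])}")
    tpm = pd.DataFrame(1e6 * rate / denom, index=counts.gene_ids, columns=counts.sample_ids)
    return counts.with_values(tpm, unit="tpm", stage="counts_to_tpm")


def filter_genes(
    m: ExpressionMatrix,
    median_tpm_min: float = 0.5,
    zero_fraction_max: float = 1.0 / 3.0,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes with no variance, low median TPM, or too many zeros.

    A gene is removed when its variance is zero, its median TPM is below
    ``median_tpm_min`` (strictly), or it is unexpressed in strictly more
    than ``zero_fraction_max`` of samples; a gene exactly at either
    boundary is retained. The report itemizes removals per rule (a gene
    failing several rules counts once, under the first rule listed).
    """
    if m.unit != "tpm":
        raise ValueError(f"expected tpm, got {m.unit}")
    vals = m.values.to_numpy(float)
    novar = vals.var(axis=1) == 0.0
    lowmed = np.median(vals, axis=1) < median_tpm_min
    toomanyzero = (vals == 0.0).mean(axis=1) > zero_fraction_max
    report = FilterReport(
        n_genes_removed_by_rule={
            "no_variance": int(novar.sum()),
            "low_median_tpm": int((lowmed & ~novar).sum()),
            "zero_fraction": int((toomanyzero & ~novar & ~lowmed).sum()),
        },
        iterations=1,
    )
    keep = ~(novar | lowmed | toomanyzero)
    if not keep.any():
        raise ValueError(f"all genes removed by filters: {report.to_dict()}")
    out = m.subset(genes=m.gene_ids[keep], stage="filter_genes")
    return out, report


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount)."""
    if m.unit != "tpm":
        raise ValueError(f"expected tpm, got {m.unit}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    vals = np.log2(m.values + pseudocount)
    return m.with_values(vals, unit="log2tpm", stage="log_transform")


def _mean_intersample_correlation(vals: np.ndarray) -> np.ndarray:
    """Mean Pearson correlation of each sample with every other sample.
    NaN cells (masked) are imputed by gene means for the correlation pool."""
    filled = vals.copy()
    gene_means = np.nanmean(filled, axis=1)
    nan_r, nan_c = np.where(np.isnan(filled))
    filled[nan_r, nan_c] = gene_means[nan_r]
    keep = filled.std(axis=1) > 0
    cor = np.corrcoef(filled[keep].T)
    np.fill_diagonal(cor, np.nan)
    return np.nanmean(cor, axis=1)


def iterative_outlier_removal(
    m: ExpressionMatrix,
    gene_sd_k: float = 3.0,
    sample_sd_k: float = 2.0,
    max_iter: int = 50,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Mask extreme expression values and drop outlier samples, iterating
    to a fixed point.

    Per iteration: (1) values more than ``gene_sd_k`` SD from their gene's
    mean (over unmasked values) are masked; (2) samples whose mean
    inter-sample Pearson correlation is more than ``sample_sd_k`` SD from
    the overall mean are removed. Stops when an iteration changes nothing.
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples")
    vals = m.values.to_numpy(float).copy()
    if m.mask is not None:
        vals[m.mask.to_numpy(bool)] = np.nan
    samples = list(m.sample_ids)
    report = FilterReport()

    for it in range(1, max_iter + 1):
        changed = False
        # gene-level value masking
        mu = np.nanmean(vals, axis=1, keepdims=True)
        sd = np.nanstd(vals, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            out = np.abs(vals - mu) > gene_sd_k * sd
        out &= ~np.isnan(vals)
        if out.any():
            vals[out] = np.nan
            report.n_values_masked += int(out.sum())
            changed = True
        # sample-level removal
        if vals.shape[1] >= 3:
            mean_cor = _mean_intersample_correlation(vals)
            mu_c, sd_c = mean_cor.mean(), mean_cor.std()
            if sd_c > 0:
                bad = np.abs(mean_cor - mu_c) > sample_sd_k * sd_c
                if bad.any():
                    vals = vals[:, ~bad]
                    samples = [s for s, b in zip(samples, bad) if not b]
                    report.n_samples_removed += int(bad.sum())
                    changed = True
        report.iterations = it
        if not changed:
            break
    else:
        raise RuntimeError(f"outlier loop did not converge: {report.to_dict()}")

    values = pd.DataFrame(vals, index=m.gene_ids, columns=samples)
    mask = values.isna()
    out_m = ExpressionMatrix(
        values.fillna(0.0), m.sample_meta.loc[samples], m.unit,
        mask=mask, provenance=list(m.provenance) + ["iterative_outlier_removal"],
    )
    return out_m, report


def impute_masked(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace masked cells by the gene's unmasked mean and clear the mask."""
    if m.mask is None or not m.mask.to_numpy().any():
        return ExpressionMatrix(m.values.copy(), m.sample_meta.copy(), m.unit,
                                provenance=list(m.provenance))
    vals = m.values.to_numpy(float).copy()
    msk = m.mask.to_numpy(bool)
    vals[msk] = np.nan
    gene_means = np.nanmean(vals, axis=1)
    r, c = np.where(msk)
    vals[r, c] = gene_means[r]
    values = pd.DataFrame(vals, index=m.gene_ids, columns=m.sample_ids)
    return ExpressionMatrix(values, m.sample_meta.copy(), m.unit,
                            provenance=list(m.provenance) + ["impute_masked"])


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the cross-sample mean quantile distribution.

    Each sample's sorted values are replaced by the means of the sorted
    values across samples; within-sample ranks are preserved (ties get the
    mean of their target quantiles).
    """
    if m.mask is not None and m.mask.to_numpy().any():
        raise ValueError("resolve masked cells (impute_masked) before quantile normalization")
    vals = m.values.to_numpy(float)
    order = np.argsort(vals, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n = vals.shape[0]
    rows = np.arange(n)
    for j in range(vals.shape[1]):
        ranks[order[:, j], j] = rows
    mean_quantiles = np.sort(vals, axis=0).mean(axis=1)
    out = mean_quantiles[ranks]
    # average over ties within a sample
    df = pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids)
    for j, col in enumerate(m.sample_ids):
        s = m.values[col]
        if s.duplicated().any():
            df[col] = df[col].groupby(s).transform("mean")
    return m.with_values(df, stage="quantile_normalize")


def batch_adjust(
    m: ExpressionMatrix,
    batch_var: str = "batch",
    protect: list[str] | None = None,
) -> ExpressionMatrix:
    """Per-gene location-scale batch standardization with protected
    biological covariates.

    Protected covariates (metadata columns; strings become indicator sets,
    numerics enter linearly) are fit per gene by least squares and their
    fitted component removed; the residuals are standardized within each
    batch to the pooled residual mean/SD; the protected component is then
    restored. Single-batch input is returned unchanged.
    """
    protect = protect or []
    batches = m.sample_meta[batch_var].astype(str)
    levels = batches.unique()
    if len(levels) == 1:
        return m.with_values(m.values.copy(), stage="batch_adjust")
    counts = batches.value_counts()
    singletons = counts.index[counts < 2].tolist()
    if singletons:
        raise ValueError(f"singleton batch(es): {singletons}")

    # design matrix for protected covariates
    cols = [np.ones(m.n_samples)]
    for key in protect:
        v = m.sample_meta[key]
        if v.dtype.kind in "ifu":
            cols.append(v.to_numpy(float))
        else:
            dummies = pd.get_dummies(v.astype(str), drop_first=True)
            cols.extend(dummies.to_numpy(float).T)
    X = np.column_stack(cols)

    Y = m.values.to_numpy(float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    resid = Y - fitted

    # batch-center first so the pooled scale reflects within-batch spread,
    # not the batch shifts being removed
    centered = resid.copy()
    for lev in levels:
        idx = (batches == lev).to_numpy()
        centered[idx] = resid[idx] - resid[idx].mean(axis=0)
    pooled_sd = centered.std(axis=0)
    pooled_sd[pooled_sd == 0] = 1.0
    adjusted = centered.copy()
    for lev in levels:
        idx = (batches == lev).to_numpy()
        sd = centered[idx].std(axis=0)
        sd[sd == 0] = 1.0
        adjusted[idx] = centered[idx] / sd * pooled_sd
    out = pd.DataFrame((adjusted + fitted).T, index=m.gene_ids, columns=m.sample_ids)
    return m.with_values(out, stage="batch_adjust")


def preprocess_pipeline(
    m: ExpressionMatrix,
    gene_lengths: pd.Series | None = None,
    median_tpm_min: float = 0.5,
    zero_fraction_max: float = 1.0 / 3.0,
    pseudocount: float = 1.0,
    gene_sd_k: float = 3.0,
    sample_sd_k: float = 2.0,
    batch_var: str = "batch",
    protect: list[str] | None = None,
    quantile: bool = True,
) -> tuple[ExpressionMatrix, dict]:
    """Run the full preprocessing chain and collect stage reports."""
    reports: dict = {}
    if m.unit == "counts":
        if gene_lengths is None:
            raise ValueError("counts input requires gene_lengths")
        m = counts_to_tpm(m, gene_lengths)
    m, reports["filter_genes"] = filter_genes(m, median_tpm_min, zero_fraction_max)
    m = log_transform(m, pseudocount)
    m, reports["outliers"] = iterative_outlier_removal(m, gene_sd_k, sample_sd_k)
    m = impute_masked(m)
    if quantile:
        m = quantile_normalize(m)
    m = batch_adjust(m, batch_var=batch_var, protect=protect or ["colony"])
    reports["final_shape"] = {"n_genes": m.n_genes, "n_samples": m.n_samples}
    return m, reports
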