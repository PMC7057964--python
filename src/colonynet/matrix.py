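"""Gene-by-sample expression container shared by every pipeline stage.

The matrix carries its unit state (``counts``, ``tpm`` or ``log2tpm``), the
per-sample metadata (colony, batch, RNA concentration, library) and an
optional per-cell outlier mask, plus a provenance trail recording which
stages have touched it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNITS = ("counts", "tpm", "log2tpm")
META_COLUMNS = ("colony", "batch", "rna_conc", "library")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with sample metadata.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample ids as columns.
    sample_meta
        DataFrame indexed by sample id; must cover every sample and carry
        at least a ``colony`` column (``batch``, ``rna_conc``, ``library``
        are filled with defaults when absent).
    unit
        One of ``counts``, ``tpm``, ``log2tpm``.
    mask
        Optional boolean DataFrame aligned with ``values``; True marks a
        cell masked out by outlier filtering.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    unit: str = "tpm"
    mask: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"sample_meta does not cover samples: {sorted(missing)[:5]}")
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)].copy()
        for col in META_COLUMNS:
            if col not in self.sample_meta.columns:
                self.sample_meta[col] = "batch0" if col == "batch" else 0
        if self.unit == "tpm":
            arr = self.values.to_numpy(float)
            if self.mask is not None:
                arr = np.where(self.mask.to_numpy(bool), np.nan, arr)
            if np.nanmin(arr) < 0:
                raise ValueError("TPM matrix contains negative values")
        if self.mask is not None:
            if not self.mask.index.equals(self.values.index) or not self.mask.columns.equals(
                self.values.columns
            ):
                raise ValueError("mask is not aligned with values")

    # -- convenience views ------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def colonies(self) -> pd.Series:
        """Per-sample colony labels, aligned with ``sample_ids``."""
        return self.sample_meta["colony"]

    def masked_values(self) -> pd.DataFrame:
        """Values with masked cells as NaN."""
        if self.mask is None:
            return self.values
        return self.values.mask(self.mask)

    def with_values(self, values: pd.DataFrame, unit: str | None = None,
                    stage: str | None = None) -> "ExpressionMatrix":
        """Return a copy with replaced values (and optionally unit), keeping
        metadata rows for the new sample set and stamping provenance."""
        meta = self.sample_meta.loc[list(values.columns)]
        mask = None
        if self.mask is not None:
            mask = self.mask.loc[values.index, values.columns]
        prov = list(self.provenance) + ([stage] if stage else [])
        return ExpressionMatrix(values.copy(), meta.copy(), unit or self.unit, mask, prov)

    def subset(self, genes=None, samples=None, stage: str | None = None) -> "ExpressionMatrix":
        vals = self.values
        if genes is not None:
            vals = vals.loc[genes]
        if samples is not None:
            vals = vals[samples]
        return self.with_values(vals, stage=stage)


@dataclass
class FilterReport:
    """Bookkeeping for gene/sample filtering stages."""

    n_genes_removed_by_rule: dict[str, int] = field(default_factory=dict)
    n_samples_removed: int = 0
    n_values_masked: int = 0
    iterations: int = 0

    @property
    def n_genes_removed(self) -> int:
        return sum(self.n_genes_removed_by_rule.values())

    def to_dict(self) -> dict:
        return {
            "n_genes_removed_by_rule": dict(self.n_genes_removed_by_rule),
            "n_genes_removed": self.n_genes_removed,
            "n_samples_removed": self.n_samples_removed,
            "n_values_masked": self.n_values_masked,
            "iterations": self.iterations,
        }
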