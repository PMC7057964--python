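"""Synthetic single-forager brain transcriptome generator.

Emulates the structure the downstream analysis assumes: ~9 colonies with
~10 foragers each, ~10^4 genes, colony-specific expression shifts, planted
coexpression modules driven by latent factors, genes linearly associated
with colony-level traits (humidity sensitivity of foraging; brain DA:5HT
ratio), sequencing-batch shifts, GO-style annotations with a planted
enriched term, and a per-species dN/dS table with a planted negative
centrality-constraint relationship.

Generative model on the log2 scale, for gene g and sample s::

    x[g, s] = baseline[g]
              + colony_effect[g, colony(s)]
              + loading[g] * factor[module(g), s]
              + effect[g, t] * z_trait[t, colony(s)]
              + batch_shift[batch(s)]
              + Normal(0, noise_sd)

then TPM = 2**x with columns rescaled to sum to 1e6.

Every draw comes from ``numpy.random.default_rng([seed, offset])`` with a
fixed per-operation offset, so each operation is a pure function of
(config, seed) and partial reruns are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

TRAITS = ("humidity", "da5ht")

# fixed RNG stream offsets, one per operation
_STREAM = {"traits": 1, "expression": 2, "annotations": 3, "dnds": 4, "counts": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stream]])


@dataclass
class ModuleSpec:
    """One planted coexpression module.

    ``colony_loading_sd`` sets the colony-level component of the module's
    latent factor (0 = purely sample-level coexpression); ``trait_link``
    ties the factor to a colony trait with correlation ``link_strength``.
    """

    size: int
    colony_loading_sd: float = 0.0
    trait_link: str = "none"  # humidity | da5ht | none
    link_strength: float = 0.0
    amplitude: float = 1.0  # log2 units per factor SD


@dataclass
class BatchSpec:
    batch_id: str
    sample_ids: list[str]
    shift: float  # log2 units


@dataclass
class GoSpec:
    n_terms: int = 50
    genes_per_term: int = 50
    # term id -> planted target: "trait:humidity", "trait:da5ht" or a module name
    planted: dict[str, str] = field(default_factory=dict)
    concentration: float = 0.8


@dataclass
class DnDsSpec:
    baseline_mean: float = 0.15
    centrality_slope: float = 0.5  # log-dN/dS units per centrality SD
    trait_slope: float = 0.5      # log-dN/dS units per |trait effect| SD
    dispersion: float = 0.3       # SD of the shared gene-level noise
    n_species: int = 6


@dataclass
class SimConfig:
    n_colonies: int = 9
    foragers_per_colony: int = 10
    n_genes: int = 10_000
    module_spec: list[ModuleSpec] = field(default_factory=list)
    frac_trait_genes: float = 0.05
    trait_effect_size: float = 1.0  # log2 units per trait SD for planted genes
    colony_effect_sd: float = 0.3
    noise_sd: float = 0.3
    batch_spec: list[BatchSpec] = field(default_factory=list)
    trait_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"humidity": (0.5, 3.0), "da5ht": (0.5, 2.0)}
    )
    go_spec: GoSpec = field(default_factory=GoSpec)
    dnds_spec: DnDsSpec = field(default_factory=DnDsSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n in [("n_colonies", self.n_colonies),
                        ("foragers_per_colony", self.foragers_per_colony),
                        ("n_genes", self.n_genes)]:
            if n < 1:
                raise ValueError(f"{name} must be a positive count, got {n}")
        if not 0.0 <= self.frac_trait_genes <= 1.0:
            raise ValueError("frac_trait_genes must be in [0, 1]")
        if sum(m.size for m in self.module_spec) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for m in self.module_spec:
            if not 0.0 <= m.link_strength <= 1.0:
                raise ValueError("link_strength must be in [0, 1]")
            if m.trait_link not in ("none",) + TRAITS:
                raise ValueError(f"unknown trait_link {m.trait_link!r}")

    # -- id helpers -------------------------------------------------------
    def colony_ids(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_colonies)]

    def sample_ids(self) -> list[str]:
        return [f"{c}_s{j + 1:02d}" for c in self.colony_ids()
                for j in range(self.foragers_per_colony)]

    def gene_ids(self) -> list[str]:
        return [f"g{i + 1:05d}" for i in range(self.n_genes)]


@dataclass
class SyntheticTruth:
    """Ground truth for parameter-recovery tests."""

    module_label: pd.Series          # gene -> module name or "none"
    trait_effect: pd.DataFrame       # gene x trait direct effect size (log2/trait SD)
    colony_traits: pd.DataFrame      # colony x trait
    sample_meta: pd.DataFrame        # sample -> colony, batch
    module_loading: pd.Series        # gene -> factor loading (0 outside modules)
    module_factor: pd.DataFrame      # module x sample latent factors
    constraint: pd.Series | None = None  # gene -> latent log dN/dS used for species draws

    def trait_genes(self, trait: str) -> pd.Index:
        eff = self.trait_effect[trait]
        return eff.index[eff != 0.0]

    def to_json(self) -> str:
        payload = {
            "module_label": self.module_label.to_dict(),
            "trait_effect": self.trait_effect.to_dict(),
            "colony_traits": self.colony_traits.to_dict(),
            "sample_meta": self.sample_meta.to_dict(),
            "module_loading": self.module_loading.to_dict(),
        }
        if self.constraint is not None:
            payload["constraint"] = self.constraint.to_dict()
        return json.dumps(payload)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_colony_traits(config: SimConfig) -> pd.DataFrame:
    """Draw per-colony trait values uniformly within the configured ranges.

    Returns a DataFrame indexed by colony id with one column per trait.
    """
    if config.n_colonies < 2:
        raise ValueError("need at least 2 colonies")
    rng = _rng(config.seed, "traits")
    out = {}
    for trait in TRAITS:
        lo, hi = config.trait_ranges[trait]
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError(f"non-finite range for {trait}")
        if lo >= hi:
            raise ValueError(f"degenerate range for {trait}: ({lo}, {hi})")
        out[trait] = rng.uniform(lo, hi, size=config.n_colonies)
    return pd.DataFrame(out, index=pd.Index(config.colony_ids(), name="colony"))


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def simulate_expression(
    config: SimConfig, traits: pd.DataFrame
) -> tuple["ExpressionMatrix", SyntheticTruth]:
    """Generate a TPM matrix with planted modules, colony and trait effects.

    Returns the matrix (columns rescaled to sum to 1e6) and the ground
    truth used to generate it.
    """
    from .matrix import ExpressionMatrix

    missing = set(config.colony_ids()) - set(traits.index)
    if missing:
        raise ValueError(f"traits missing colonies: {sorted(missing)}")
    rng = _rng(config.seed, "expression")
    genes = config.gene_ids()
    samples = config.sample_ids()
    colonies = config.colony_ids()
    n_g, n_s = len(genes), len(samples)
    colony_of = np.repeat(np.arange(config.n_colonies), config.foragers_per_colony)

    # standardized colony traits, replicated to samples
    z_trait = {t: _standardize(traits.loc[colonies, t].to_numpy()) for t in TRAITS}

    baseline = rng.normal(5.0, 2.0, size=n_g)
    x = np.tile(baseline[:, None], (1, n_s))

    # per gene x colony shifts -> colony-specific expression patterns
    if config.colony_effect_sd > 0:
        ce = rng.normal(0.0, config.colony_effect_sd, size=(n_g, config.n_colonies))
        x += ce[:, colony_of]

    # planted modules: one latent factor each, per-gene loadings
    module_label = np.array(["none"] * n_g, dtype=object)
    loading = np.zeros(n_g)
    factors = {}
    pos = 0
    for k, spec in enumerate(config.module_spec):
        name = f"M{k + 1}"
        idx = np.arange(pos, pos + spec.size)
        pos += spec.size
        module_label[idx] = name
        f_col = rng.normal(0.0, 1.0, size=config.n_colonies)
        f_smp = rng.normal(0.0, 1.0, size=n_s)
        f = spec.colony_loading_sd * f_col[colony_of] + f_smp
        f = _standardize(f)
        if spec.trait_link != "none" and spec.link_strength > 0:
            z = z_trait[spec.trait_link][colony_of]
            f = spec.link_strength * z + np.sqrt(1 - spec.link_strength**2) * f
        factors[name] = f
        lam = spec.amplitude * rng.normal(1.0, 0.3, size=spec.size)
        loading[idx] = lam
        x[idx] += lam[:, None] * f[None, :]

    # trait-linked background genes (direct linear effect on log expression)
    effect = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=list(TRAITS))
    n_trait = int(round(config.frac_trait_genes * n_g))
    bg = np.arange(pos, n_g)  # background genes only, so module truth stays clean
    if n_trait > 0 and len(bg) > 0:
        for t in TRAITS:
            pick = rng.choice(bg, size=min(n_trait, len(bg)), replace=False)
            signs = rng.choice([-1.0, 1.0], size=len(pick))
            eff = signs * config.trait_effect_size
            effect.iloc[pick, effect.columns.get_loc(t)] = eff
            x[pick] += eff[:, None] * z_trait[t][colony_of][None, :]

    # batch shifts
    batch = pd.Series("batch0", index=samples, name="batch")
    for b in config.batch_spec:
        batch.loc[b.sample_ids] = b.batch_id
        cols = [samples.index(s) for s in b.sample_ids]
        x[:, cols] += b.shift

    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, size=(n_g, n_s))

    tpm = np.exp2(x)
    tpm *= 1e6 / tpm.sum(axis=0, keepdims=True)

    values = pd.DataFrame(tpm, index=pd.Index(genes, name="gene"), columns=samples)
    meta = pd.DataFrame(
        {
            "colony": [colonies[c] for c in colony_of],
            "batch": batch.to_numpy(),
            "rna_conc": np.round(rng.uniform(20, 200, size=n_s), 1),
            "library": [f"lib{i + 1:03d}" for i in range(n_s)],
        },
        index=pd.Index(samples, name="sample"),
    )
    matrix = ExpressionMatrix(values, meta, unit="tpm", provenance=["simulate"])
    truth = SyntheticTruth(
        module_label=pd.Series(module_label, index=values.index, name="module"),
        trait_effect=effect,
        colony_traits=traits.loc[colonies],
        sample_meta=meta[["colony", "batch"]],
        module_loading=pd.Series(loading, index=values.index, name="loading"),
        module_factor=pd.DataFrame(factors, index=samples).T,
    )
    return matrix, truth


def simulate_annotations(config: SimConfig, truth: SyntheticTruth) -> dict[str, set[str]]:
    """Build a term -> gene-set map with optional planted enriched terms.

    A planted term draws ``concentration`` of its genes from its target set
    (a module's genes or a trait's linked genes) and the remainder at
    random; all other terms are uniform random draws.
    """
    spec = config.go_spec
    if spec.genes_per_term > config.n_genes:
        raise ValueError("genes_per_term exceeds n_genes")
    rng = _rng(config.seed, "annotations")
    genes = np.asarray(truth.module_label.index)
    annot: dict[str, set[str]] = {}
    for i in range(spec.n_terms):
        term = f"GO:{i + 1:07d}"
        target = spec.planted.get(term)
        if target is None:
            picked = rng.choice(genes, size=spec.genes_per_term, replace=False)
        else:
            if target.startswith("trait:"):
                pool = np.asarray(truth.trait_genes(target.split(":", 1)[1]))
            else:
                pool = np.asarray(truth.module_label.index[truth.module_label == target])
            n_in = min(int(round(spec.concentration * spec.genes_per_term)), len(pool))
            inside = rng.choice(pool, size=n_in, replace=False)
            rest_pool = np.setdiff1d(genes, inside)
            outside = rng.choice(rest_pool, size=spec.genes_per_term - n_in, replace=False)
            picked = np.concatenate([inside, outside])
        annot[term] = set(picked.tolist())
    return annot


def simulate_dnds(
    config: SimConfig, truth: SyntheticTruth, kme_proxy: pd.Series | None = None
) -> pd.DataFrame:
    """Per-species dN/dS with planted centrality and trait-effect slopes.

    ``log dN/dS = log(baseline) - centrality_slope*z(centrality)
    - trait_slope*z(|trait effect|) + gene noise``, replicated per species
    with independent species-level noise around the shared gene component.
    """
    spec = config.dnds_spec
    if spec.dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = _rng(config.seed, "dnds")
    if kme_proxy is None:
        kme_proxy = truth.module_loading
    centrality = kme_proxy.reindex(truth.module_label.index).fillna(0.0).to_numpy(float)
    tmag = truth.trait_effect.abs().max(axis=1).to_numpy(float)
    log_mu = (
        np.log(spec.baseline_mean)
        - spec.centrality_slope * _standardize(centrality)
        - spec.trait_slope * _standardize(tmag)
        + rng.normal(0.0, spec.dispersion, size=len(centrality))
    )
    truth.constraint = pd.Series(log_mu, index=truth.module_label.index, name="log_dnds")
    species = [f"sp{j + 1}" for j in range(spec.n_species)]
    draws = {
        sp: np.exp(log_mu + rng.normal(0.0, spec.dispersion / 2, size=len(log_mu)))
        for sp in species
    }
    return pd.DataFrame(draws, index=truth.module_label.index)


def simulate_counts(
    matrix: "pd.DataFrame | object", config: SimConfig, mean_depth: float = 5e6
) -> tuple[pd.DataFrame, pd.Series]:
    """Emit Poisson read counts plus gene lengths consistent with the TPM
    matrix, for exercising the counts -> TPM conversion."""
    values = matrix.values if hasattr(matrix, "unit") else matrix
    rng = _rng(config.seed, "counts")
    lengths = pd.Series(
        rng.integers(500, 5000, size=values.shape[0]).astype(float),
        index=values.index, name="length",
    )
    rate = values.to_numpy(float) * lengths.to_numpy()[:, None]
    rate = rate / rate.sum(axis=0, keepdims=True) * mean_depth
    counts = pd.DataFrame(rng.poisson(rate), index=values.index, columns=values.columns)
    return counts, lengths


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_simulation(
    outdir: str | Path,
    matrix,
    truth: SyntheticTruth,
    traits: pd.DataFrame,
    annotations: dict[str, set[str]] | None = None,
    dnds: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the simulated dataset as the pipeline's TSV/JSON interchange."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["expression"] = outdir / "expression.tsv"
    matrix.values.to_csv(paths["expression"], sep="\t")
    paths["sample_meta"] = outdir / "sample_meta.tsv"
    matrix.sample_meta.to_csv(paths["sample_meta"], sep="\t")
    paths["traits"] = outdir / "colony_traits.tsv"
    traits.to_csv(paths["traits"], sep="\t")
    if annotations is not None:
        paths["annotations"] = outdir / "annotations.tsv"
        with open(paths["annotations"], "w") as fh:
            for term in sorted(annotations):
                for gene in sorted(annotations[term]):
                    fh.write(f"{gene}\t{term}\n")
    if dnds is not None:
        paths["dnds"] = outdir / "dnds.tsv"
        dnds.to_csv(paths["dnds"], sep="\t")
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(truth.to_json())
    return paths


def default_config(**overrides) -> SimConfig:
    """Study-scale defaults: 9 colonies x 10 foragers, planted modules with
    colony structure and trait links, two sequencing batches."""
    n_colonies = overrides.pop("n_colonies", 9)
    foragers = overrides.pop("foragers_per_colony", 10)
    modules = overrides.pop("module_spec", [
        ModuleSpec(300, colony_loading_sd=1.0, trait_link="humidity", link_strength=0.8),
        ModuleSpec(250, colony_loading_sd=1.0, trait_link="da5ht", link_strength=0.8),
        ModuleSpec(200, colony_loading_sd=1.0),
        ModuleSpec(150, colony_loading_sd=0.5),
    ])
    cfg = SimConfig(
        n_colonies=n_colonies,
        foragers_per_colony=foragers,
        module_spec=modules,
        **overrides,
    )
    if not cfg.batch_spec:
        samples = cfg.sample_ids()
        half = len(samples) // 2
        cfg.batch_spec = [
            BatchSpec("batch1", samples[:half], 0.0),
            BatchSpec("batch2", samples[half:], 0.5),
        ]
    return cfg
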