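import numpy as np
import pandas as pd
import pytest

from colonynet import preprocess, simulate
from colonynet.matrix import ExpressionMatrix


def make_matrix(values: np.ndarray, colonies=None, batches=None,
                unit: str = "log2tpm") -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with minimal metadata."""
    n_g, n_s = values.shape
    genes = [f"g{i:04d}" for i in range(n_g)]
    samples = [f"s{j:03d}" for j in range(n_s)]
    meta = pd.DataFrame(
        {
            "colony": colonies if colonies is not None else ["C1"] * n_s,
            "batch": batches if batches is not None else ["batch0"] * n_s,
        },
        index=samples,
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            meta, unit=unit)


@pytest.fixture(scope="session")
def small_sim():
    """Shared small study-shaped simulation: 9 colonies x 10 foragers,
    600 genes, two planted modules (one humidity-linked), trait genes,
    two batches."""
    cfg = simulate.default_config(
        n_genes=600, seed=11,
        module_spec=[
            simulate.ModuleSpec(80, 1.0, "humidity", 0.8),
            simulate.ModuleSpec(60, 1.0),
        ],
        frac_trait_genes=0.05,
    )
    traits = simulate.simulate_colony_traits(cfg)
    matrix, truth = simulate.simulate_expression(cfg, traits)
    return cfg, traits, matrix, truth


@pytest.fixture(scope="session")
def preprocessed_sim(small_sim):
    cfg, traits, matrix, truth = small_sim
    pp, reports = preprocess.preprocess_pipeline(matrix)
    return cfg, traits, pp, truth, reports


@pytest.fixture(scope="session")
def large_sim():
    """2,000-gene study-scale simulation for ranking/power checks, where
    the number of planted trait genes is large enough for stable AUCs."""
    cfg = simulate.default_config(
        n_genes=2000, seed=11,
        module_spec=[
            simulate.ModuleSpec(80, 1.0, "humidity", 0.8),
            simulate.ModuleSpec(60, 1.0),
        ],
        frac_trait_genes=0.05,
    )
    traits = simulate.simulate_colony_traits(cfg)
    matrix, truth = simulate.simulate_expression(cfg, traits)
    pp, _ = preprocess.preprocess_pipeline(matrix)
    return cfg, traits, pp, truth


@pytest.fixture(scope="session")
def block_sim():
    """Clean two-block coexpression fixture: no colony effects, no trait
    genes, 200 module genes + 1000 noise genes (a realistic module
    fraction, so background genes share no compositional factor)."""
    cfg = simulate.default_config(
        n_genes=1200, seed=3, colony_effect_sd=0.0, frac_trait_genes=0.0,
        noise_sd=0.4,
        module_spec=[
            simulate.ModuleSpec(100, 0.0, amplitude=1.2),
            simulate.ModuleSpec(100, 0.0, amplitude=1.2),
        ],
    )
    traits = simulate.simulate_colony_traits(cfg)
    matrix, truth = simulate.simulate_expression(cfg, traits)
    pp, _ = preprocess.preprocess_pipeline(matrix)
    return cfg, traits, pp, truth
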