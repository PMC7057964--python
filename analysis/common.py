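"""Shared configuration for the numbered analysis scripts.

The scripts run in order (01 -> 06) on one simulated study: 9 colonies x
10 foragers, 2,000 genes with two planted coexpression modules (one tied
to colony humidity sensitivity), 5% trait-linked background genes, two
sequencing batches, and a six-species dN/dS table with a planted negative
centrality-constraint slope. Large intermediates live under scratch/run;
small result tables and summaries under results/.
"""

from pathlib import Path

from colonynet import simulate

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"
SEED = 1


def study_config() -> simulate.SimConfig:
    return simulate.default_config(
        n_genes=2000,
        seed=SEED,
        module_spec=[
            simulate.ModuleSpec(120, 1.0, "humidity", 0.8),
            simulate.ModuleSpec(100, 1.0),
        ],
        frac_trait_genes=0.05,
        go_spec=simulate.GoSpec(
            n_terms=50, genes_per_term=40,
            planted={"GO:0000001": "trait:humidity"}, concentration=0.8),
    )
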