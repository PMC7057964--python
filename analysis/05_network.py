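"""Signed coexpression network with the iterative density filter.

Soft threshold by the scale-free criterion, signed adjacency, topological
overlap, persistence-cut modules, pseudo-module density filter, quality
Z, module eigengene-trait correlations, and eigengene-colony ANOVA.

Writes module labels/kME under scratch/run and the module summary,
module-trait correlations and colony ANOVA to results/05_*.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH, SEED  # noqa: E402

from colonynet import io, network  # noqa: E402
from colonynet.network import NetworkParams  # noqa: E402


def main() -> None:
    m = io.read_expression(SCRATCH / "preprocessed.tsv",
                           SCRATCH / "preprocessed_meta.tsv", unit="log2tpm")
    colony_traits = io.read_traits(SCRATCH / "sim" / "colony_traits.tsv")
    trait_r = pd.read_csv(SCRATCH / "trait_correlations.tsv", sep="\t", index_col=0)

    beta, fit = network.pick_soft_threshold(m, candidate_betas=(2, 4, 6, 8, 10, 12))
    params = NetworkParams(beta=beta, min_module_size=50, n_pseudo=2000, seed=SEED)
    modules, to = network.iterative_density_filter(m, params)

    io.write_tsv(modules.labels.to_frame(), SCRATCH / "module_labels.tsv")
    if modules.linkage_matrix is not None and to is not None:
        (SCRATCH / "dendrogram.nwk").write_text(
            network.dendrogram_to_newick(modules.linkage_matrix, to.index))
    summary = {"beta": beta, "rounds": len(modules.filter_log),
               "n_modules": len(modules.module_names()),
               "n_genes_final": int(len(modules.labels))}
    if modules.module_names():
        io.write_tsv(modules.kme.round(5).to_frame(), SCRATCH / "module_kme.tsv")
        modules.quality_z = network.module_quality_z(
            to, modules.labels, n_perm=200, seed=SEED)
        io.write_tsv(modules.summary().round(5), RESULTS / "05_module_summary.tsv")
        net_m = m.subset(genes=modules.labels.index)
        mt = network.module_trait_analysis(modules, net_m, colony_traits,
                                           trait_r=trait_r)
        io.write_tsv(mt["me_trait"].round(5), RESULTS / "05_module_trait.tsv")
        anova, contrasts = network.me_colony_comparison(modules, net_m.colonies())
        io.write_tsv(anova.round(6), RESULTS / "05_me_colony_anova.tsv")
        summary["module_sizes"] = modules.sizes()
        summary["quality_z"] = {k: round(v, 2) for k, v in modules.quality_z.items()}
    (RESULTS / "05_network.json").write_text(json.dumps(summary, indent=2))
    print(f"beta = {beta}; {summary['n_modules']} modules over "
          f"{summary['n_genes_final']} genes after {summary['rounds']} "
          f"filter round(s); quality Z: {summary.get('quality_z', {})}")


if __name__ == "__main__":
    main()
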