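"""Evolutionary constraint vs expression: decile recoding, the constraint
GLM, module-level constraint tests, and per-species centrality slopes.

Writes the GLM coefficient table, module constraint tests and per-species
slopes to results/06_*.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH  # noqa: E402

from colonynet import evolution, io  # noqa: E402


def main() -> None:
    dnds = io.read_dnds(SCRATCH / "sim" / "dnds.tsv")
    expr = pd.read_csv(SCRATCH / "sim" / "expression.tsv", sep="\t", index_col=0)
    trait_r = pd.read_csv(SCRATCH / "trait_correlations.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(SCRATCH / "module_labels.tsv", sep="\t",
                         index_col=0)["module"]
    kme = pd.read_csv(SCRATCH / "module_kme.tsv", sep="\t", index_col=0)["kME"]

    table = evolution.build_dnds_table(
        dnds,
        median_tpm=expr.median(axis=1),
        expr_sd=np.log2(expr + 1).std(axis=1),
        trait_r=trait_r,
        kme=kme,
        module_label=labels.replace({"grey": "none"}),
    )
    preds = [c for c in ("abs_r_sample_humidity", "abs_r_sample_da5ht",
                         "kme", "median_tpm", "expr_sd") if c in table.columns]
    glm = evolution.constraint_glm(table, predictors=tuple(preds))
    io.write_tsv(glm.round(6), RESULTS / "06_constraint_glm.tsv")

    modules = [mname for mname in table["module"].unique() if mname != "none"]
    mtests = pd.DataFrame([evolution.module_constraint_test(table, mname)
                           for mname in modules]).set_index("module")
    io.write_tsv(mtests.round(6), RESULTS / "06_module_constraint.tsv")
    slopes = evolution.per_species_centrality_slope(table)
    io.write_tsv(slopes.round(6), RESULTS / "06_species_slopes.tsv")

    background = evolution.in_module_vs_background_test(table)
    (RESULTS / "06_evolution.json").write_text(json.dumps({
        "glm_kme": {"estimate": float(glm.loc["kme", "estimate"]),
                    "p": float(glm.loc["kme", "p"])} if "kme" in glm.index else None,
        "in_module_vs_background": background,
        "n_species_negative_slope": int((slopes["slope"] < 0).sum()),
        "n_species": int(len(slopes)),
    }, indent=2))
    print(f"GLM kME coefficient {glm.loc['kme', 'estimate']:.3f} "
          f"(p = {glm.loc['kme', 'p']:.2e}); modules vs background t = "
          f"{background['t']:.2f} (p = {background['p']:.2e}); "
          f"{(slopes['slope'] < 0).sum()} of {len(slopes)} species show a "
          f"negative centrality slope")


if __name__ == "__main__":
    main()
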