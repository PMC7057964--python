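"""Preprocess the simulated expression matrix: gene filters, log2,
iterative outlier masking/removal, quantile normalization, batch
adjustment with colony protected.

Reads scratch/run/sim, writes the preprocessed matrix to
scratch/run/preprocessed.tsv and the stage reports to
results/02_preprocess.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH  # noqa: E402

from colonynet import io, preprocess  # noqa: E402


def main() -> None:
    m = io.read_expression(SCRATCH / "sim" / "expression.tsv",
                           SCRATCH / "sim" / "sample_meta.tsv", unit="tpm")
    pp, reports = preprocess.preprocess_pipeline(m, protect=["colony"])
    io.write_tsv(pp.values.round(4), SCRATCH / "preprocessed.tsv")
    pp.sample_meta.to_csv(SCRATCH / "preprocessed_meta.tsv", sep="\t")

    payload = {k: (v.to_dict() if hasattr(v, "to_dict") else v)
               for k, v in reports.items()}
    payload["colonies_kept"] = pp.colonies().value_counts().to_dict()
    (RESULTS / "02_preprocess.json").write_text(json.dumps(payload, indent=2))
    out = reports["outliers"]
    print(f"kept {pp.n_genes} genes x {pp.n_samples} samples; "
          f"outlier loop masked {out.n_values_masked} values and removed "
          f"{out.n_samples_removed} samples in {out.iterations} iterations")


if __name__ == "__main__":
    main()
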