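#!/usr/bin/env python
"""Batch-aware moderated differential expression, MES vs non-MES.

Fits per-gene OLS models with group and batch covariates on the retained
concordant samples, shrinks residual variances by empirical Bayes, and
derives the mesenchymal signature gene lists (q < 0.05) plus the top-100
display list.

Writes results/de_results.tsv and results/de_signature.gmt.
"""

from pathlib import Path

import pandas as pd

from mesreg import diffexp, io

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    values = io.read_expression_tsv(ROOT / "harmonized.tsv")
    batches = pd.read_csv(ROOT / "batch_labels.tsv", sep="\t", index_col=0)["batch"]
    calls = pd.read_csv(ROOT / "subtype_calls_primary.tsv", sep="\t", index_col=0)
    retained = (ROOT / "retained_samples.txt").read_text().split()

    group = calls.loc[retained, "label"].map(
        lambda l: "MES" if l == "MES" else "nonMES")
    design = diffexp.DesignInfo(group=group, batch=batches.loc[retained])
    fits = diffexp.fit_gene_models(values[retained], design)
    results = diffexp.moderated_test(fits, design)
    results.to_csv(ROOT / "de_results.tsv", sep="\t", index_label="gene")

    up, down, top = diffexp.make_signature(results, q_threshold=0.05, top_n=100)
    io.write_gmt({"MES_up": up, "MES_down": down, "top_de": top},
                 ROOT / "de_signature.gmt")

    d0 = results.attrs["d0"]
    print(f"{len(retained)} samples ({(group == 'MES').sum()} MES); "
          f"EB prior df d0={d0 if d0 != float('inf') else 'inf'}")
    print(f"signature: {len(up)} up, {len(down)} down at q<0.05")
    print("strongest MES genes:",
          ", ".join(results.sort_values('t_mod').tail(5).index[::-1]))


if __name__ == "__main__":
    main()
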