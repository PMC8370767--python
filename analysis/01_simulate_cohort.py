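#!/usr/bin/env python
"""Simulate the multi-batch GSC expression collection and assay tables.

Generates the synthetic study inputs with known ground truth: three
expression batches (150 samples x 2000 genes, 100 TFs of which 5 drive the
mesenchymal state with regulons of 40 genes, effect 1.0, noise SD 1),
two subtype-signature schemes, a survival cohort tied to a marker gene
(hazard ratio 3), and limiting-dilution well counts at the frequencies the
downstream analysis should recover (1 in 3 control vs 1 in 28.6 knockout).

Writes everything under results/inputs/.
"""

from pathlib import Path

from mesreg import synthetic
from mesreg.pipeline import stage_seed

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    datasets, gt = synthetic.gen_expression(seed=SEED)
    paths = synthetic.write_inputs(OUT, datasets, gt, signature_seed=SEED)

    clinical, marker = synthetic.gen_survival(
        n=400, hazard_ratio=3.0, seed=stage_seed(SEED, "survival"))
    clinical.to_csv(OUT / "clinical.tsv", sep="\t", index=False)
    marker.to_frame().to_csv(OUT / "marker_expression.tsv", sep="\t",
                             index_label="sample")

    wells = synthetic.gen_lda(
        doses=(1, 2, 4, 8, 16, 32, 64, 128), wells_per_dose=12,
        true_n_per_group={"sgCtrl": 3.0, "sgFosl1": 28.6},
        seed=stage_seed(SEED, "lda"))
    wells.to_csv(OUT / "lda_wells.tsv", sep="\t", index=False)

    n_samples = sum(d.values.shape[1] for d in datasets)
    print(f"wrote {len(datasets)} expression batches ({n_samples} samples, "
          f"{datasets[0].values.shape[0]} genes) to {OUT}")
    print(f"planted MES-driving TFs: {', '.join(gt.mes_tfs)}")
    print(f"decoy TFs with regulons but no MES effect: {', '.join(gt.decoy_tfs)}")


if __name__ == "__main__":
    main()
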