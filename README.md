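# mesreg

Master-regulator discovery for glioma stem-cell (GSC/BTSC) expression
programs: an end-to-end, fully tested pipeline that finds the
transcription factors driving the mesenchymal (MES) transcriptional state
in heterogeneous multi-platform expression collections, and quantifies the
downstream phenotypes (patient survival stratified by a marker gene, and
stem-cell frequency from limiting-dilution sphere assays).

## The problem

Glioblastoma stem-cell lines occupy a transcriptional gradient between a
mesenchymal and a non-mesenchymal (proneural/classical, or "developmental")
state. Identifying the *master regulators* of the mesenchymal program from
expression data takes a chain of analyses, each with its own statistics:

1. **Harmonization** — per-platform matrices are collapsed from probes to
   genes (per-sample median), restricted to the genes common to all
   batches, and every gene is z-scored *within its batch*
   (mean 0, SD 1, population SD), which removes gene-wise affine platform
   effects before concatenation.
2. **Subtype calls** — each sample is scored against subtype signatures
   with single-sample GSEA (ssGSEA). For a sample with genes ranked by
   decreasing expression, the score of signature *S* is

   ES = Σᵢ [ Pᵢⁿ(S) − Pᵢᵒᵘᵗ(S) ],

   the summed difference between the weighted in-set and uniform
   out-of-set cumulative fractions. Empirical p-values come from
   size-matched random gene sets (1000 permutations); a sample keeps its
   label only when two independent classification schemes agree
   (MES↔INJ, non-MES↔DEV concordance filtering).
3. **Differential expression** — per-gene OLS of expression on group +
   batch indicators; residual variances are shrunk by empirical Bayes
   (scaled inverse-χ² prior fitted by moments of log s²), giving
   moderated t statistics with d₀ + df degrees of freedom and BH-adjusted
   p-values.
4. **Regulon inference** — mutual information between every TF and every
   other gene, estimated with the Gaussian-copula closed form
   MI = −½·ln(1 − r²) on normal scores (rank-based, hence invariant to
   monotone transforms). Each TF's sample order is permuted 1000 times;
   all null MIs are pooled into one distribution, edges keep empirical
   p-values, and edges at BH q < 0.05 are pruned by the data processing
   inequality: in any fully connected triangle of two TFs and a target,
   the strictly weakest edge is removed.
5. **Master-regulator analysis (MRA)** — each TF's regulon is tested for
   overlap with the MES signature genes by the upper-tail hypergeometric
   distribution (BH across TFs), plus one-tail GSEA of the regulon against
   the moderated-t ranking (NES = ES / mean |null ES|).
6. **Survival** — cohorts are split at the top/bottom 30% of a marker
   gene's expression; Kaplan–Meier curves and the log-rank test compare
   the groups.
7. **Limiting dilution (ELDA)** — under the single-hit Poisson model,
   P(well negative | dose d) = e^(−f·d); the sphere-forming frequency f is
   the MLE of a binomial GLM with complementary log-log link and offset
   ln d, reported as "1 in N" (N = 1/f) with a Wald 95% CI, and groups are
   compared with a likelihood-ratio χ².

Because the original cohorts are external downloads, the package ships a
first-class synthetic-data generator (`mesreg.synthetic`) that plants the
structure the analysis assumes — two transcriptional states, TF-driven
regulons with signed targets, batch distortions, survival effects and
single-hit well counts — so every stage is testable against known truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
collection (3 batches, 150 samples, 2000 genes, 100 TFs of which 5 drive
the MES state with 40-gene regulons, effect 1.0, noise SD 1):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_harmonize_and_classify.py
python analysis/03_differential_expression.py
python analysis/04_network_and_mra.py
python analysis/05_survival_stratification.py
python analysis/06_limiting_dilution.py
```

which prints, among other things:

```
planted MES-driving TFs: TF002, TF029, TF034, TF058, TF093
harmonized matrix: 2000 genes x 150 samples (0 zero-variance genes removed)
concordance between schemes: 93.3% (140 samples retained)
signature: 108 up, 103 down at q<0.05
641 significant edges after DPI over 100 TFs
5 TFs at BH q < 1e-4; top 10: TF029, TF058, TF034, TF002, TF093, ...
planted MES drivers recovered in top 10: 5/5
log-rank chi2 = 55.51, p = 9.3e-14
sgCtrl: 1 in 3.5 (95% CI 2.3-5.1)
sgFosl1: 1 in 26.3 (95% CI 18.2-38.1)
```

All five planted regulators are the five most significant master
regulators; the survival split at hazard ratio 3 is detected at
p ≈ 1e-13; and the limiting-dilution fits recover the planted "1 in 3"
vs "1 in 28.6" sphere-forming frequencies within sampling error.

The same stages are exposed as a CLI (`mesreg simulate | harmonize |
classify | diffexp | network | mra | survival | elda | run-all`); `run-all`
takes a YAML config, derives per-stage seeds from one global seed, and
writes a manifest — reruns with the same config and seed are byte-identical.

## Layout

- `src/mesreg/` — the library: `harmonize`, `subtype`, `diffexp`,
  `netinfer`, `mra`, `survival`, `elda`, `synthetic`, `pipeline`, `cli`.
- `analysis/` — the numbered study drivers (thin wrappers over the library).
- `tests/` — unit, property and acceptance tests (pytest + hypothesis).
- `docs/methods.md` — the methods note: models, defaults, numerical
  choices and limitations.
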