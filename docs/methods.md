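# Methods

This note documents the models implemented in `mesreg`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that make results deterministic.

## Harmonization

Input batches are probe- or gene-level matrices. Probes mapping to the
same gene are collapsed to the per-sample median (even counts: mean of the
two middle values). Analysis is restricted to the genes present in every
batch, and each gene is standardized to mean 0, SD 1 *within its batch*
before concatenation.

Decisions:

- **Scaling axis.** Standardization is per gene within batch, not per
  sample: gene-wise location/scale differences are exactly what differs
  between array and RNA-seq platforms, and removing them is what makes
  cross-platform concatenation meaningful. Per-sample scaling would leave
  gene-wise platform effects in place.
- **Population SD (divisor n).** The choice between n and n−1 is a
  constant per-gene factor within a batch and cannot affect any rank- or
  correlation-based downstream statistic; fixing it makes the z-scoring
  exactly idempotent and the tests exact.
- **Zero-variance genes** (constant in any batch) are removed globally and
  reported, rather than set to 0: a constant vector has no ranks and would
  poison the MI estimator.
- **Missing values** are rejected at ingestion; an explicit
  `impute_missing` entry point fills row medians for callers who want it.

## ssGSEA subtype classification

For one sample, genes are ranked by decreasing expression (ties broken
lexicographically by gene id, so calls are deterministic). The score of a
signature is the sum over ranked positions of the difference between the
in-set weighted cumulative fraction and the out-of-set uniform cumulative
fraction. In-set weights are the *rank statistic* (N for the top gene down
to 1) raised to `weight_exponent`; using ranks rather than raw values
keeps the score invariant under any strictly monotone transform of the
profile, so array- and count-scale profiles score identically.

- `weight_exponent` defaults to 0.25, the canonical ssGSEA choice; it is a
  config knob because published classifiers rarely state it.
- The resampling null draws size-matched gene sets uniformly without
  replacement from the profile's genes ("equivalent-distribution"
  resampling); p = (1 + #{null ≥ observed}) / (n_perm + 1), so the
  smallest attainable p is 1/(n_perm+1). The label is the signature with
  the smallest p; ties go to the larger observed score, then signature
  order.
- Raw scores are not normalized by set size. Within a sample the
  comparison across signatures runs through the size-matched null, which
  absorbs scale. Note the mean score of a *random* set is exactly 0 only
  at weight exponent 0; at positive exponents the rank weights give random
  sets a small positive offset — irrelevant to p-values, which compare
  against the same offset null.
- Concordance filtering keeps samples whose labels agree across two
  schemes under an explicit mapping (MES↔INJ, PN/CL↔DEV); the retained
  fraction is reported.

## Moderated differential expression

Per gene: OLS on intercept + group indicator + batch indicators (first
batch as reference; rank-deficient designs are rejected with the aliased
columns named). Residual variances s² with d degrees of freedom are
assumed to follow s² | σ² ~ σ²·χ²_d/d with a scaled inverse-χ²(d₀, s₀²)
prior on σ². The prior is fitted by method of moments on log s²: the
excess variance of log s² over the trigamma(d/2) sampling term identifies
d₀ through the inverse trigamma, and the mean identifies s₀². If the
observed dispersion does not exceed the sampling term, d₀ = ∞ and the
posterior collapses to the pooled (mean) variance. The moderated t uses
the posterior variance (d₀s₀² + d·s²)/(d₀ + d) and d₀ + d degrees of
freedom (normal when infinite). Multiple testing is Benjamini–Hochberg
throughout.

- Moments on log s² (digamma/trigamma matching) rather than marginal
  likelihood: closed-form, deterministic, and testable by parameter
  recovery (the suite recovers d₀ = 4, s₀² = 1 from 5000 simulated genes).
- Signature thresholds default to q < 0.05 with a 100-gene display list;
  both are config knobs since no universal cutoff exists.
- A `no_shrinkage` flag forces d₀ = 0, reducing exactly to the classical
  covariate-adjusted t-test (verified against an independent OLS oracle).

## Regulon inference

The MI estimator is the Gaussian-copula closed form: map each vector to
normal scores Φ⁻¹(rank/(n+1)) (average ranks for ties), take the
correlation r of the scores, return −½·ln(1−r²) with r² clipped at
1 − 1e−12. It is symmetric, deterministic, invariant to monotone
transforms, and exactly 0 at score-correlation 0. A fixed-bin histogram
estimator is available behind a flag for comparison only.

- **Null and pooling.** Each TF's sample order is permuted `n_perm` times
  (default 1000) and scored against all of that TF's candidate targets;
  all null values pool into a single distribution of size
  n_TFs × n_perm × (n_genes − 1). Pooling matches the analysis design
  (one global null for all edges) and gives p-value resolution far below
  1/(n_perm+1). Counting is done on the r² scale (MI is monotone in r²),
  sorting each permutation block once and locating the observed values by
  binary search — exact and O(pool·log).
- **Edge filtering** keeps BH q < alpha (default 0.05); the edge sign is
  the sign of the normal-score correlation.
- **DPI pruning.** For every fully connected triangle of two TFs and a
  third gene, the strictly weakest edge is marked when its MI is below
  (1 − tolerance)× the smaller of the other two (default tolerance 0;
  exact ties remove nothing). Marks are computed on the un-pruned table
  and applied simultaneously, making the result order-independent and
  idempotent. Any of the three edges may be removed, including the TF–TF
  edge — the rule speaks of the weakest interaction of the triangle, not
  of a particular edge type; `protect_tf_tf=True` exempts TF–TF edges for
  users who prefer the conservative variant.

## Master-regulator analysis

The hypergeometric test asks whether a regulon is enriched in the
signature genes: p = P(X ≥ overlap) with population = genes present in the
harmonized matrix (not the genome — regulons and signatures were derived
there), successes = signature size, draws = regulon size; BH across TFs.
The signature defaults to the union of up- and down-regulated genes at
q < 0.05 (per-direction overlaps are reported alongside). One-tail GSEA
runs the classical weighted KS statistic of the unsigned regulon against
the moderated-t ranking; the null draws size-matched random sets,
NES = ES / mean |null ES|, and regulons with fewer than three ranked genes
are skipped with a warning. TFs are ranked by q, then p, then |NES|, then
id.

## Survival

Samples are sorted by marker expression (ties broken by sample id); the
top ⌊0.30·n⌋ form the high group and the bottom ⌊0.30·n⌋ the low group
(floor, not round — the convention is stated since published splits rarely
are). Kaplan–Meier estimation and the log-rank test are delegated to
lifelines (product-limit estimator, events before censorings at tied
times, classical variance without continuity correction); the test suite
checks them against a hand O−E−V tabulation to 1e−10. Percentile cuts are
computed on the pooled cohort by default; per-batch cutting is available.

## Limiting dilution

Single-hit model: a well at dose d is negative with probability e^(−f·d).
Negative-well counts are binomial, so the MLE of ln f is the intercept of
a binomial GLM with complementary log-log link and offset ln d
(statsmodels); the single-dose closed form f̂ = −ln(neg/tested)/d seeds
the fit, and a bounded 1-d likelihood optimization backstops the rare
non-convergent case. The 95% CI is Wald on ln f (the standard ELDA
choice; a profile interval was considered and rejected for comparability),
reported on the 1-in-N scale. All-negative data give the boundary f = 0
(N = ∞, flagged); all-positive data leave f unbounded and raise. Group
equality is a likelihood-ratio χ² between pooled and per-group fits on
(groups − 1) df, verified against a dense likelihood-grid oracle.

## Synthetic data

`gen_expression` plants: MES labels on half the samples; TF genes as unit
noise, plus an `effect` shift (default 1.0) in MES samples for the
MES-driving TFs; regulon targets as sign·TF + noise(noise_sd); background
genes as independent noise; and per-batch gene-wise affine distortions
(scale ~ logN(0, 0.2²), shift ~ N(0, 1)) that per-batch standardization
removes *exactly* — so the value of harmonization is itself testable by
ablation. A heavier-tailed (t₃) noise option exercises the rank-based MI
estimator.

Regulons are planted for the MES-driving TFs and for a configurable
number of *decoy* TFs (default 10) that carry regulons without any group
effect: decoys are what separates "has a regulon" from "is a master
regulator" in the recovery tests. The remaining TFs are background genes.
(Planting 40-gene regulons for all 100 TFs inside 2000 genes is
arithmetically impossible, and decoys are the stronger test anyway.)

`gen_survival` draws exponential event times with the hazard multiplied
by `hazard_ratio` for the upper half of samples by marker value, with
independent exponential censoring (base hazard 1e−3/day ≈ 693-day median).
`gen_lda` draws Binomial(wells, 1 − e^(−d/N)) positives per dose. Every
generator is a pure function of (config, seed).

What the generator does **not** emulate: count-based mean–variance
structure of RNA-seq, correlated background co-expression beyond the
planted modules, non-affine batch effects, gradual (mixed-state)
phenotypes, informative censoring, or multi-hit sphere formation. Passing
tests therefore demonstrate correctness of the statistics under the
model's own assumptions, not robustness to every feature of real data.

## Reproducibility and problem sizes

A single global seed derives per-stage seeds by CRC32 of "seed:stage", so
stages can be rerun in isolation; every stage output is byte-identical
across reruns. The acceptance surface runs the full pipeline at the study
scale — 3 batches, 150 samples, 2000 genes, 100 TFs, 5 planted drivers,
regulon size 40, effect 1.0, noise SD 1, 1000 permutations for every
resampling step — and requires all five planted drivers in the top 10 by
hypergeometric q in at least 9 of 10 seeds. Calibration suites use
210-gene/50-TF null matrices for edge p-values, 20 null datasets for the
FDR of differential expression, 500 seeds for log-rank uniformity, and
500 replicate plates for ELDA CI coverage; these sizes keep Monte-Carlo
error well below the tested tolerances.

## Known limitations

- The Gaussian-copula MI is exact for monotone dependencies; purely
  non-monotone relationships (e.g. quadratic) have score correlation ≈ 0
  and are missed by design — the histogram estimator exists for such
  exploration.
- The pooled permutation null assumes exchangeable samples; strong
  residual batch structure after harmonization would inflate it.
- Hypergeometric MRA treats the signature and regulon as fixed sets,
  ignoring estimation uncertainty in both; the resampling GSEA p is the
  complementary view.
- The ELDA Wald interval undercovers slightly when few wells are
  informative; the suite pins coverage at 93–97% for 96-well designs.
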