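# Methods

`proteoscope` re-implements, as a tested pipeline over synthetic cohorts, a
family of analyses of constitutive-proteasome (CP) and immunoproteasome (IP)
gene expression in cancer: signature scoring and survival stratification,
CpG-methylation filtering, two-condition co-expression network co-clustering,
and threshold Fisher gene-set enrichment. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Expression scale and signature scores

All analysis operates on `log10(1000 * RPKM + 1)`-transformed expression. The
transform maps RPKM 0 to 0 and RPKM 0.999 to exactly 3, and the
`ExpressionMatrix` container carries an explicit scale tag with a
double-transform guard. Gene-wise z-scores use the sample standard deviation
(n − 1 denominator), matching the default of the statistical environments
these analyses are usually run in; genes constant across samples are dropped
with a warning (constant detection uses the exact value range rather than a
floating SD, which is ~1e-16 instead of 0 for constant rows).

The global CP score of a sample is the sum of z-scores of PSMB5/6/7; the IP
score sums PSMB8/9/10. Stratification into k = 2 or 3 groups sorts by
(score, sample id) ascending and cuts into contiguous groups whose sizes
differ by at most one, remainders going to the lower groups. The secondary
sort on sample id makes ties deterministic and the grouping invariant to any
strictly monotone rescaling of the scores.

## Survival

Times are days: `days_to_death` for expired samples, `days_to_last_followup`
for living ones; missing days are NaN, never sentinels, and expired records
without a death date are dropped with a logged warning. Kaplan–Meier curves,
log-rank tests and Cox fits are delegated to `lifelines`; Greenwood standard
errors are assembled from the fitted event table. Choices the source
protocol leaves open:

* Cox ties are handled by the Efron approximation (lifelines' default and
  the best standard approximation).
* For three or more groups, pairwise log-rank p-values are Bonferroni
  corrected ("corrected for three or more comparisons" names no method);
  the correction is config-exposed.
* The 3-group hazard ratio is high-vs-low with the mid tertile excluded;
  a per-tertile trend coefficient is a plausible alternative reading.
* Complete separation is reported with `unbounded_ci=True` (CI [0, ∞))
  rather than raised.

## Synthetic cohorts

The generator encodes the contrast the analysis is about. Expression is
drawn directly on the log scale (Gaussian, clipped at 0; gene means 2.5–3.0
and noise SD 0.5 keep the clip ≳4 SDs away, so the Gaussian factor model is
effectively exact). In `breast_like` mode one latent N(0,1) infiltration
factor loads with weight λ (`til_loading`, default 0.7; tests use 0.9) on
the IP genes, PSME1/2 and the TIL/IFN markers (CD3E, CD8A, PRF1, IFNG,
EMR1). In `aml_like` mode the IP genes load on a separate cell-intrinsic
factor and the markers stay on the infiltration factor, decoupling the two.
CP genes load on their own factor (weight 0.7) in both modes, so the
8-subunit PCA shows two co-expression blocks. The closed-form correlation
between the summed IP z-score and one marker under this model,
3λ² / (√(9λ² + 3σ²)·√(λ² + σ²)), is exported as
`expected_marker_correlation` and checked by simulation. λ has no published
value; the defaults are calibration choices of this package.

FAB labels are drawn from a mix resembling an adult AML cohort (M3 9%,
M5 12%); in `aml_like` mode IP expression is shifted by +δ in M5 samples and
−δ in M3 (δ = `ip_fab_shift`, default 0.5 log units ≈ 3-fold RPKM). The
shift is a myeloid-subtype effect and is not applied in `breast_like` mode.

Survival is exponential proportional hazards on the standardised IP score
(log-HR `beta_surv` per SD; baseline hazard ln 2/1500 days ≈ median 4
years). Censoring is administrative, Uniform(0, h), with h solved
numerically so the expected censored fraction matches `censoring_frac`
(default 0.5). The analysis scripts use `beta_surv` = −0.3 (protective) for
the breast-like cohort and +0.2 (adverse trend) for the AML-like cohort,
matching the direction of the contrast being emulated.

Methylation: for each target gene, CpG beta values are
`logistic(slope · (ρ_m·z_expr + √(1−ρ_m²)·ε))` with ρ_m ∈ [−1, 0] (promoter
methylation represses transcription, so only anti-correlation is modelled);
planted sites sit strictly within the ±10 kb TSS window, decoys outside it
with independent beta. The logistic link attenuates Pearson r only mildly
at slope 1 (ρ_m = −1 still yields r < −0.9).

What the generator does **not** emulate: batch effects, tumour purity,
count noise, library-size artefacts, linkage disequilibrium among CpGs, or
realistic gene-gene correlation beyond the planted factors and blocks.
Passing tests therefore certify the statistical machinery and its planted-
signal recovery, not performance on real cohort data.

## Structure analyses

PCA of the eight subunit genes (PSMB5–10, PSME1/2) is an
eigen-decomposition of the covariance of z-scored expression (correlation
PCA — forced by scoring on z-scores), with signs fixed so the
alphabetically first gene has non-negative loadings. Hierarchical
clustering of samples on PSMB8/9/10 Euclidean distances uses complete
linkage (none is named in the protocol) and an always-explicit k (default
5, matching the manual tree cut being reproduced; never inferred). Cluster
× category enrichment uses the two-sided Fisher exact test with odds ratio
ad/bc, Haldane 0.5 correction only when a zero cell occurs.

The methylation filter keeps a CpG iff |Pearson r(beta, log expression)| >
0.2 **and** |signed TSS distance| < 10 kb, both strict, matching the
printed inequalities. All annotated sites are scored and returned
(score-then-window) so both gates stay auditable.

## Networks and co-clustering

Per condition, all gene pairs are scored by |Pearson r| and exactly
⌈centile · n_pairs⌉ edges are kept (default centile 0.01), counting pairs
among genes with nonzero variance; ties at the threshold are filled in
lexicographic pair order so edge sets are exactly reproducible.
Zero-variance genes remain as isolated nodes.

Cross-layer alignment tests each shared gene's expression distribution
between conditions with a two-sided Mann–Whitney–Wilcoxon test. The default
rule aligns a gene iff p ≥ α (not detectably different, consistent with the
stated goal of enriching for gene similarity); the protocol's wording could
also be read as aligning at p < α, so `rule="different"` is available, and
the default is a documented choice, not a resolution of that ambiguity.

Co-clustering maximises H = Q_A + Q_B + κ·(same-cluster fraction over
aligned genes), with Q the Newman–Girvan modularity of each thresholded,
unweighted graph and cluster labels shared across layers (an
OrthoClust-style coupled objective; κ default 1). Optimisation is simulated
annealing over single-node reassignments (including to a fresh cluster)
with geometric cooling (T₀ = 1, ratio 0.99, 20 sweeps per temperature,
stop below 1e-3 — sized so exhaustive-oracle toys are solved to the global
optimum while a 40-node two-layer problem anneals in ~2 s), followed by a
zero-temperature greedy polish; labels are canonicalised by cluster size.
Every stored objective is re-verified against a full recomputation.
IP-correlate extraction returns, per IP gene, the genes sharing both its
cluster and an edge with it; companion-identity summaries are computed over
non-IP correlates, since the IP genes themselves are neither immune nor
metabolic companions.

## Enrichment

The threshold Fisher test is one-sided (enrichment only), with
Benjamini–Hochberg q-values over the tested terms. A term is enriched only
if q ≤ 0.05 **and** odds ratio > 2 (strict); with zero query overlap the OR
is defined as 0, so such terms can never pass. The q ≤ 0.05 criterion is
this package's declared default — the original in-house tool printed only
the OR floor. Semantic grouping of terms uses an explicit term → category
map supplied by the user (the web-service grouping step is not reproducible
infrastructure); percentages are over all enriched terms, and any "hide
categories under 10%" flooring is left to rendering.

## Problem sizes and numerical checks

The test suite and the acceptance script exercise: cohorts of n = 500;
methylation at n = 300 with 30 planted and 400 null CpGs; planted two-layer
networks of 2 × 10 genes at n = 200/layer over 10 seeds; exhaustive
partition oracles on two-layer toys of 8 nodes total (4 140 partitions);
an exhaustive sweep of all 2×2 tables with total ≤ 40 against exact integer
hypergeometric enumeration; 100 Cox replicates at 400/group for CI
coverage; and 200 null log-rank replicates. Exhaustive joint-partition
enumeration grows as the Bell numbers, which is why the oracle toys stop at
8 nodes total.

## Known limitations

* The annealer is a stochastic heuristic; global optimality is only
  guaranteed on the exhaustively checked toys.
* The MWW alignment rule ambiguity (above) is exposed, not resolved.
* No multivariable Cox adjustment; hazard ratios are group contrasts only.
* Gene-set enrichment takes sets as given (no GO-graph propagation).
* The drug-response contrast is an unpaired rank-sum test: the high and low
  expression deciles contain different cell lines, so the "paired" label
  sometimes attached to this comparison cannot apply.
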