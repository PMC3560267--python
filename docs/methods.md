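# Methods

## Statistical model

The unit of inference is a k-way locus combination among M biallelic SNPs
coded 0 (homozygous reference), 1 (heterozygous), 2 (homozygous variant),
with a binary phenotype (1 = case). Subjects are cross-classified into the
3^k genotype cells of the combination; cell j holds X_j cases and Y_j
controls. With p₀ the overall case fraction (the naive-Bayes threshold), a
cell is high predisposing risk iff X_j/(X_j+Y_j) > p₀ — strictly: ties and
empty cells (the ratio of an empty cell is taken as 0) are low risk, which
also fixes the score of genotype combinations never seen in the analysis
sample at 0. Collapsing cells into high/low strata gives a 2×2 table with
margins n_{s+}, n_{+t} and expected counts e_st = n_{s+} n_{+t} / N.

Three raw statistics summarize the table: the odds ratio
OR = n₁₁n₂₂/(n₁₂n₂₁), the relative risk
RR = [n₁₁/(n₁₁+n₁₂)] / [n₂₁/(n₂₁+n₂₂)], and the Pearson chi-square
Chi = Σ (n_st − e_st)²/e_st. Because the high/low split is selected by the
data, all three are stochastically inflated under the null (the median
permuted OR on a typical null dataset is ≈ 1.5, not 1), so nominal
asymptotics do not apply.

## Empirical calibration

Two empirical distributions are estimated per combination, shared by all
three statistics:

* **F₀ (null)** — the statistic over B phenotype permutations. Each
  subject's SNP vector stays intact; only labels are reshuffled, the
  threshold p₀ is label-count invariant, and the high/low classification
  is redone per permutation (the selection effect is part of the null).
* **F (alternative)** — the statistic over B_j jackknife subsamples
  keeping a fraction f of subjects (SNPs and phenotype kept paired), with
  threshold and classification recomputed per subsample. Subsamples
  missing a phenotype class are redrawn.

The calibrated statistic is x_obs / F₀⁻¹(F(x_obs)) with the empirical CDF
(fraction ≤ x) and its order-statistic inverse (inf{x : ECDF ≥ p};
the ceil(pB)-th order statistic, sample minimum at p = 0). Under no
association F ≈ F₀ and the ratio centres at 1.

Numerical conventions: OR and RR receive the +0.5 continuity correction on
all four cells whenever any cell is zero, keeping resampled values finite;
Chi uses uncorrected counts with margin-zero tables contributing 0 (their
observed and expected counts vanish together); a non-positive null
quantile in the calibration denominator (possible for Chi) is clamped to
the smallest positive null sample. A table with an empty high- or
low-risk margin is flagged degenerate and reported with p-value 1.

**p-values.** The permutation p-value is the upper tail
(1/B) #{i : x_obs < x_i} with strict inequality, computed on the raw
statistic's scale. This equals the p-value obtained after transporting
observed and permuted values through any common monotone calibration, and
avoids re-scaling null-range values by near-zero null quantiles, which
destabilizes the reference distribution. An add-one conservative variant
is available. FDR adjustment is Benjamini–Hochberg per statistic across
all C(M, k) combinations.

**Confidence intervals.** The 95% interval takes the 2.5th/97.5th
order-statistic percentiles of the jackknife values divided by the
observed statistic's calibration denominator, after inflating log-scale
deviations from their mean by the delete-d jackknife factor
sqrt(m/(n−m)) (m = kept subjects). A keep-90% subsample understates
full-sample variability by exactly that factor; without the inflation the
interval collapses onto the point estimate and covers 1 in only ~65% of
null replicates, versus ~100% with it, while under a strong planted signal
the inflated interval still excludes 1 in ≥93% of replicates. Percentile
intervals of the calibrated permutation statistics are available as an
alternative (`ci_source="permutation"`).

## Risk aggregation

Subject n's epistasis-enriched score counts the significant interactions
(p-value strictly below α̂) whose high-risk cell set contains the
subject's genotype combination. α̂ maximizes the AUC of the score over
candidates in (0, 0.05]; since inclusion is strict, every achievable set
of significant interactions is realized by using an observed p-value as
the threshold, so the candidate grid is the distinct observed p-values
plus 0.05, scanned in ascending order with ties in AUC broken toward the
sparsest model. AUC is the rank/concordance statistic with half credit
for ties; ROC points are taken at every distinct score threshold. The
classification cutoff scans midpoints between adjacent distinct scores
(plus a half-step beyond either extreme) maximizing overall accuracy,
ties toward the lower cutoff. Scores, α̂, AUC and cutoff are evaluated
in-sample on the analysis dataset; no holdout is performed.

## Original MDR reference

The comparison method searches all C(M, k) combinations with stratified
k-fold cross-validation (per-class fold sizes differing by ≤1; fold
assignment seeded and derived from id-sorted subject order, so results do
not depend on row order). Within each training set, cells are classified
against that training set's own case fraction; the best model maximizes
mean testing accuracy (ties: higher cross-validation consistency, then
lexicographic order), and CVC counts the folds in which the model had the
best training accuracy. The permutation test re-permutes labels and
re-derives folds per replicate; by default the reference distribution is
the *selected model's own* CV testing accuracy under permutation (a test
of that model's association). A selection-corrected variant that re-runs
the full search per permutation and compares against the permuted
best-of-all accuracy (`null="search"`) is substantially more conservative
and is available as an option.

## Synthetic data

The simulator emulates candidate-gene case-control studies: five loci with
independent Hardy–Weinberg genotypes ((1−q)², 2q(1−q), q²) in linkage
equilibrium, and disease assigned through 3×3 two-locus penetrance tables.
Four built-in models are used: two purely epistatic tables with no
marginal effects (MAF 0.5; maximum penetrance 0.1 and 0.05) and two noisy
tables with small marginal components (MAF 0.25). Architectures:

* **A (single pair)** — P(D=1|g) = p₁₂(g₁, g₂); loci 3–5 are inert.
* **B (genetic heterogeneity)** — a latent source splits the *affected
  sample*: a fraction γ₁ of the cases is generated by the loci-1×2
  process and γ₂ = 1−γ₁ by loci 4×5 (case quotas are fixed, so the
  mixture weights are the case-sample composition, not population
  priors); controls are rejection-sampled against γ₁p₁₂ + γ₂p₄₅.
* **C (additive)** — union of two independent disease processes,
  P(D=1|g) = p₁₂ + p₄₅ − p₁₂p₄₅.

Balanced samples (n/2 cases, n/2 controls) are produced by rejection
sampling with a 10⁷-candidate budget. The generator does not emulate
linkage disequilibrium, covariates, missing genotypes, genotyping error or
population stratification, so passing tests demonstrate statistical
correctness of the machinery under idealized sampling, not robustness to
those real-data features.

The power harness runs R replicated datasets per condition; a calibrated
statistic rejects a pair when its FDR-adjusted p-value is below 0.05
(matching the conservative empirical type-I rates of the method; the
unadjusted rule is available), and MDR rejects a pair only when it is the
best CV model *and* its permutation p is below 0.05. Type-I error is the
mean rejection rate over pairs of loci absent from the susceptibility
formula; pairs sharing one causal locus are excluded because, under the
noisy penetrance models, those loci carry marginal effects and such pairs
are genuinely associated with the phenotype.

## Defaults and problem sizes

| parameter | default | meaning |
|---|---|---|
| B | 1000 | phenotype permutations per combination (null ECDF, p-values) |
| B_j | 200 | jackknife draws per combination (alternative ECDF, CIs) |
| fraction | 0.9 | kept subject fraction per jackknife draw |
| k | 2 | interaction order |
| folds | 10 | MDR cross-validation folds |
| rejection rule | FDR < 0.05 | per-pair significance in the power harness |
| reps | 100 | datasets per power-study condition |

All randomness flows from one seed through named substreams (simulation,
permutation, jackknife, CV folds), so runs are bit-reproducible and
changing one resample count does not perturb the others. The test suite
and the reproduction script use the study conditions above (100 replicates
per condition; MDR permutation count 200 within the harness); the
brute-force agreement checks run at deliberately small sizes (N ≤ 30,
M ≤ 4, B ≤ 50) where loop-based recomputation is exact.

## Known limitations

* A single interaction order k per risk score; mixing orders (or adding
  main effects) into one score is not supported.
* No asymptotic distributions for the calibrated statistics — inference
  is purely resampling-based, and p-value resolution is 1/B.
* The exhaustive search is O(C(M, k)·3^k·N) per resample; the
  implementation is vectorized but not parallelized, targeting
  candidate-gene panels rather than GWAS scale.
* In-sample evaluation of AUC/accuracy is optimistic by construction;
  the α̂ selection maximizes in-sample AUC.
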