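# Methods

This note records the statistical model the package implements, the
conventions chosen where the method is commonly described only verbally,
the numerical details that affect reproducibility, and what the bundled
synthetic-data generator does and does not emulate.

## Score statistic

The phenotype is reduced to one real score per subject before any genotype
is examined: the response residual `s_i = y_i − μ̂_i` from a GLM of
phenotype on covariates with intercept. Families: Gaussian/identity for
quantitative traits, Bernoulli/logit for binary, Poisson/log for counts.
Response residuals (rather than deviance or Pearson residuals) are used in
all three families: they coincide with the linear-regression residual in
the quantitative case and are proportional to the GLM score contribution in
the canonical-link families, and the maximum-likelihood score equations
with an intercept force them to sum to zero — the property that makes 0 a
principled high/low-risk threshold downstream. Intercept-only models are
fit in closed form (the MLE fitted mean is the sample mean in all three
families), so a balanced binary trait without covariates yields scores of
exactly ±0.5. GLM fits with covariates go through statsmodels; logistic
separation and non-convergence are raised as errors naming the covariates
rather than silently producing degenerate scores. User-supplied scores are
accepted verbatim; they should be centered, and the documentation says so.

## Cell classification and accuracy

A k-SNP combination maps each subject with complete genotypes at those k
SNPs to one of 3^k cells (subjects missing any of the k calls are excluded
for that combination only — missing genotypes are never imputed). Within a
training set, a cell is high-risk iff the sum of its training scores is
strictly positive. Conventions, all deliberate and tested:

- tie (cell sum exactly 0) → low-risk;
- cell never seen in training → unclassified, treated as low-risk at
  evaluation (a flag instead excludes such subjects from the testing
  denominator);
- the accuracy of a labelling on an evaluation set is the score-weighted
  balanced accuracy given in the README; it is invariant to positive
  rescaling of the scores and equals classical MDR balanced accuracy when
  scores are ±constant;
- an evaluation set with no positive-score (or no negative-score) subjects
  contributes ½ for the missing class term, so the degenerate single-cell
  model on mean-zero scores gets accuracy exactly 0.5.

The accuracy formula is the package's central documented assumption: the
method's literature defers the formula to earlier work, so the reduction
property above (exact agreement with MDR balanced accuracy in the binary,
covariate-free case) is the justification for this choice.

## Cross-validation, ranking, CVC

Folds are an equal-size (±1 subject) seeded random partition, K = 10 by
default, stratified by case/control for binary traits (off for
quantitative; the stratified assignment cycles fold labels across label
groups so overall sizes stay balanced). Per training set, combinations are
ranked by training accuracy with ties broken lexicographically by SNP index
tuple — an arbitrary but bit-reproducible rule. CVC = number of training
sets ranking a combination in the top n (default n = 1); candidates require
CVC strictly greater than K/2. The same fold assignment is reused at every
interaction order so CVCs are comparable across orders.

## Permutation test

Scores are permuted across subjects; folds and genotypes stay fixed; cell
models are re-fit per training set and the testing-accuracy average
re-computed. p = M/N with M counting permuted accuracies ≥ observed
(strict-greater available behind a flag); M = 0 is reported as the bound
"< 1/N" (add-one estimator (M+1)/(N+1) available). Comparisons use a 1e-12
tie tolerance so exact ties are not broken by float summation order. Each
combination draws from an independent stream seeded by (global seed,
combination tuple), making p-values independent of evaluation order and of
whether other combinations were tested. Permutations are evaluated in
vectorised batches (default 512) via a cell-indicator matrix product per
fold. The genome-scale default of 10^7 permutations is configurable; the
package's default is 10^4, sized for interactive desk use.

## Quality control

Per SNP: missingness (fraction of missing calls), MAF = min(f, 1−f) with
f = (2n₂+n₁)/2n over non-missing calls, and the exact conditional
Hardy-Weinberg test (enumeration over heterozygote counts compatible with
the observed allele totals, computed in log-space; probabilities no more
probable than the observed outcome are summed, with a 1e-12 relative guard
for mirror-symmetric ties; monomorphic → p = 1). A chi-square variant is
available. For binary traits, missingness and MAF must pass in cases and
in controls separately and HWE is tested in controls only; quantitative
traits use the full sample. All threshold comparisons are strict
(removal when missingness > 0.10, MAF < 0.05, HWE p < 0.001), so values
exactly at a threshold survive. Filters are evaluated from the raw column
in the fixed order missingness → MAF → HWE; only the recorded `reason`
depends on that order, not the kept set.

## Staged search

The distance filter skips any combination containing two SNPs on the same
chromosome strictly closer than 1 Mb (default); inter-chromosomal pairs
always pass, since physical distance across chromosomes is undefined and
the rule exists to avoid linkage-disequilibrium artifacts. The exhaustive
two-way search feeds harvesting: the union of SNP indices over each fold's
top-n pairs (the same n as selection). Higher orders (3–5) search only
combinations drawn from the harvested subset, with the distance filter
still applied. The significance filter keeps CVC ≥ final_cvc_min and
p ≤ final_p_max, where a bound "< 1/N" qualifies iff 1/N ≤ final_p_max;
when `final_p_max` is not set the pipeline uses 1/n_perm, the finest
threshold the permutation resolution can certify. A core SNP is one
appearing in ≥ `core_min_models` (default 2) distinct significant models of
any orders; the rule is parameterized because the practice it encodes is
described only verbally in the method's literature, and the report lists
each core SNP's supporting models so the rule is auditable.

## Determinism

One config seed fans out to named substreams (folds; one permutation
stream per combination; the simulator). The pipeline sorts subjects
lexicographically by subject id after loading, so outputs are invariant to
input row order, and two runs with the same config and inputs produce
byte-identical result tables. Output files contain no timestamps.

## Synthetic-data generator

Genotypes are independent Hardy-Weinberg draws at specified MAFs; loci are
simulated without linkage disequilibrium (the 1 Mb filter is exercised
through SNP positions instead). Phenotypes come from a k-locus penetrance
table (binary), a cell mean-shift plus Gaussian noise (quantitative), or a
log-mean table (counts), optionally with additive standard-normal
covariate effects; the null model draws the phenotype independently of all
genotypes. The canonical planted fixture is the two-locus XOR
(checkerboard) model — affected iff exactly one locus is heterozygous —
which at MAF 0.5 has zero marginal effect at either locus and hence
isolates pure interaction detection. What passing tests on these data show:
the machinery classifies, ranks, and calibrates correctly under
independence and detects planted epistasis. What they do not show:
robustness to LD structure, population stratification, genotyping batch
effects, or case-control ascertainment, none of which the generator
emulates.

## Problem sizes and defaults

- K = 10 folds; top n = 1 per fold; candidate rule CVC > K/2; final filter
  CVC ≥ 7/10 with p ≤ 1/n_perm unless configured otherwise.
- Null calibration runs 200 replicates of n = 300 subjects × 10 SNPs with
  200 permutations — enough for the binomial 99% band around α = 0.05 to
  be informative while staying interactive.
- Planted-interaction recovery runs n = 800 subjects × 20 SNPs (190 pairs),
  20 noise-free and 100 attenuated (penetrance 0.9/0.1) replicates; at
  these sizes recovery is essentially certain, which is the point of the
  fixture.
- The 6-subject worked example (cells {+3,−1}, {+1,−2}, {+2,−3} → accuracy
  2/3) is the hand-checkable anchor for the accuracy formula.

## Known limitations

Exhaustive search is O(C(m,k)) evaluations and is intended for candidate
panels or harvested subsets, not a million-SNP genome at k ≥ 3; the
permutation default (10^4) bounds attainable p-values at 10⁻⁴. Phased
haplotypes, X-chromosome coding, dosage genotypes, subject-level QC and
meta-analysis across datasets are out of scope. The high/low threshold of
0 presumes centered scores; supplying uncentered user scores shifts every
cell toward one class and the documentation flags this.
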