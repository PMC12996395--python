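# Methods

This note documents the statistical models implemented in `endosafe`, the
parameters that matter, the synthetic-data model used to exercise them, and
the numerical and design choices that were genuinely open.

## Cell-type deconvolution

Bulk endometrial methylation at a marker CpG *g* is modelled as
`beta_gj = sum_k pi_jk m_gk + noise`, where `pi_j` lies on the probability
simplex over cell types and `m_gk` is the expected beta of cell type *k*.
Proportions are the constrained least-squares solution (non-negativity and
sum-to-one). The solver enumerates candidate support sets and solves the
equality-constrained normal equations (KKT system) on each; for the small
cell-type counts involved (3 compartments, 6 immune subtypes) this is exact,
deterministic, and trivially cheap, avoiding iterative-solver tolerance
questions entirely. Robust-regression deconvolution modes are deliberately
not implemented; constrained least squares is the testable, contract-stable
choice, and its estimates can diverge numerically from robust-partial-
correlation implementations of the same idea.

Hierarchical (two-level) inference runs the level-1 solve on compartment
markers, then a second solve on immune-subtype markers, and multiplies the
subtype fractions by the level-1 immune fraction *ic*. A subtype whose
estimated fraction stays below a detection threshold in every sample is
reported "undetected" and excluded from trial comparisons. The default
threshold is 1e-3, appropriate for clean or low-noise input; on noisy small
cohorts the non-negativity-truncated noise floor is nearer 1e-2, and the
threshold is exposed as a parameter (`undetected_threshold`) for that
regime.

## The methylation index

Given a case/control beta matrix with ages and deconvolved *ic*:

1. **Split** — label-stratified 70/30 train/test, subjects kept together.
2. **Adjusted per-CpG models** (training data only) — OLS of beta on
   (group, age, *ic*); two-sided t-test on the group coefficient;
   Benjamini-Hochberg FDR across all tested CpGs. Constant CpGs are flagged
   with p = 1.
3. **Delta-beta at ic = 0** — within cases and within controls separately,
   OLS of beta on *ic* alone; the difference of the two intercepts
   estimates the case/control methylation difference in a notional
   immune-free tissue. The group-wise model deliberately contains no age
   term: with beta linear in *ic*, the intercept-at-zero interpretation is
   exact in this form. *Estimand caveat:* in a three-compartment tissue the
   intercept at *ic* = 0 reflects the whole non-immune compartment, so the
   statistic recovers `delta * E[epithelial share of non-immune tissue]`
   rather than the pure epithelial `delta`; it is unbiased exactly when the
   non-immune compartment is essentially epithelial. This is a property of
   the estimator, not of the implementation, and drives the simulation
   defaults below.
4. **Ranking** — by |delta-beta at ic = 0| descending, ties broken
   lexicographically by CpG id; by default restricted to FDR-significant
   CpGs (q < 0.05), with a flag to rank all.
5. **Grid and selection** — one penalised logistic classifier per
   (alpha, feature count) cell, alpha in {0, 0.5, 1} and counts 100, 500,
   1000, then 1000-steps. Features are standardised internally
   (means and sds stored in the model); penalty strength is chosen by
   5-fold stratified cross-validated deviance over a 20-point logarithmic
   path (C in 1e-3..1e3). Twenty points was chosen over a denser path
   because the deviance curve is smooth at these sample sizes and the full
   grid must stay cheap on one CPU; an optional glmnet-style one-standard-
   error rule (`penalty_selection="1se"`) trades a little deviance for
   sparser supports. Each cell is evaluated on the held-out test set by
   AUC (Mann-Whitney concordance, ties 0.5) and calibration slope and
   intercept (maximum-likelihood logistic regression of outcomes on
   logit of the predicted probability).

   **Selection rule.** Test AUC governs, but AUC differences below 0.02 —
   about one Hanley-McNeil standard error for an AUC near 0.95-0.98 on a
   30-versus-30 test set, i.e. a handful of discordant pairs — are treated
   as ties and resolved by calibration closeness |slope - 1| + |intercept|,
   then smaller feature count, then smaller alpha. A strict
   max-AUC-first rule was rejected: whenever some grid cell separates a
   small test set perfectly (AUC = 1), the calibration MLE for that cell
   diverges, so strict lexicographic ordering systematically returns an
   uncalibratable model; the practical-equivalence rule returns the
   best-calibrated model among those statistically indistinguishable in
   discrimination.

Scores are reported on the linear-predictor (log-odds) scale: index
comparisons need ordering and shifts only, and log-odds avoids probability
saturation. At scoring time up to 10% of model features may be absent; they
are imputed at their stored means and so contribute zero after
standardisation.

## The expression index

Transcript counts are collapsed to gene symbols by summation, filtered on a
minimum-count rule (two presets: at least 10 counts in strictly more than
80% of samples for tumour cohorts; at least 1 count in 80% or more for
small trial data — the strictness is a flag because both conventions are in
use), normalised with median-of-ratios size factors (genes containing any
zero are excluded from the reference set), and transformed to
`log2(count/s + 1)`.

Differential expression is a per-gene negative-binomial GLM with log link
and log-size-factor offsets, fitted by a vectorised IRLS over all genes
simultaneously, with a Wald test on the group coefficient. Dispersions are
method-of-moments estimates on normalised counts, pooled across the two
groups and floored at 1e-8. This is a deliberately plain estimator — no
dispersion shrinkage, no fold-change shrinkage, no independent filtering —
because the contribution here is the index recipe, not the DE machinery;
expect numerical differences from shrinkage-based DE packages, mainly for
low-count genes. Under the null its type-I rate at p < 0.05 is calibrated
to within about a percentage point at 20 samples per arm.

Significant genes (raw p < 0.01 by default; q-values are also computed)
feed a single elastic-net logistic fit (mixing 0.5, exposed as a
parameter; no alpha-by-count grid). The retained genes are the nonzero-
coefficient features. The resulting model reuses the methylation index
contract, so serialisation and scoring are one code path.

Gene-set shift scores are mean per-gene z-scores: each gene is z-scored
across samples, and a sample's set score is the mean z over member genes.
This is the package's own definition — simple, linear, and with an exact
null (scores sum to zero across samples). Zero-variance genes are excluded.
The correlation-signature rule selects genes whose maximum Pearson r with
any anchor gene strictly exceeds a threshold (default 0.75), anchors
excluded.

## Trial statistics

Paired pre/post comparisons use the two-sided Wilcoxon signed-rank test.
Zero differences are discarded before ranking (classical convention; Pratt
handling is available behind a flag). With no ties among |differences| and
at most 25 effective pairs, the full null distribution of W+ is computed by
dynamic programming over integer ranks and the two-sided p is
`min(1, 2 min(P(W+ <= w), P(W+ >= w)))` — at n = 8 the smallest attainable
value is 2/2^8 = 0.0078125. Otherwise a tie- and continuity-corrected
normal approximation is used. Between-arm comparisons of post - pre changes
use the Mann-Whitney test with the same exact/approximate structure
(exact when n_x n_y <= 400 and untied). Both exact branches are verified
against brute-force enumeration in the test suite.

Covariate adjustment residualises a per-sample score on age and fibroblast
fraction by OLS with intercept, pooled across all analysis samples (both
arms and both timepoints) — at 14 pairs, per-arm fits would spend too many
degrees of freedom. Residuals are exactly orthogonal to each covariate and
the operation is idempotent. Exactly collinear covariates raise an error
naming the pair.

Sample identity is checked on genotype-like SNP probes: beta < 0.25 calls
AA, 0.25-0.75 AB, > 0.75 BB; a subject passes when at least 90% of calls
agree between pre and post samples. The thresholds reflect the standard
tri-modal clustering of such probes. Subjects failing the gate are excluded
before any comparison, and the run manifest records the exclusions.

## The synthetic-data model

**Methylation cohorts.** Each sample draws cell proportions from a
group-specific Dirichlet and an age uniform on `age_range`. Expected beta
is the convex mixture of per-cell-type baselines: reference values at
marker CpGs, a shared mid-range baseline elsewhere. Case-specific effects
(`n_differential` CpGs, magnitudes uniform on `delta_range`, random sign)
are injected into the epithelial component only, so a sample's expected
shift is `delta * pi_epithelial`; age adds a linear drift
(`age_slope` per year, default 0.002) at `n_age_cpgs` background CpGs.
Observed betas are Beta-distributed around the expectation with
concentration `noise_concentration` — the (mean, concentration)
parameterisation respects the [0, 1] support, unlike additive Gaussian
noise. Defaults (100 + 100 samples, 5000 CpGs, 5% differential, deltas
0.1-0.4, concentration 50) emulate a tumour-versus-normal array cohort at
desk scale.

The default cohort composition is epithelial-plus-immune dominant (Dirichlet
alphas 12/0.3/3.7 for cases, 10/0.3/5.7 for controls): per the estimand
caveat above, delta-beta at *ic* = 0 is unbiased only in this
two-compartment regime, and the cohort model is the regime in which the
index recipe's own assumption (composition = epithelium diluted by immune
infiltrate) holds. The trial generator instead uses the endometrial
composition (Dirichlet 11/6.2/2.8, i.e. roughly 55% epithelial, 31%
fibroblast, 14% immune) where compositional change, not delta recovery, is
the target.

**RNA-seq cohorts.** Counts are negative binomial with
`mean = depth_j q_g FC_g^{case}`, log-normal gene baselines, per-sample
depth factors, and `n_de` genes carrying signed log2 fold-changes from
`lfc_range`. At dispersion 0 the generator reduces to Poisson.

**Trials.** Two samples per subject (pre/post), default 8 treated and 6
comparator pairs — the paired molecular cohort size this package is built
around. Treated subjects' post-treatment fibroblast fraction is shifted by
`fibroblast_shift` (default +0.05, the direction and size of compositional
change the analysis is designed to detect) and renormalised on the simplex;
`index_effect` (default 0: the no-oncogenic-change null) moves treated post
samples along the stored case-signal axis. A block of 59 genotype-like SNP
probes (centres 0.05/0.5/0.95, jitter sd 0.01) is constant within subject.
When a level-2 reference is supplied, immune-subtype markers are appended
with CD8T held at exactly zero; at those markers the synthetic non-immune
compartment mirrors the immune-average methylation, which makes two-stage
deconvolution factorise exactly.

**What the generator does not emulate:** array probe annotation and
genomic coordinates, batch and chip effects, menstrual-phase biology beyond
a carried label, transcript-level structure, and any coupling between the
methylation and expression noise of a sample. Passing tests therefore
establish the correctness and calibration of the machinery under the
stated model, not performance on real arrays.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each property is sharply testable:
deconvolution recovery at 100 samples x 150 markers; delta-beta recovery at
100 per arm x 3000 CpGs with 200 differential CpGs; the full index grid at
200 samples x 5000 CpGs over 21 grid cells; trial null and power studies at
500 replicates of the 8 + 6 pair design; DE calibration at 2000 genes x 40
samples. The index-grid cohort uses a moderate signal (40 differential
CpGs, deltas 0.04-0.12, concentration 20): strong enough for held-out AUC
near 0.97, weak enough that the test scores of the two classes overlap —
with perfect separation the calibration-slope MLE diverges and calibration
becomes unmeasurable. Even in this regime the slope estimate from a
60-sample test set is noisy (roughly half its sampling distribution lies
outside 1 +/- 0.3), a known small-sample limitation of calibration
assessment rather than of the pipeline.

Every stochastic stage takes an explicit integer seed and is bit-
reproducible; simulation, splitting, cross-validation folds and solver
behaviour are pure functions of (inputs, seed). Tie-breaks are
lexicographic and documented where they occur (CpG ranking, grid
selection).
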