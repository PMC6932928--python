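# Methods

`esometh` implements a two-stage marker workflow for DNA methylation
(Illumina 450K-style beta-values) of the esophagus: a multiclass diagnostic
classifier for normal squamous esophagus (NSE), Barrett's esophagus (BE),
esophageal adenocarcinoma (EAC) and esophageal squamous cell carcinoma
(ESCC), and per-histology prognostic risk scores for overall survival. This
note records the models, the numerical choices, and what the synthetic-data
experiments do and do not demonstrate.

## Differential methylation: moderated t

For a two-group comparison at CpG g with group sizes n_a, n_b, the effect
is Δβ_g = mean_a − mean_b on the beta scale and the pooled variance s²_g has
d_g = n_a + n_b − 2 degrees of freedom. Variances are shrunken toward a
common prior by the standard empirical-Bayes scheme: assuming
s²_g | σ²_g ~ σ²_g χ²_{d}/d and 1/σ²_g ~ χ²_{d0} s0⁻²/d0, the
hyperparameters (d0, s0²) are estimated by moment matching on
z_g = log s²_g, using the digamma/trigamma identities of the log scaled-F
distribution; d0 solves a trigamma equation by Newton iteration (with the
asymptotic branches 1/√y and 1/y used for extreme targets). The posterior
variance is s̃²_g = (d0 s0² + d_g s²_g)/(d0 + d_g) and the moderated t
statistic Δβ_g / (s̃_g √(1/n_a + 1/n_b)) is referred to a t distribution on
d0 + d_g degrees of freedom (normal when the moment equations indicate
d0 = ∞, i.e. no excess variance heterogeneity). CpGs with zero sample
variance are excluded from hyperparameter fitting. Tests are run on
beta-values, not M-values, so the Δβ effect-size thresholds apply directly;
this choice trades some variance homogeneity for interpretability of the
effect scale.

Benjamini–Hochberg adjustment is applied within each pairwise comparison
across CpGs. A CpG is a **tissue-specific marker** for a target class when
its adjusted p-value is below the FDR threshold (default 0.05) in *all
seven* comparisons of that class against the other tissue classes — the
intersection rule that discards CpGs behaving identically in an esophageal
class and an adjacent-organ class (head-and-neck or stomach), the failure
mode of markers collected by non-endoscopic sampling devices. **DMCs** for
the prognostic arm require |Δβ| > 0.2 and FDR < 0.05, both strict.

## Diagnostic classifier

Selection model: multinomial logistic regression with a grouped lasso
penalty,

    min  −(1/n) Σ_i log p_{i,y_i} + λ Σ_j ‖β_j·‖₂ ,

with unpenalized intercepts and the class coefficients of each CpG
penalized as one group, so a CpG enters or leaves the model for all four
classes simultaneously. Features are standardized to training-set mean 0 /
variance 1 before penalization; reported coefficients are mapped back to
the beta scale. The solver is FISTA (accelerated proximal gradient) with
the fixed step 1/L, L = 0.5·σ_max(X̃)²/n an upper bound of the multinomial
Hessian, monotone restarts, and exact group soft-thresholding; convergence
is declared on relative objective change (default 1e-10) and can be
polished to a stationarity (KKT) tolerance. Softmax identifiability is
fixed by sum-to-zero rows/intercepts, which is prediction-invariant and
penalty-minimal.

λ is tuned by stratified 10-fold cross-validation over a path of 100
log-spaced values from λ_max (computed from the null-model gradient) down
to 10⁻³ λ_max, with warm starts along the path. The one-standard-error
rule is applied to CV *accuracy*: the chosen λ is the largest one whose
mean accuracy is at least the maximum mean accuracy minus the standard
error at the maximizer (ties at the maximum resolve to the larger λ).

Stability selection repeats this on 10 stratified 2:1 train/test
partitions of the cohort; each partition contributes the set of CpGs with
any nonzero coefficient at its chosen λ, and CpGs selected in ≥ 9 of 10
partitions form the final panel (partitions are stratified by class even
though the source protocol says only "randomly partitioned": with ~60
samples in the smallest class, unstratified splits can starve CV folds).
The final model is a multinomial logit on the panel fit by maximum
likelihood with a tiny ridge term (1e-6) that guarantees a finite optimum
under quasi-separation; it serializes to JSON losslessly (double-precision
round trip), so a stored model reloads with bit-identical predictions.

## Prognostic risk score

Per histology (EAC or ESCC, never pooled): DMCs from the tumor-vs-NSE
contrast are screened one at a time in a Cox proportional-hazards model
(Efron ties) adjusted for age, gender, BMI, smoking, alcohol use and
advanced AJCC stage (III/IV vs I/II); the CpG's *covariate-adjusted Wald
p-value* < 0.05 — not a multiplicity-adjusted p — defines the candidate
set. Candidates enter an L1-penalized Cox model whose stability is
assessed over 100 replicates of subsampling 75% of patients without
replacement; within each replicate the penalty path is tuned by 5-fold
cross-validation on the partial-likelihood deviance and the refit support
is recorded. CpGs selected in strictly more than 30 of 100 replicates form
the panel. The risk score is the linear predictor of an unpenalized Cox
refit on the panel; patients split into high/low risk at the median score
of the fitting cohort (ties at the median go low), and the stored cutoff
applies unchanged to external samples.

Cross-validated deviance uses the Verweij–van Houwelingen construction,
dev_k(λ) = −2[ pll(all; β_{−k}) − pll(train_k; β_{−k}) ]. The
one-standard-error band is computed on the per-fold deviance *differences
paired against the minimizing penalty*, not on the raw per-fold deviances:
fold deviances share a large fold-composition variance component, and a
naive SE (several times the height of the whole deviance curve at these
cohort sizes) makes the rule degenerate — it essentially always returns
the null model, after which no CpG can accumulate selection frequency.
Pairing within folds removes the shared component and keeps the rule's
parsimony-seeking intent. A replicate whose subsample has fewer events
than CV folds is redrawn.

Monotone partial likelihoods (perfect separation) have no finite MLE; the
fit is flagged (`converged=False`), retried with a small ridge penalizer
(0.1) and a warning is emitted, as the three-subject toy in the test suite
exercises.

## Evaluation

Confusion matrices are hypothesized class (rows) × true class (columns);
per-class accuracy is the correctly classified fraction of each true-class
column, overall accuracy the trace over the total, both reported in
percent rounded half-up to two decimals. The 95% CI on overall accuracy is
Clopper–Pearson exact (the source tables print CIs without naming a
method; this is a documented choice, not a reproduction claim).
Multiclass ROC pools every (sample, class) one-vs-all pair into a single
binary problem (micro-averaging); the AUC is the Mann–Whitney rank
statistic with ties counted one half.

Survival: Kaplan–Meier per group with the k-group log-rank test;
univariate plus joint multivariate Cox tables for the classifier group and
the clinical factors; and a Kaplan–Meier-based cumulative-case /
dynamic-control time-dependent AUC at a horizon t (default: median
follow-up):

    sens(c,t) = (1 − S(t|X>c)) P(X>c) / (1 − S(t))
    spec(c,t) = S(t|X≤c) P(X≤c) / S(t)

swept over all observed cutoffs and integrated by the trapezoid rule in
threshold order (re-sorting by FPR is avoided: float-tied FPRs would
scramble the staircase). The estimate is undefined (NaN) when S(t) is
exactly 0 or 1. With no censoring the construction reduces exactly to the
static AUC of cases (event by t) versus controls.

Risk stratification crosses the classifier group with stage: G1 =
low-risk/early (I/II), G2 = low/advanced, G3 = high/early, G4 =
high/advanced. Each level's HR vs G1 comes from a Cox model adjusted for
age, gender, BMI, smoking and alcohol — stage is excluded from the
adjustment because it is a component of the level coding; the trend p is
the Wald test of the ordinal 0–3 coding in the same adjusted model. Empty
levels are reported as missing contrasts without failing the others.

## Synthetic data

The generator emulates an eight-class 450K beta matrix. Baseline
(non-specific) CpG means follow a two-component logit-normal mixture
concentrated near 0.1 and 0.9, mimicking the bimodal 450K beta
distribution; samples add Gaussian noise on the logit scale (default SD
0.9) to the class mean and map back through the inverse logit, so values
stay in (0,1) and the planted mean shift is preserved up to a small Jensen
bias (≤ ~0.03 at the default noise). The class-mean structure is seeded
separately from the per-sample noise, so independently drawn cohorts (an
external validation set) carry the same signal.

Planted tissue-specific CpGs shift exactly one esophageal class by delta
(default 0.3) toward mid-methylation from a baseline drawn from the
concentrated hypo-/hypermethylated ends, which keeps the planted effects
homogeneous in strength. Defaults plant three markers per class (twelve in
total) whose members are individually informative but deliberately
*imperfect* (single-marker one-vs-rest separation ≈ 1.9 SD at the default
noise): a class separable by one perfect CpG would make stability
selection trivial (one marker always selected, the rest never), whereas
the interesting regime — and the one the protocol's frequency thresholds
presuppose — is a panel whose members all contribute. Because three
equally-strong markers per class are partially redundant, the stability
benchmark scenario plants a leaner non-redundant panel instead (two
markers per class among 500 CpGs): with redundancy, a sparsity-seeking
one-SE rule *correctly* drops an exchangeable marker in some partitions,
so full-panel recovery at frequency ≥ 9/10 is a property of non-redundant
designs, not of the estimator.
Contaminant-mimicking decoys shift identically in an esophageal class and
its adjacent-organ partner (NSE/ESCC ↔ HNSC, BE/EAC ↔ STAD) to exercise
the intersection rule's rejection of them.

Prognostic CpGs are hypomethylated in normal classes (mean 0.15) and
mid-methylated in tumor classes (mean 0.50) — so they pass the |Δβ| > 0.2
DMC screen — with a larger logit-scale dispersion (default 1.5, beta-scale
SD ≈ 0.3) that gives the risk score patient-to-patient spread. Survival
times are exponential proportional hazards with linear predictor
Σ_k coef_k · (beta_k − 0.5), default baseline hazard 0.1 per time unit and
planted log-HR 1.5 per unit beta; censoring is an independent exponential
(default rate 0.05), giving roughly 70–75% events at these settings.
Clinical covariates are drawn independently of survival: age ~ uniform
integers 40–80, gender/smoking/alcohol ~ Bernoulli(0.5), BMI ~ uniform
18–35, AJCC stage ~ uniform over I–IV (tumor samples only). Times are
unit-agnostic.

What the generator does *not* emulate: probe-type chemistry, batch and
cohort harmonization effects, correlated CpG blocks (probes are
independent given class), cell-type composition, informative censoring,
and clinical covariates that confound methylation. Passing tests therefore
demonstrate the correctness and internal calibration of the procedures,
not their operating characteristics on real 450K data.

## Problem sizes and defaults

Study-scale runs use 500 CpGs, 60 samples per class for the diagnostic
pipeline (50 per class for the marker-recovery benchmark) and 200 tumors
for the prognostic arm — large enough that the planted effects sit in the
power regime the thresholds assume, small enough that the full workflow
runs in minutes on one CPU. All protocol constants
default to the source values: FDR 0.05, DMC |Δβ| > 0.2, 10 partitions at
2:1 with 10-fold CV and frequency ≥ 9 (diagnostic); 100 × 75% subsampling
with 5-fold CV and frequency > 30 (prognostic). A single pipeline seed
fans out to per-stage child seeds, so stages are independently
reproducible and a fixed seed reproduces the entire report.

## Known limitations

- The grouped-lasso path is solved per fold and partition; with thousands
  of candidate features the FISTA solver is the bottleneck (the path uses
  warm starts, but the design targets hundreds of features, as produced by
  the marker-intersection stage).
- The time-dependent AUC estimator is the simple KM-subgroup construction;
  it is not guaranteed monotone under heavy censoring (no IPCW variant is
  provided).
- The accuracy CI method and several protocol details (stratification of
  partitions, penalized-vs-refit final coefficients) are unstated in the
  source protocol; the choices here are documented above and in the type
  docstrings.
- Missing betas are handled by complete-case dropping (or optional median
  imputation) before marker discovery; no model-based imputation.
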