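# Methods

## The problem

A left ventricular ejection fraction (LVEF) below 40% identifies patients
with reduced systolic function who benefit from early echocardiography and
treatment. Machine-learning classifiers can flag reduced LVEF from the scalar
parameters that ECG machines measure automatically (per-lead amplitudes,
durations and intervals plus global intervals and demographics), but a bare
probability is of limited clinical use. This package implements a pipeline
that makes such a classifier's reasoning legible: per-record Shapley
attributions are clustered into a small number of decision *patterns*, and
each pattern is translated into conventional ECG findings ("negative T-wave
inversion in I/V5–6", "low voltage in II/V4–5", ...) that a cardiologist can
verify against the tracing.

## Pipeline

1. **Classification.** Four families (random forest, RBF-SVM with Platt
   calibration, L2 logistic regression, one-hidden-layer MLP) are trained on
   the parameter table; the train/test split is grouped by patient so that
   repeated ECGs of one patient never straddle the split. A record is called
   reduced-LVEF when its predicted probability strictly exceeds 0.5.
2. **Attribution.** Each prediction is decomposed into per-parameter Shapley
   values under the interventional set function
   `v(S) = E_z[f(x_S, z_{-S})]`, the expectation taken over a seed-fixed
   background sample of training records (default 64 rows; larger backgrounds
   change little but cost linearly). In probability space the efficiency
   axiom is then exact: base value + row sum = predicted probability, so
   attributions compose directly with the 0.5 cut-off.
3. **Geometry.** Attribution vectors of the explanation cohort (predicted
   positive, non-paced) are reduced by PCA (20 components) then UMAP
   (n_neighbors 15, min_dist 0.1, fixed seed) and clustered with a
   variational Bayesian Gaussian mixture, K_max = 10.
4. **Criteria.** Within each cluster, a parameter is a decision factor when
   its median Shapley value exceeds the mean + 1 SD (population convention)
   of the per-parameter medians. Factors on waveform parameters become signed
   findings by comparing the cluster's median parameter value against the
   reference (whole test set) median, through a per-kind direction
   vocabulary; findings map onto six canonical categories, with VAT and
   S-wave prolongation additionally grouped as intraventricular conduction
   delay.
5. **Statistics.** Accuracy, sensitivity, specificity and AUROC (tie-corrected
   Mann–Whitney) carry percentile-bootstrap 95% CIs (default B = 10 000).
   Before/after reader studies are tested with a reader-clustered
   paired-proportions statistic (below).

## Shapley computation

The exact oracle enumerates all 2^p coalitions (guarded at p ≤ 12). For tree
ensembles of any p, attributions are computed exactly by the leaf-conjunction
decomposition: against one background row, a leaf is reached iff a
conjunction of "feature in S" / "feature out of S" literals holds, and the
Shapley value of a conjunction game has the closed form
`± w · a!·b!/((a+b)!·{a or b})` over its positive/negative literal sets. The
numba kernel sums this over leaves, background rows and trees; it agrees with
the enumeration oracle to ~1e-15 and satisfies efficiency to float precision.
Non-tree models fall back to exact enumeration (p ≤ 12) or antithetic
permutation sampling, which keeps efficiency exact per permutation and is
unbiased per feature.

Interventional (background-marginalised) semantics were chosen over
conditional ones because they make the efficiency check against predicted
probabilities exact and keep the oracle implementable by enumeration.

## Clustering: scale-aware priors with a separation gate

Off-the-shelf variational mixtures with an uninformative Wishart prior use
the *total* empirical covariance as the covariance prior. On a UMAP embedding
— total spread of tens of units, within-cluster spread well under one unit —
this inflates every component's covariance by `dof·Σ_prior/(N_k+dof)`, an
order of magnitude above the within-cluster scale, and demonstrably absorbs
clusters separated by five within-cluster SDs into one component. The
primary fit therefore uses `Σ_prior = cov(X)/K_max` (the within-cluster scale
expected if up to K_max clusters tile the embedding) with degrees of freedom
d + 3. Because a tight scale prior can conversely tile a diffuse unimodal
cloud, the primary solution is accepted only when its clusters are separated
(mean silhouette ≥ 0.5 — on our benchmarks genuine structure scores
0.83–0.92 and spurious tilings 0.25–0.36); otherwise the fit falls back to
the uninformative prior, and if that too is unseparated the cohort is
reported as one cluster. Clusters with fewer than 10 members are kept but
flagged "unexplained": too few records to support a criteria read-out.

## The synthetic benchmark

Paired hospital ECG/echo datasets of this kind are not publicly deposited,
so the generator plants a known ground truth with the structure such data
have: 5 000 patients contributing 1 + Poisson(1) ECGs each (~2 per patient),
a 19.4% patient-grouped test split, 9.2% label prevalence, a 5% paced
subpopulation (pacing widens QRS by ~56 ms and excludes the record from
explanation), and five reduced-LVEF phenotypes realising the canonical
finding combinations (lateral T inversion, low voltage, precordial Q waves,
VAT prolongation, S-wave prolongation in V2–3, QTc prolongation) on distinct
lead sets. Baseline means and SDs are conventional adult resting-ECG values
(HR 74 ± 15, PR 172 ± 44, QRS 106 ± 23, QTc 435 ± 34 ms, R waves
0.8 ± 0.35 mV, ...); noise is equicorrelated within each lead (ρ = 0.3) and
independent across leads. LVEF is drawn per record from the class's Gaussian
(healthy 62 ± 8, phenotypes 33 ± 8) and thresholded at 40%, so labels are
noisy relative to phenotype and AUROC stays below 1. Phenotype mixing
weights are rescaled in closed form so the expected prevalence hits the
configured target.

Effect sizes are the generator's central design choice. Findings *shared*
between phenotypes are planted at 2.5 baseline SDs (an overt abnormality —
e.g. a clearly inverted lateral T wave); each phenotype's *hallmark*
findings at 3.5 SDs. Early designs with uniform ~2 SD shifts produced
attribution clouds whose within-phenotype spread (driven by each record's
distance to the decision cut-off) swamped the between-phenotype directions,
making recovery impossible for any clustering method; the hallmark/shared
split restores the contrast that distinguishes the patterns, which is also
the clinically coherent reading — a pattern is defined by what sets it
apart. Amplitude parameters are treated as signed net deflections, so a
strongly planted low-voltage phenotype can push small R waves below zero.

Because all classes share one covariance, the exact posterior
P(reduced | parameters) is available in closed form, giving a Monte-Carlo
Bayes-optimal AUROC against which the forest is benchmarked (observed gap
≤ 0.007 across seeds).

What passing the benchmark does and does not show: the generator's
within-lead equicorrelation is far simpler than real inter-parameter
covariance; phenotypes are discrete rather than graded; measurement error,
drift and missingness are absent. Recovery here validates the machinery
(attribution, geometry, criteria extraction) against a known truth — it does
not certify performance on hospital data.

## Reader-study statistics

The reader study simulator draws, per reader × ECG, correct/incorrect calls
with configurable sensitivities/specificities per phase; a Gaussian-copula
latent shared between phases (correlation ρ, default 0.3) induces realistic
before/after pairing.

For the before/after comparison across K readers who each read the same
ECGs, per-reader discordance counts `b_k` (correct before, wrong after) and
`c_k` (the reverse) are formed and the statistic
`T = (Σ d_k)² / Σ d_k²`, `d_k = b_k − c_k`, is referred to χ²(1). The
variance of Σ d_k is estimated across clusters from the uncentred second
moment: with few clusters (K = 7 here) the centred estimator referred to
χ²(1) is markedly anticonservative (the statistic is then a squared t with
K−1 degrees of freedom; analytic type-I ≈ 0.10 at K = 7), whereas the
uncentred form stays near nominal (empirical type-I 0.035–0.042 over 2 000
null simulations). With one paired observation per cluster the statistic
reduces exactly to the classical McNemar χ². A within-reader sign-flip
permutation test (exact enumeration of all 2^K flips for K ≤ 16) ships
alongside as an assumption-free oracle; note its p-values are granular
(minimum 2/2^K), so decision agreement with the χ² test is expected but not
logically forced at the boundary.

The bootstrap is the percentile interval over joint row resamples;
degenerate resamples (e.g. single-class draws under which sensitivity is
undefined) are redrawn and counted. Empirical 95% coverage is 0.958–0.968 in
the calibration experiment (500 simulations, B = 200, n = 200).

## Numerical and degenerate-input choices

- Classification at the cut-off is strict (`prob > 0.5`): probability exactly
  0.5 is a negative call.
- Argmax responsibility ties break toward the lower component index; cluster
  ids are relabelled by decreasing size.
- A cohort of identical attribution rows embeds to a single point (UMAP's
  repulsion would otherwise spread it artificially) and clusters as one
  component with full responsibility.
- Medians use the standard midpoint convention; all summary SDs that mirror
  published tables use the population convention (divisor n), which is the
  convention the published Mean (SD) rows follow.
- Direction calls in criteria interpretation require a minimum effect of 0.2
  reference SDs, suppressing noise findings the qualitative published
  procedure would never have reported.
- Lead merging joins a shared finding only within its canonical lead family
  (lateral T, broad low voltage, precordial Q, lateral VAT, right-precordial
  S); the same finding outside the family stands alone and is reported
  outside the six categories.

## Problem sizes

The validation suite and the acceptance script run the recovery benchmark at
5 000 patients (~10 000 records, explanation cohort ≈ 160–210), the type-I
experiment at 2 000 simulated studies, the coverage experiment at 500
simulations with B = 200, and the byte-determinism check at 1 200 patients
with a 60-tree forest. These sizes give stable estimates (the benchmark was
additionally validated across seven generator seeds: effective K = 5 every
time, ARI ≥ 0.956, minimum factor recall ≥ 0.88).

## Known limitations

- The 178-parameter schema is a documented reconstruction of what ECG
  carts of this class emit (12 leads × 14 measurements + 10 globals); any
  other schema can be supplied as JSON, and only the default is privileged.
- SVM probabilities come from Platt calibration; logistic regression and MLP
  attributions use sampling rather than an exact polynomial path.
- UMAP's `transform` for new points is approximate; projections of training
  rows land near, not on, their fitted coordinates.
- The clustered paired-proportions literature contains several variance
  estimators; the one implemented is chosen for small-K calibration and is
  cross-checked against the permutation oracle rather than against a
  reference implementation.
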