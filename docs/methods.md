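# Methods

This note documents the statistical machinery in `battery_ontology`, the
assumptions behind it, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## The problem

A behavioral battery measures each participant on many dependent variables
(DVs) — condition contrasts, model parameters and scale means from cognitive
tasks, plus scores from self-report surveys — together with self-reported
real-world outcomes. The package derives a *psychological ontology* from such
a matrix: a low-dimensional embedding of the DVs (an oblique factor space),
clusters of DVs within that embedding, a partial-correlation network
quantifying how the two measurement categories relate, and an out-of-sample
assessment of how well the discovered traits predict outcomes.

## Factor model and estimation

The common factor model is `X − μ = F L' + ε` with m DVs, f latent factors,
loading matrix L (m × f), oblique factor correlations Φ and uniquenesses Ψ.
Estimation runs on the Pearson correlation matrix of the standardized DVs
(DVs have arbitrary, mixed units, so the correlation metric is the right
scale); near-singular matrices receive a 1e-8 ridge, logged.

* **Maximum likelihood.** The Wishart likelihood is concentrated over L, so
  the optimization runs over the m uniquenesses only (L-BFGS-B on
  Ψ ∈ [0.001, 1] with the analytic gradient). Uniquenesses pinned at the
  lower bound are flagged as Heywood cases. A degenerate perfect-fit check
  (Ψ = 1, zero common variance) handles otherwise non-identified inputs such
  as an identity correlation matrix.
* **Rotation.** Direct oblimin with γ = 0 (quartimin) via gradient
  projection, from the identity start plus 9 random starts (seeded), keeping
  the lowest criterion. Rotation changes neither the likelihood nor the
  communalities; both invariances are asserted in tests. Factors are ordered
  by explained sum of squares and sign-anchored to positive loading sums.
* **Scores.** ten Berge correlation-preserving weights
  `W = R^{-1/2} C Φ^{1/2}` with
  `C = R^{-1/2} L Φ^{1/2} (Φ^{1/2} L' R^{-1} L Φ^{1/2})^{-1/2}`; the
  defining property — corr(scores) = Φ̂ at the training correlation matrix —
  is exact and used as a test oracle. When a frozen weight matrix is applied
  to a new cohort (e.g. the retest sample), the new sample is standardized
  with its own means and SDs; a switch retains the training statistics
  instead.
* **Dimensionality.** BIC = χ² − df·ln(n) with the Bartlett-corrected
  likelihood-ratio χ² and df = ((m−f)² − (m+f))/2; the selected f is the
  argmin over converged candidate fits. Since BIC is rotation-invariant the
  sweep skips rotation entirely. Default candidate range 1..⌊m/3⌋, capped at
  25.
* **Robustness.** Bootstrap loadings refit the model on 90% participant
  subsamples drawn *without* replacement (1000 by default). Refitted factors
  are aligned to the base solution by the permutation and sign flips that
  maximize total absolute Tucker congruence (assignment problem solved
  exactly); element-wise means/SDs are reported. Drop-a-measure robustness
  removes every DV of one measure at a time and reports per-factor
  congruence with the base solution on the shared DVs.

## Reliability and attenuation

Per-DV test-retest reliability uses Pearson r across the two sessions and
ICC(3,k) — two-way mixed, consistency, average of k = 2 sessions,
(MS_rows − MS_err)/MS_rows. Degenerate (constant) columns are flagged, never
silently dropped. Attenuation-corrected variance explained divides a DV's
communality by its squared retest r; the correction is undefined for r ≤ 0
(an error) and DVs with r ≤ 0.2 are excluded from the
communality-reliability analysis. Because h²/r² is unbounded, per-DV values
above 1 are reported raw but clipped to 1 in aggregates, so the mean
adjusted variance explained stays interpretable as a proportion.

## Clustering in loading space

DVs are clustered on their loading rows with the absolute-correlation
distance d = 1 − |r| (measure direction is arbitrary: an impulsivity DV could
as well be scored as self-control). The tree is average-linkage (UPGMA), the
standard companion to dynamic branch cutting.

The **dynamic hybrid cut** is implemented as a recursive branch
decomposition using the hybrid algorithm's core criteria. A node is split
into its two subtrees only when *both* qualify as distinct branches: at
least `min_cluster_size` members (default 3 — small published clusters
require a small minimum), a compact core (mean pairwise dissimilarity among
the earliest-joined core members, core size `min_cluster_size/2 + 1 +
sqrt(extra)`, below a scatter threshold), and a clear gap between the merge
height and that core scatter. Scatter/gap thresholds are set by
`deep_split` ∈ 0..4 (default 2 → scatter fraction 0.82, gap fraction 0.135)
relative to the span between the 5th percentile of merge heights and the cut
height. Because the metric is bounded by 1, the default cut height is an
absolute 0.99: a tight homogeneous block therefore stays a single cluster
instead of being shredded by data-relative thresholds. Leaf clusters smaller
than the minimum dissolve to "unassigned" (label 0); a second,
dissimilarity-based stage then attaches each unassigned object to the
cluster with the smallest average dissimilarity, provided it is below the
cut height. Fixed-height cutting (optionally silhouette-optimized over merge
heights) is provided for comparison; agreement between the two is
summarized with adjusted mutual information (arithmetic-mean normalization,
hypergeometric expected MI; verified against a brute-force enumeration
oracle in the tests). Silhouette uses the standard (b−a)/max(a,b) with
singletons scored 0 and unassigned DVs excluded (with a warning).

**Consensus robustness.** Each of `n_sim` (default 5000) simulations draws
every loading element from Normal(bootstrap mean, bootstrap sd), drops 20%
of DVs at random, and reruns the full distance → tree → dynamic-cut
pipeline. Pairwise co-occurrence is computed conditional on joint retention
(unconditional proportions would be biased by dropout), and 1 − co-occurrence
is clustered by the identical pipeline to give the consensus solution and
its AMI against the original.

## Partial-correlation network

The graphical lasso (block coordinate descent on the correlation matrix)
traces a path of 100 log-spaced penalties spanning [0.01·λ_max, λ_max],
λ_max being the largest absolute off-diagonal correlation. The lasso path is
used to *propose* edge sets; each distinct support along the path is refit
by the unpenalized constrained MLE (modified-regression/IPF algorithm), and
the extended BIC (γ = 0.5), −2ℓ + E·ln n + 4γE·ln m, is evaluated on the
refit likelihood. This makes the selection a true BIC comparison across
graphs: with the penalized likelihood, EBIC is monotone in λ whenever strong
edges are present (penalty-induced shrinkage of strong edges dominates the
criterion) and weak spurious edges survive; with refit-EBIC a
conditional-independence chain is recovered exactly and an independent null
yields an empty graph. The reported precision matrix is the refit MLE on the
selected support, so partial correlations ρ_ij = −ω_ij/√(ω_ii ω_jj) are
unshrunk. Edge lists are exported at |ρ| ≥ 0.05 by default (0.01 available
as a flag; both conventions exist in the literature for such figures).

Cross-category prediction assesses the same separability predictively:
every DV is predicted from all other task DVs and, separately, from all
other survey DVs (never from itself) by 10-fold cross-validated ridge
regression, yielding four within/across R² distributions.

## Outcome prediction

Outcome variables are residualized on age and sex (OLS per column), factor
analyzed by the identical EFA pipeline, and the resulting target factor
scores predicted from task and/or survey factor scores.

* **Folds.** Balanced k-fold (default 10): participants are ordered by
  target value (stable ties), consecutive rank blocks of size k each deal
  one member per fold. Fold sizes differ by ≤1 (522 participants → 469/53
  train/test splits) and fold-wise target means are tightly balanced.
* **Ridge.** The primary model; the penalty is selected inside each
  training fold by efficient leave-one-out error over 25 log-spaced values
  in 10⁻³..10³, computed from one SVD per fold. Feature standardization
  also happens strictly within training folds (leakage sentinels — target
  copied into features, shuffled features — are part of the test suite).
  Lasso, random forest and SVR are available as alternates; random-forest
  style overfitting is precisely what the in-sample-vs-CV comparison is
  meant to expose.
* **Metrics.** cv R² is the squared Pearson correlation between
  concatenated out-of-fold predictions and the actual target; the signed r
  and the 1 − SSE/SST variant are stored alongside because squared
  correlation hides anti-prediction. MAE and in-sample counterparts are
  reported from a full-data fit.
* **Null.** The empirical null shuffles the target, rebuilds balanced folds
  on the shuffled values, and reruns the entire CV pipeline including
  penalty selection (the conservative choice), 2500 times by default;
  p = (1 + #{null ≥ observed})/(1 + n_perm). Calibration (type-I error
  0.05) is verified by simulation in the acceptance tests.
* **Fingerprints.** Standardized β from the full-data ridge fit (features
  and target z-scored) form each outcome's coefficient profile; the
  feature-wise view is the exact transpose.

## Synthetic-data generator

The generator plants the full causal structure the pipeline is supposed to
recover: `x_i = L_i f + s_i ξ_i + e_i` with traits f ~ N(0, Φ_joint), a
stable specific factor ξ_i retained across sessions, and session noise e_i
redrawn at retest, scaled to unit DV variance so the retest correlation
equals the configured reliability h²_i + s_i². Reliability ≥ communality by
construction — the common signal cannot exceed the stable variance — so the
attenuation-corrected variance explained is ≤ 1 when the model is true;
loading rows are shrunk (direction preserved) whenever a drawn communality
would exceed 95% of the drawn reliability.

Defaults mirror the study design the package targets: 522 participants, 150
retest; 129 task DVs on 5 factors with heterogeneous reliability
N(0.45, 0.21) clipped to (0.05, 0.95); 64 survey DVs on 12 factors with
reliability N(0.80, 0.06); primary loadings U(0.5, 0.8) in consecutive
blocks, within-category cross-loadings U(−0.15, 0.15), within-category
factor correlations 0.3, cross-category factor correlations 0.1 (the weak
task-survey coupling). Outcomes: 8 latent targets, each driven by 1-3
random survey factors, with population R² profile
(0.29, 0.15, 0.12, 0.10, 0.08, 0.06, 0.05, 0.03) — spanning the
moderate-to-weak range typical of survey-based outcome prediction — plus
small age/sex effects (β = 0.2) that the residualization step must remove;
three observed outcome DVs per latent target. All randomness flows from a
single seed via independent substreams; outputs are bit-reproducible.

What the generator does **not** emulate: non-Gaussian and ordinal DVs,
missingness and imputation artifacts, trial-level noise structure,
measure-level method variance beyond the block structure, and participant
attrition. Passing recovery tests therefore demonstrates correctness of the
pipeline under a linear-Gaussian world consistent with its own assumptions,
not robustness to the full messiness of real batteries.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the full study-scale battery
(n = 522, 193 DVs) for generation, reliability, dimensionality selection,
factor recovery and clustering; dimensionality-recovery rates use 20 seeds.
Monte-Carlo-heavy components use reduced but statistically adequate sizes,
chosen as the package's own defaults for desk-scale verification:
permutation-calibration uses 200 null targets × 200 permutations in the
tests (100 × 100 in the acceptance script), consensus clustering a few
hundred simulations, and the script's per-DV cross-category prediction a
regular one-in-four DV subsample. Increasing these sizes changes only
Monte-Carlo error, not any contract being checked.

## Known limitations

* The dynamic hybrid cut is a faithful-in-spirit reimplementation (core
  scatter + gap branch criteria, stage-2 assignment) rather than a port of
  the reference implementation; printed cluster counts on real data may
  differ by a small margin under default parameters.
* ML EFA assumes the correlation matrix is well-conditioned relative to f;
  Heywood cases are flagged, not repaired.
* EBIC model selection uses refit likelihoods (see above); users comparing
  against penalized-likelihood EBIC implementations should expect sparser
  graphs from this package.
* Permutation tests shuffle the target before fold construction; the null
  therefore includes fold-assignment variability.
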