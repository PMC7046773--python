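# Methods

## The model

`pnet` ranks and classifies patients for a binary phenotype (e.g. poor vs
good prognosis) transductively: the whole cohort — labeled and unlabeled
patients alike — forms a similarity graph, and each patient's score is read
off the labels of its graph neighborhood. No model is exported to unseen
cohorts; a fitted object is bound to the cohort it was fitted on.

The pipeline has five stages:

1. **Feature filtering.** A two-sample t-test (Welch by default; pooled
   variance behind `equal_var=True`) on the labeled training patients ranks
   features by class association; the top m′ are kept. Ties in p-value break
   by larger |t|, then lexicographic feature ID, so rankings are
   deterministic across platforms. Zero-variance features get p = 1 (equal
   means) or p = 0 (perfectly separated means) rather than NaN.
2. **Patient similarity.** From the m′ × n selected matrix, the patient
   graph adjacency is W with w_ij = max(0, corr(x_i, x_j)) (filtered Pearson
   by default; filtered Spearman and inverse Euclidean/Manhattan distance
   1/(1+d) as alternatives). The diagonal is forced to zero: W is a graph
   adjacency, and self-similarity must not inflate node degrees.
3. **Random-walk kernel.** K₁ = (a−1)I + D^(−1/2) W D^(−1/2) with
   d_ii = Σ_j w_ij, and the p-step kernel K = K₁^p. With a ≥ 2, K₁ equals
   (a−2)I plus (2I − L) with L the normalized Laplacian, whose spectrum lies
   in [0, 2], so K₁ — and hence every power — is positive semidefinite.
   a < 2 is rejected. The default a = 2 is the boundary choice: a only
   shifts the spectrum, and the smallest admissible value adds the least
   self-affinity. Isolated nodes take D^(−1/2) entry 0, giving them kernel
   row ((a−1)^p at the diagonal, zeros elsewhere) instead of infinities.
4. **Edge filtering.** Off-diagonal kernel entries strictly below a
   threshold τ are zeroed (the diagonal is untouched). τ is chosen by grid
   search: candidates are the empirical quantiles of the strictly positive
   off-diagonal entries at `tau_grid_size` (default 50) equally spaced
   probabilities, plus 0 — quantiles adapt the grid to the kernel's scale.
   Each candidate is evaluated by the leave-one-out criterion below on the
   training subgraph; ties go to the smallest τ (retain more edges).
5. **Scoring and classification.** Six score functions turn the kernel row
   K_i and the positive set V_C into a score: AV (mean weight into V_C), NN
   (largest weight), kNN (mean of the k largest), TOT (positive weight
   fraction), Diff (positive minus negative weight), Dnorm (Diff normalized
   by the total). For TOT/Diff/Dnorm the negative set is the labeled
   negatives by default; `negatives="all-non-positive"` switches to the
   literal set-complement, in which unlabeled patients also count as
   negative evidence. 0/0 ratios (isolated nodes) score 0. The binary rule
   is score > decision_threshold ⇒ positive, with the threshold chosen to
   maximize leave-one-out training accuracy over all cut-point candidates
   (midpoints of consecutive distinct scores plus one point below the
   minimum and one above the maximum; ties to the smallest candidate).

Two distinct thresholds exist and are never conflated: `tau` prunes kernel
edges; `decision_threshold` cuts the score axis.

## The efficient leave-one-out

Scoring patient i without its own label evidence is equivalent to zeroing
k_ii: every score of i depends on i's label only through the k_ii term. One
pass over the diagonal-zeroed kernel therefore reproduces all n hold-out
runs. Two refinements make the pass *arithmetically identical* to the naive
hold-out rather than merely equivalent up to normalization:

- For the count-normalized scores (AV, kNN) the per-row positive count and
  candidate set also shrink by one when the row itself is positive —
  otherwise AV would divide by |V_C| where the true hold-out divides by
  |V_C|−1.
- A held-out patient contributes no label evidence to its own score in
  either direction: under `all-non-positive` negatives, the held-out node is
  not added to its own negative evidence set.

Evidence sums run over patients in index order through 1-D contiguous
reductions (column gathers are made C-contiguous first — numpy sums strided
axes in a different order), so the single pass is bit-reproducible against a
per-definition evaluation. The test suite asserts exact (`==`) agreement
with a naive hold-out oracle on random kernels for all six scores and both
negative-evidence modes.

A structural consequence of hold-out worth knowing: under a label-free
(null) kernel, LOO biases the differential scores *against* each node's own
class, because the held-out node's class loses one evidence term in the
direct positive-vs-negative comparison (measured fixed-τ null AUROC ≈ 0.2
for TOT/Diff/Dnorm on dense balanced random kernels, ≈ 0.5 for AV/NN). This
does not affect the permutation test (observed and shuffled rankings share
the bias) nor held-out evaluation, but the *maximized* τ-selection criterion
is upward-biased under the null (winner's curse over the grid), so the
training criterion value should never be read as an unbiased performance
estimate — the cross-validation harnesses exist for that.

## Evaluation harnesses

- `repeated_kfold`: stratified k-fold over labeled patients, repeated
  (defaults 10 × 15). Held-out patients stay in the graph as unlabeled
  nodes; feature selection, τ and the decision threshold are refitted per
  split from training labels only; AUROC/AUPRC/accuracy/F1 are computed on
  the held-out labeled patients.
- `mccv`: Monte-Carlo cross-validation — many random stratified splits
  (default 1000) at each fixed training-set size, reporting mean accuracy
  and the standard error of the mean (SD/√n_splits).
- `permutation_test`: the observed statistic is the LOO ranking AUROC of
  the labeled patients (τ re-selected) under the true labels; each of B
  permutations (default 10000) shuffles the labels over labeled patients
  and recomputes it. p = #(shuffled AUC > observed)/B, with an optional
  (g+1)/(B+1) small-sample correction. By default each permutation re-runs
  only the label-dependent stages (τ selection and scoring) on the kernel
  built once from the true-label feature selection; re-selecting features
  thousands of times is disproportionate. **Caveat:** with m ≫ n and
  label-dependent feature selection, this default is anti-conservative —
  the observed kernel was built from features chosen to separate the true
  labels, the permuted rankings were not (measured p ≈ 0 on pure-noise data
  with m′ = m/2). Use `full_refit=True` when feature selection is part of
  the claim being tested, or make selection label-free. The calibration
  simulations run with selection a no-op (m′ = m), where the default scheme
  is exact: null rejection at α = 0.05 stays within binomial noise.

All splitting is stratified so every training set holds both classes, and
every harness derives per-split seeds from one master seed, making results
bit-reproducible.

## The synthetic cohort generator

`SyntheticSpec` emulates the shape of prognosis microarray cohorts: m ≫ n,
two outcome classes plus an unlabeled fraction that joins the graph without
labels, and a small planted set of class-associated features. Values are
Gaussian (log-intensity desk model; a Student-t(3) variant rescaled to unit
variance behind `heavy_tails=True`); differential features are shifted by
`effect_size · noise_sd` in the positive class, optionally with
equicorrelated residuals via a shared per-patient factor. Unlabeled masking
is class-balanced so the labeled subsample keeps the positive fraction. The
defaults — 120 patients, 1000 features, 20 differential at 2 SD, 20%
unlabeled, balanced classes — are the standard conditions of the simulation
studies; the null variants set `effect_size=0`, and the permutation-test
calibration uses the smallest cohort shape (n = 30, m = 100, no unlabeled
patients) so that 200 cohorts × 100 permutation rounds stay tractable.

What the generator does *not* emulate: probe/batch effects, heteroscedastic
per-gene variances, correlated background networks, survival-time
dichotomization noise. Passing tests on these cohorts show the machinery is
correct and recovers planted structure; they do not certify performance on
real cohorts. One modeling detail matters for interpretation: a *uniform*
mean shift on exactly the selected features is invisible to correlation
similarity (Pearson is location-invariant per profile) — class signal
appears through the shift *pattern* across a mixed selected set, which is
why m′ deliberately exceeds the number of planted features in the recovery
studies.

## Numerical and design choices

- Dense matrices throughout; target cohorts have at most a few hundred
  patients, where dense linear algebra beats sparsity in both speed and
  simplicity.
- Filtering uses strict inequality (< τ removes), so τ = 0 is the identity.
- The internal AUROC is the midrank Mann-Whitney statistic (identical to
  trapezoidal ROC integration with tied scores); the public metrics go
  through scikit-learn.
- m′ has no library-level default — it is cohort-dependent — but the CLI
  defaults to 100.
- Degenerate cases are total, not fatal: empty similarity graphs warn and
  yield diagonal kernels; a τ search whose LOO scores are constant
  everywhere warns and returns τ = 0; all-equal LOO scores give a decision
  threshold on the majority-class side.
- Determinism: identical inputs, config and seed give bit-identical fitted
  models, scores and CV results; all randomness flows from
  `numpy.random.SeedSequence` children of one seed.

## Limitations

- Transductive by construction: adding a patient changes the graph, the
  kernel, and potentially every score; there is no out-of-cohort predict.
- The t-test filter is univariate; feature sets with purely multivariate
  class structure will not be found.
- τ selection explores a quantile grid, not all n² distinct thresholds; a
  criterion optimum strictly between grid points can be missed (by at most
  one quantile step).
- The default permutation scheme's anti-conservatism under label-dependent
  feature selection, and the LOO class bias of the differential scores at
  the null, are discussed above.
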