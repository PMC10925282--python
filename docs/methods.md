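# Methods

This note records the modeling choices, defaults and numerical conventions
behind `ppidiff`, in the spirit of a model-description document: what is
computed, why the open design points were settled the way they were, and
what the synthetic benchmarks do and do not establish.

## Protein descriptors

Sequences are validated against the 20-letter standard alphabet; the
ambiguity and non-standard codes B, J, O, U, X, Z (and internal `*`) mark
a protein as non-natural and exclude it (or raise, in strict mode).
Terminal `*` stop characters are stripped and lowercase input is
uppercased, matching common proteome FASTA dialects.

* **AAC / DPC.** Plain counting. DPC divides each of the 400 dipeptide
  counts by the N − 1 overlapping positions, so the vector is a
  probability distribution for every N ≥ 2.
* **Moran autocorrelation.** The lag-d statistic normalizes the mean
  lagged co-deviation by the sequence variance of the property. It is
  invariant under affine rescaling of the property scale (asserted in the
  tests), so the choice of units in the bundled scale tables is
  immaterial; scales are nevertheless standardized to zero mean / unit SD
  over the 20 letters before use, the convention of standard descriptor
  toolkits. A constant property along the sequence gives 0/0; the package
  returns 0, the "no autocorrelation" neutral element, keeping feature
  matrices finite. Proteins shorter than the largest requested lag are
  excluded with a logged reason rather than zero-padded — padding would
  fabricate autocorrelation signal.
* **PAAC / APAAC.** The closed forms follow the standard published
  definitions: sequence-order correlation tiers built from standardized
  hydrophobicity, hydrophilicity and side-chain-mass tables, blended with
  the residue frequencies through the weight w. Defaults λ = 10,
  w = 0.05, the defaults of the descriptor toolkits this schema is
  compatible with. PAAC components are non-negative and sum to 1; APAAC's
  correlation tracks are product terms that may legitimately be negative,
  while the vector still sums to 1.
* **CTD.** Standard three-class property alphabets (hydrophobicity,
  normalized van der Waals volume, polarity, polarizability, charge,
  secondary structure, solvent accessibility: buried ALFCGIVW / exposed
  RKQEND / intermediate MSPTHY). Distribution percentiles use the
  position of the ⌈p·k⌉-th occurrence of a class (k occurrences in the
  sequence), as a percentage of N; an absent class reports 0.

All descriptor math is double precision with no tolerances applied at
computation time. Feature names are stable under a fixed configuration
(`AAC_<X>`, `DPC_<XY>`, `MoranAuto_<Scale><d>`, `PAAC<k>`, `APAAC<k>`,
`CTD_<Prop>_<C|T|D>_...`), and a schema digest ties downstream artifacts
to the configuration that produced them.

## Pair space

Min–max normalization is fit on a stated reference set; application clips
to [0, 1] so parameters fit on a training subset cannot push test values
outside the unit interval. Degenerate features (max = min) map to 0 and
are dropped before modeling — constant columns carry no information and
break standardization. The default pair representation is the *absolute*
difference: interaction is a symmetric relation and the ordering of ids in
a pair file is arbitrary, so the design matrix should be invariant under
swapping the two proteins. The signed difference is available
(`mode="signed"`) for fidelity experiments.

Normalization in the command-line `pairs` stage is global over the input
protein set, which mirrors how such rescaling is usually described;
fitting it per training fold instead (and clipping test values) avoids a
small information leak and is how the evaluation module standardizes
features internally.

## Feature selection

The selector standardizes features, draws `n_folds` stratified shuffled
80/20 splits, grid-searches the regularization strength by mean validation
accuracy, refits every fold at the chosen strength, and keeps the
intersection of the per-fold non-zero-coefficient sets ("bagging"), scored
by the mean signed coefficient across folds. Decisions taken where the
procedure was genuinely open:

* **LASSO parameterization.** The L1-penalized squared-error regression on
  the 0/1 labels (not logistic regression; an L1-logistic variant is
  available as `method="logistic_lasso"`). The penalty λ is quoted on the
  per-sample objective `(1/2l)·RSS + λ‖w‖₁` — the convention of the major
  sparse-regression software — so grid values are comparable across fold
  sizes. Default grid: 13 log-spaced points over 10⁻⁴…10¹.
* **SVM sparsity.** Coefficient-based selection needs exact zeros, which
  the classic L2 soft-margin objective never produces (its weight vector
  is generically dense — a magnitude threshold either keeps everything or
  can never return an empty set under a label-permuted null). The SVM
  selector therefore solves the L1-penalized soft-margin problem
  (liblinear primal, ‖w‖₁ + C Σ ξᵢ²), whose solution is sparse and shrinks
  to w = 0 as C → 0, making "features with non-zero coefficients" literal.
  The L2 hinge objective remains available (`fit_svm_fold(penalty="l2")`).
  Default grid: 11 log-spaced points over 10⁻³…10².
* **Grid search.** One search over the fold ensemble, then the chosen
  value is reused for every fold's fit (per-fold search is a flag). The
  grid is scored on the first 5 folds of the ensemble — scoring on all
  folds tripled the cost without changing the chosen value in pilot runs —
  while the selection fits always use every fold. Two guards make the
  choice robust to validation noise. First, a *no-information gate*: if
  the best mean validation accuracy does not significantly beat the
  no-information rate (the majority-class share; Bonferroni-corrected 5%
  normal test with the binomial SE over the pooled validation count),
  every candidate is treated as chance-level and the most regularized
  value wins — without this, winner's curse over the grid hands
  signal-free data to a near-unregularized dense model whose consensus is
  large. Second, the one-standard-error rule (glmnet's convention): among
  the surviving candidates the most regularized value (largest λ,
  smallest C) whose mean accuracy is within one SE of the best is
  chosen. ``one_se_rule=False`` restores the plain argmax with
  exact-tie-toward-regularization breaking.
* **Importance score.** Mean signed coefficient across folds on
  standardized features — the simplest signed importance consistent with
  reading negative scores as "differences that disfavor interaction".
* **Determinism.** All shuffling flows from the required seed; identical
  (data, config, seed) gives an identical result. Solver iteration caps
  (Lasso 5·10⁴ coordinate-descent iterations at tol 10⁻⁸; liblinear 500
  iterations at tol 10⁻⁴) keep grid searches affordable; hitting a cap is
  logged, never silent, and only affects heavily-regularized-out or
  grid-losing fits in practice.

## Evaluation

The baseline classifier is a linear SVM (C from the selection stage when
the SVM selector ran, otherwise 0.1; RBF available by flag) trained on the
consensus-restricted design matrix, standardized with training-fold
statistics. Metrics are computed per fold on the 20% test side from the
confusion matrix — Accuracy, Recall (sensitivity on the interacting
class; the benchmark sets are balanced, so no macro-averaging), F1, and
MCC — and the headline numbers are unweighted means across folds. MCC
with a zero marginal factor (e.g. a constant classifier) is 0 by
convention. Evaluation folds are fresh stratified splits under their own
seed, independent of the selection folds.

## Synthetic data generator

The generator emulates the *structure* of balanced PPI benchmark sets: a
proteome (default 300 proteins, 100–300 residues, uniform letter
background) and an exactly balanced labeled pair set (default 500 + 500,
the size of typical benchmark organisms' sets). The interaction signal is
planted in dipeptide-composition space — the feature family this method
exists to interrogate — default VV, KK, IK, EE.

* **Signal subpopulation.** A random half of the proteins are drawn from a
  first-order Markov chain whose planted-dipeptide transitions are fixed
  at 1.5× the rejection threshold and whose remaining transition mass is
  biproportionally rescaled so the stationary letter distribution equals
  the background — without this, enriching e.g. VV would raise the
  frequency of *every* V-containing dipeptide and leak planted signal
  into non-planted features. Sequences are rejection-sampled (bounded
  attempts) until every planted dipeptide's DPC reaches
  `enrichment_factor` (default 3) times its background expectation.
* **Labels.** For candidate pairs, P(interact) = sigmoid(α − β·z) where z
  is the planted |ΔDPC| sum standardized over the candidate pool and α is
  bisection-calibrated so the marginal positive rate is 0.5; classes are
  then down-sampled to exact balance. Standardizing the signal makes β a
  dimensionless per-SD log-odds: β = 0 is an exact null, the default
  β = 2.5 gives an analytic Bayes accuracy near 0.83, and β ≈ 50 makes
  labels effectively deterministic. Similar proteins interact, so the
  planted coefficient on the difference features is negative.
* **Bayes ceiling.** `bayes_accuracy` averages max(p, 1 − p) over the
  retained pairs — the expected accuracy of the oracle thresholding the
  true linear predictor at 0, an upper bound for any classifier on these
  features and the calibration target for evaluation tests.

What passing the synthetic suites shows: the selection machinery recovers
a known sparse signal through the full descriptor → normalization → pair →
selection stack, rejects label-permuted nulls, and the evaluation metrics
track an analytically known ceiling. What it does not show: performance on
real proteomes — real sequences have length distributions, domain
architecture, compositional biases and PPI network topology (hubs, degree
correlations) that the generator deliberately does not model.

## Problem sizes

The default test-suite conditions are the generator defaults above: 300
proteins, 1000 pairs, a 400-feature DPC design matrix, 15 folds, and
10-seed replicate loops for the recovery, null and permutation suites —
sizes at which every property of interest is measurable while the full
suite stays desk-scale.

## Known limitations

* PAAC/APAAC/CTD follow the standard published definitions; other
  toolkits differ in small conventions (normalization denominators,
  distribution percentile definitions), so cross-package numerical
  comparisons need care.
* The bagging intersection is a hard rule: one unlucky fold removes a
  feature. With few folds and strong class imbalance per fold this is
  conservative by design; no stability-selection softening is provided.
* The evaluation baseline deliberately stays a linear SVM for
  interpretability; no ROC/AUC or calibration analysis is included.
* Descriptor computation is per-protein Python/numpy; it is comfortable at
  benchmark scale (hundreds to thousands of proteins), not engineered for
  whole-proteome all-vs-all scans.
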