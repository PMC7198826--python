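# Methods

## The model

`dynconn` classifies subjects from ROI-averaged rs-fMRI time series
(an M×N matrix per subject: M time volumes, N regions of interest) using
three levels of functional-connectivity (FC) representation:

1. **Static network (C-FCN).** Entry (i, j) is the Pearson correlation of
   ROI i's and ROI j's full-length series. It assumes temporally stationary
   connectivity over the scan.
2. **Low-order dynamic network (Lo-D-FCN).** The series is segmented with a
   rectangular sliding window of length `T` volumes and step `S`;
   `K = floor((M−T)/S) + 1` windowed correlation matrices are produced, and
   trailing volumes not covered by a full window are discarded. No tapering,
   no within-window detrending, no Fisher z-transform.
3. **High-order dynamic network (Ho-D-FCN).** For each window, ROI i's
   *FC profile* is its row of the windowed correlation matrix. The
   high-order edge (i, j) is the Pearson correlation of the two profiles —
   a "correlation's correlation" that involves all other ROIs, capturing
   multi-region interactions that pairwise signal correlation misses.

Resting-state windows have no temporal correspondence across subjects, so
each pair's length-K dynamic series is summarized by **central moments**,
which depend only on the multiset of values:

    m_ij(d) = Σ_k (ρ_ij(k) − mean)^d / K^d        d = 2..D

with the order-1 feature defined as the plain mean (the raw first central
moment is identically zero). The divisor `K^d` is the package default
(`normalization="paper"`); the conventional d-th central moment with divisor
`K` is available as `normalization="standard"`. On a fixed window grid the
two differ only by the constant factor `K^(d−1)`, so downstream selection
and classification — which z-score features per column — are unaffected by
the choice; both are tested.

Each of the three feature blocks is the strictly-lower-triangle
vectorization of its symmetric N×N matrix (length N(N−1)/2; 6670 for the
116-ROI AAL atlas), ordered by the canonical row-major pair index used
everywhere in the package.

## Feature selection and classification

Per feature block, fitted strictly on training subjects:

1. **t-test filter.** Two-sided pooled-variance two-sample t-test per
   feature; keep p < `p_threshold`. (The equal-variance Student form was
   chosen; the test is scale-invariant.)
2. **z-scoring.** Features are standardized with training mean/sd before the
   LASSO and SVM. Raw moment features of different orders live on wildly
   different scales; without standardization a single λ or C could not be
   shared across feature types.
3. **LASSO refinement.** Minimize `(1/2L) Σ_l (I(l) − ⟨y_l, w⟩)² + λ‖w‖₁`
   with labels I ∈ {+1, −1} as regression targets and an unpenalized
   intercept; keep features with |w| > 1e-8. λ is on the per-subject
   (mean-squared-error) scale, so the grid 0.1–0.7 spans nearly-unpenalized
   to fully sparse: all weights vanish at λ ≥ max_j |⟨x_j, I − Ī⟩| / L.
   Solved by scikit-learn coordinate descent (tol 1e-6, ≤10⁴ iterations).
4. **Linear SVM.** Soft-margin linear SVM (libsvm) with trade-off constant
   C; decision scores are fused across the three feature types by a
   weighted average Σ α_c s_c / Σ α_c. A fused score of exactly 0 predicts
   the control class.

**Nested cross-validation.** Performance is estimated by stratified 6-fold
outer CV repeated R times (repetition r uses outer-split seed
`seed + r`). Within each outer training set, a stratified 5-fold inner CV
tunes (p, λ, C) per feature type by maximizing inner mean accuracy, then
the fusion weights (α₀, α₁, α₂) over the α grid on the stored inner
validation scores of the per-type winners; α triples are enumerated freely
and normalized to sum 1 (no simplex constraint is imposed during the
search). Ties always break toward the first grid point in enumeration
order, making the whole procedure a pure function of the data and the seed.
The winning configuration is refit on the full training set and applied
once to the held-out fold. Repetition-level metrics are computed from each
repetition's pooled out-of-fold predictions; aggregates are the mean and
(population) SD over repetitions.

**Metrics.** ACC, TPR (sensitivity), TNR (specificity), PPV, NPV and F1
from the confusion counts with patients (+1) as positives; PPV = TP/(TP+FP)
and F1 = 2TP/(2TP+FN+FP). A ratio with zero denominator is reported as NaN
with a warning rather than silently clamped.

**Selection frequency.** Feature relevance is reported as the number of
(outer fold × repetition) cases in which a ROI pair was selected, per
feature type, sorted descending — the basis of the top-10 most
discriminative connection tables. ROI indices are 1-based in all reports.

## Default parameters

| parameter | default | meaning |
| --- | --- | --- |
| `lo_window`, `lo_step`, `lo_order` | 60, 2, 4 | low-order window length/step (volumes) and moment order |
| `ho_window`, `ho_step`, `ho_order` | 40, 12, 2 | same for the high-order network |
| `p_thresholds` | 0.01…0.10 step 0.01 | stage-1 grid |
| `lambdas` | 0.1…0.7 step 0.1 | stage-2 grid |
| `svm_tradeoffs` | 2⁻⁵…2⁵ | SVM C grid |
| `fusion_weights` | 0.1…0.9 step 0.1 | α grid per classifier |
| outer/inner folds, repetitions | 6 / 5 / 10 | cross-validation design |
| `T_grid`, `S_grid`, `d_grid` | 40:10:90, 2:2:12, 1:1:7 | `sweep_params` ranges |

The (T, S, d) values are fixed per network level before fusion; sweeping
them is exposed as a separate `sweep-params` command (one nested CV per grid
point) rather than folded into the inner CV, where the joint search would be
combinatorially explosive.

### Desk-scale configuration

The bundled tests and `scripts/acceptance.py` run the complete nested CV at
desk scale: `HyperGrid.desk()` (p ∈ {0.01, 0.05, 0.1}, λ ∈ {0.1, 0.3, 0.5,
0.7}, C ∈ {2⁻³, 2⁻¹, 2, 2³}, full α grid) with 3 repetitions and the default
16-ROI synthetic cohort. This keeps a full run at roughly a minute on one
CPU while exercising every stage identically to a full-scale run.

## The synthetic-data generator

`dynconn.simulate` draws each subject from a Markov state-switching
multivariate normal: a hidden connectivity-state sequence follows the
subject's group's Markov chain (initialized at its stationary
distribution), and each volume is a zero-mean Gaussian draw with the active
state's covariance plus isotropic N(0, `noise_sd`²) observation noise.
This is the simplest process in which the three quantities the moment
features are meant to detect are separately controllable:

* **static / mean connectivity** — via the state correlation structure and
  the group's stationary occupancy;
* **fluctuation variance** — via dwell times (switching rate);
* **fluctuation asymmetry** — via asymmetric occupancy (a group sitting
  mostly in one state with brief excursions has a skewed
  windowed-correlation distribution).

Default study conditions: 45 patients / 47 controls (the cohort sizes of
the motivating clinical setting), N = 16 ROIs (desk scale; N = 116 is
supported but slow for high-order construction in tests), M = 170 volumes,
two block-structured connectivity states (two equal blocks, within-block
correlation 0.6, across-block 0, small jittered perturbation projected back
to a unit-diagonal SPD matrix). State 1 swaps one ROI per block half
relative to state 0, so exactly 28 of the 120 pairs change correlation
between states — these are the injected *effect pairs*. Controls dwell in
state 0 (stay-probability 0.97, return-probability 0.15; stationary
occupancy 5/6), patients alternate symmetrically (stay 0.88; occupancy
1/2). Patients therefore differ from controls in the effect pairs' mean
correlation (≈0.17 after noise attenuation), windowed-correlation variance
(≈30% higher), and skewness. `null_transitions()` gives both groups the
control chain, removing every group difference while preserving the
dynamics.

The ground-truth object records the hidden state sequences, the effect
pairs, the per-group stationary occupancy, and the exact population
full-scan correlation (stationary mixture covariance plus noise), which
serves as a Monte-Carlo oracle for the static network.

What the generator does **not** emulate: hemodynamic response convolution,
1/f and physiological noise spectra, head motion, scanner drift,
inter-subject anatomical variability, or site effects. Passing tests on
this generator demonstrate that the pipeline detects group differences in
connectivity mean/variance/asymmetry when they exist and reports chance
accuracy when they do not — not that any particular accuracy is attainable
on real clinical data.

## Numerical and design choices

* **Degenerate correlations.** A zero-variance signal (constant ROI within
  a window) yields correlation 0 with a `DegenerateCorrelationWarning`,
  keeping matrices total; NaN would poison every downstream moment.
* **Exact order invariance.** Central moments accumulate over the
  *window-sorted* pair series. Sorting is analytically a no-op but makes the
  computed value bitwise identical under any permutation or reversal of the
  windows — the invariance the features exist for — rather than identical
  only up to floating-point summation order.
* **High-order profile trimming.** By default positions i and j are removed
  from both FC profiles before correlating (`ho_trim="pair_excluded"`):
  untrimmed profiles contain the two unit self-correlations and the
  duplicated (i, j) entry, which mechanically inflate the correlation.
  `"full_profile"` retains complete rows. Pair-excluded trimming requires
  N ≥ 4 so trimmed profiles have length ≥ 2.
* **Selection fallbacks.** An empty stage 1 falls back to the 10 smallest-p
  features; a LASSO that zeroes everything falls back to the 10 smallest-p
  stage-1 features. Both warn; in the degenerate fallback paths the
  "weights nonzero exactly where selected" invariant is deliberately
  relaxed to keep nested CV total.
* **Ties.** Inner-CV ties break to the first grid point in enumeration
  order; a fused score of exactly 0 predicts control.
* **SPD projection.** Jittered block covariances are repaired by eigenvalue
  clipping at 1e-6 followed by rescaling to unit diagonal.
* **Diagonals.** Connectivity matrices carry diagonal 1 by convention;
  moment-matrix diagonals are 1 (d = 1) or 0 (d ≥ 2). Diagonals never enter
  the feature vector.
* **Stratification.** Outer folds are stratified by class; with a 45/47
  cohort unstratified 6-fold splits can produce strongly imbalanced test
  folds that destabilize per-fold metrics.

## Limitations

* Feature extraction treats each pair's dynamic series independently;
  cross-pair dependence enters only through the joint LASSO.
* The high-order construction is O(K·N²·N) per subject and dominates run
  time at N = 116; the estimator caches nothing across calls.
* Inner-CV accuracy over small folds is a coarse, plateau-prone tuning
  objective; deterministic tie-breaking makes results reproducible but can
  mask near-equivalent configurations.
* Aggregate SDs over repetitions share subjects across repetitions and are
  therefore not independent replicates.
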