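# Methods

## Network estimators

For a subject matrix `X ∈ R^{T×N}` (T timepoints, N regions), all three
estimators are built from Pearson correlation:

* **Low-order FCN** `C_LON[i,j] = corr(x_i, x_j)` over the raw columns.
* **Correlation-of-correlations FCN** `C_HON[i,j] = corr(c_i^{-ij}, c_j^{-ij})`
  where `c_i^{-ij}` is row i of `C_LON` with positions i and j deleted from
  *both* rows (positional alignment preserved; compared vectors have length
  N−2, hence the requirement N ≥ 4).
* **Hypergraph high-order FCN**: incidence `H[i,j] = 1 iff C_LON[i,j] ≥ t`
  (signed, inclusive comparison; an `absolute=True` variant thresholds
  |c_ij| instead), hyperedge series = unweighted per-timepoint mean of the
  *raw* member series, and `H-C_HON[i,j] = corr(x′_i, x′_j)`.

Conventions and edge cases:

* The threshold comparison is **signed** by default: hyperedges collect
  strongly *positively* correlated regions; anticorrelated regions are
  excluded.  The absolute-value variant is exposed but off by default.
* Membership is inclusive (`≥ t`), so the central region (self-correlation
  1) always belongs to its own hyperedge and no hyperedge is empty.  There
  is exactly one hyperedge per region, keeping `H-C_HON` N×N.
* Hyperedge averaging uses the raw series, not z-scored ones; consequently
  `C_LON` and `C_HON` are invariant to positive rescaling of any region's
  series while `H-C_HON` is not (rescaled members contribute more or less
  to their hyperedge means).  This is deliberate and tested behaviour.
* Undefined correlations (a constant series, or a zero-variance exclusion
  vector in `C_HON`) are imputed to 0 — the no-association neutral value —
  flagged in `degenerate_pairs`, and warned about.  Diagonals are defined
  as 1 by convention.
* Symmetry/identity assertions use an absolute tolerance of 1e-10.
* Regions and hyperedges are reported 1-based in all user-facing output.

## Feature selection and classification

Features are the strictly-lower-triangle entries in fixed row-major order
((1,0), (2,0), (2,1), …), giving `N(N−1)/2` values per view.  Selection is
two-stage and order-fixed:

1. **t-test filter** — per-feature two-sample test between groups, Welch's
   unequal-variance variant by default (a pooled-variance toggle exists);
   keep `p < p_threshold`.  No multiple-testing correction: the threshold
   is itself a tuned hyperparameter on a raw-p scale.  A feature constant
   in both groups gets p = 1 (equal means) or 0 (unequal).
2. **LASSO** — minimise `½‖k − Yω‖² + λ‖ω‖₁` with labels `k = ±1`
   (patients +1) and no intercept, on features z-scored with training-fold
   statistics.  The solver is scikit-learn's coordinate descent; its
   mean-loss parameterisation is mapped via `alpha = λ/n` so `λ` always
   refers to the sum-of-squares objective above (tolerance 1e-10, max
   100 000 passes).  Tests verify the fitted weights against the
   subgradient optimality conditions directly.  The support is the set of
   nonzero weights; LASSO can never resurrect a t-test-removed feature.

The classifier is a linear soft-margin SVM; the tuned constant `γ` is its
cost parameter C (there is no kernel width in a linear kernel).  Fusion
averages the two views' signed decision scores with fixed weights 0.5/0.5.
A score of exactly 0 predicts the control class — deterministic and
specificity-favouring.

## Nested cross-validation

Outer loop: stratified 10-fold (class ratios per fold within one subject
of the cohort ratio), shuffled by the user seed.  Inner loop: stratified
10-fold over each outer-training set; the triple `(p, λ, γ)` maximising
mean inner accuracy is refit on the full outer-training set and evaluated
on the held-out fold; test predictions are pooled over folds into one
confusion matrix per method.  Design choices:

* Hyperparameters are tuned **per view**; fusion reuses the two
  single-view models and only the weights 0.5/0.5 are fixed.
* Inner-accuracy ties resolve to the smallest p, then λ, then γ — the most
  parsimonious/most regularised candidate.
* A hyperparameter point whose selection stage keeps zero features scores
  chance (0.5) in the inner loop rather than erroring; if the final refit
  ends with an empty support the view outputs zero scores (control
  predicted).
* The incidence threshold t is **not** tuned in the inner loop; it is fixed
  (default 0.7) and studied separately by the `sweep` command over
  t = 0.10, 0.15, …, 0.95 (18 points).
* Stratification plus a required minimum of folds ≤ smaller-class size
  guards against single-class training folds; violations raise with advice
  to reduce the fold count.
* Metrics: ACC, SEN, SPE, BAC = (SEN+SPE)/2, PPV, NPV, and F1 defined as
  the harmonic mean of PPV and SEN.  Zero-denominator ratios are reported
  as 0 and flagged.
* `C_HON` participates as an optional third benchmarked method; fusion is
  strictly `C_LON` + `H-C_HON`.

Selection frequency counts, per feature, the outer folds whose final
support contained it; ranking is by count (desc), then mean |LASSO weight|
(desc), then feature index (asc).  For the hypergraph view each ranked
feature is a hyperedge pair `(e_i, e_j)`; since incidence is built per
subject from that subject's own `C_LON`, the reported member sets are the
majority vote (> half the subjects) within each diagnostic group.

## Synthetic cohorts

The generator draws each subject's T rows i.i.d. from `N(0, Σ_g)` where
`Σ_g` is a group-specific correlation matrix: `within_block_corr` inside
each of `n_blocks` contiguous, near-equal communities and
`between_block_corr` elsewhere.  The patient group's matrix differs at
`discriminative_pairs` (default: five cross-community pairs) by
`effect_size`; modified matrices are repaired to SPD by eigenvalue
clipping at 1e-6 and re-normalisation to unit diagonal, which can slightly
perturb the planted effects — the realised per-pair differences are
reported alongside the request.  White noise of sd `noise_sd` is added,
attenuating all observable correlations by `1/(1+noise_sd²)` (also
reported).  Randomness is hierarchical — subject s of group g uses an
independent generator seeded `(seed, g, s)` — so enlarging a cohort never
changes existing subjects.

Defaults (45 patients + 47 controls, 170 timepoints × 116 regions,
8 communities, within/between correlations 0.6/0.05, effect 0.5, noise sd
0.25) emulate the shape of a single-site resting-state cohort.  A
multivariate-normal model was chosen because Pearson-based pipelines are
exactly parameterised by correlation structure, making ground truth
well-defined.  The generator does **not** model haemodynamics, temporal
autocorrelation, or site effects; passing tests therefore demonstrate
correctness of the machinery and recoverability of correlation-level
signal, not performance on real multi-site fMRI.

## Problem sizes used by tests and the acceptance script

The cross-validation-level checks (null-cohort chance control, signal
recovery, fusion behaviour) run on scaled-down cohorts — 40+40 subjects,
100 timepoints × 30 regions, 5 communities — with reduced grids
(`p ∈ {0.01, 0.05}`, `λ ∈ {0.1, 0.5, 0.9}`, `γ ∈ {2⁻², 2⁰, 2²}`), 20 seeds
in the test suite and 5 in `scripts/acceptance.py`.  These sizes keep the
full nested protocol affordable on a single CPU while leaving the
statistical conditions (effect sizes 0 and 0.5, cohort balance, fold
structure) intact.  Oracle-equivalence checks run at N ≤ 10, T ≤ 50
against naive nested-loop references.

## Reproducibility and limitations

Every pipeline run writes its resolved configuration (with package
version) and seed next to its outputs; the declared data outputs
(`cv_report.json`, `metrics.tsv`, selection-frequency tables, hyperedge
report) are bit-identical across re-runs with the same config and seed.
The log file carries timestamps and is excluded from that guarantee.

Known limitations: no dynamic/sliding-window networks, no weighted
hyperedges or hypergraph-Laplacian spectral methods, no nonlinear kernels
or probability calibration, no multi-site harmonisation, and no
between-method significance testing.  Real-data performance additionally
depends on upstream fMRI preprocessing, which is out of scope — the
package consumes already-extracted regional time series.
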