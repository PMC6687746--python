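# Methods

`neurocca` implements a complete brain–behaviour covariation analysis for
two-view subject data: a brain view **X** (n subjects × p connectivity
edges) and a behaviour view **Y** (n subjects × q questionnaire/IQ/
demographic items), linked by canonical correlation analysis (CCA) after
PCA reduction, with permutation-based model selection and inference and a
multiple hold-out generalizability check.

## Data model and preprocessing

Connectivity enters either as per-subject symmetric Pearson-correlation
matrices over r regions — vectorized to the r(r−1)/2 upper-triangle edges
in row-major order (i < j), so 348 regions give 60378 edges — or directly
as a subjects × edges matrix. Regional time-series can be converted to
connectivity with pairwise Pearson correlation.

QC and preprocessing follow fixed, configurable rules (defaults in
parentheses):

1. **Region exclusion.** A region is dropped when its mean signal,
   z-scored across regions within a subject (sample SD, ddof = 1), falls
   strictly below a cut (−1.96) for at least one subject. A subject whose
   regional signals have zero variance contributes no exclusions and is
   logged.
2. **Subject exclusion.** A subject is dropped when max framewise
   displacement exceeds 1.3 mm or mean FD exceeds 0.3 mm (both strict
   "greater than"; a subject exactly at a threshold is retained). Motion
   exclusion is applied before all other steps.
3. **Near-constant items.** A behaviour item is dropped when its modal
   value's share among *observed* entries strictly exceeds 0.95. The
   filter runs before imputation, on observed values.
4. **Imputation.** Missing behaviour entries are replaced by the item's
   median over observed values (even counts: mean of the middle two).
5. **Confound regression.** Mean FD and one-hot scanner site are
   regressed out of every brain and behaviour variable by OLS with an
   intercept; the last one-hot column is dropped to keep the design
   full-rank. Residuals are exactly orthogonal to all confound columns.
6. **Standardization.** Each variable is scaled to mean 0, SD 1 (sample
   SD). A zero-variance column at this stage is an error, never silently
   zeroed.

For the permutation workflow, confound betas and scaling are estimated on
the full analysis sample (standard practice when no held-out data exist).
For hold-out, every data-dependent parameter — retained items, medians,
betas, scaling, PCA bases, canonical weights — is estimated on training
subjects only and applied frozen to test subjects, so no test statistic
can influence training.

## PCA + CCA

Each view is reduced to its top d principal components via SVD of the
centred matrix; each basis vector's largest-magnitude weight is made
positive so runs are reproducible. CCA between the reduced views X_d and
Y_d is solved by SVD of the whitened cross-covariance (thin QR of each
centred view, then SVD of Q_x'Q_y), which is numerically stable and exact
for full-rank inputs. Canonical variates are scaled to unit sample
variance; within a view they are mutually uncorrelated, and the paired
variates' Pearson correlation equals the canonical correlation. CCA signs
are arbitrary, so each mode is optionally re-signed to make the behaviour
item with the largest absolute loading positive (u/P_X flipped jointly
with v/P_Y).

Interpretation uses **loadings** (structure coefficients): the Pearson
correlation of each preprocessed variable with the corresponding
canonical variate — not the canonical weights, which are unstable in
correlated data. Top-k or top-fraction tails per sign are selected
(fractions convert to counts by rounding half away from zero: 0.5% of
60378 edges → 302), selected edges are summarized per node by mean
absolute loading, and nodes are grouped into the seven cortical
resting-state networks plus subcortex via a user-supplied label map.

## Permutation inference and model selection

For a candidate dimensionality d, the true canonical correlations **q**
are computed once; then the rows of the reduced behaviour matrix are
randomly permuted n_perm times (default 10000) and CCA refit, giving the
null matrix Q* (d × n_perm). Mode i receives a family-wise-error
corrected p-value by the maximum-statistic rule

    p_fwe[i] = (1 + #{permutations: max_j q*_j ≥ q_i}) / (1 + n_perm),

comparing every true correlation against the null distribution of the
*largest* permuted correlation. This makes p_fwe non-decreasing in the
mode index (significant modes always form a prefix) and controls the FWE
across modes. With the add-one convention the smallest reportable value
is 1/(n_perm + 1); it is displayed as, e.g., "< 0.0001" at 10000
permutations. Because row permutation commutes with the fixed PCA
projection, permuting reduced rows equals permuting raw behaviour rows.

Model selection repeats this over a candidate grid (default
{5, 10, 25, 50, 75, 100, 125, 150, 200}) and Bonferroni-corrects the
first-mode p-values over the grid (0.05/9 ≈ 0.0056 at the default); the
chosen d attains the minimal p among significant candidates, ties broken
toward the smallest d (preferring the more parsimonious model).

### Nuisance handling in the permutation scheme

Regressing the *same* confound design out of both views leaves both
residual matrices orthogonal to the design's column space. The unpermuted
views are therefore aligned within an (n − k)-dimensional subspace that
permuted pairs do not share, which makes the naive shuffle of residualized
rows measurably liberal at small n: in our simulations at n = 120 with a
4-column design, the empirical FWE of the naive scheme is ≈ 0.063 (1600
null replicates) instead of 0.05. At n ≈ 300 with a 5-column design the
effect is negligible, but it is a genuine property of permuting after
residualization.

The package therefore defaults to a projection scheme in the spirit of
the permutation-CCA literature: both reduced views are mapped into an
orthonormal basis of the confound design's null space (n − k rows whose
entries are exchangeable under the null for Gaussian-like noise), and the
permutation shuffles those rows. The true canonical correlations are
mathematically unchanged — the reduced views already live in that
subspace column-wise, so the uncentred canonical correlations of the
transformed views equal the centred ones of the originals (verified
bit-identical in the tests) — while the empirical FWE returns to 0.051
(1600 replicates) even when site and motion effects contaminate both
views. `select_pca_dimension(..., nuisance="naive")` retains the plain
row shuffle. For non-Gaussian noise the projected rows are exchangeable
only approximately; this is the usual caveat of such projections.

## Multiple hold-out validation

Defaults: 10 random splits with 20% of subjects held out, 1000
permutations per split. Per split, the candidate-d choice (when a grid is
given) reuses the permutation selection on training data only; the first
mode's out-of-sample correlation is computed on projected test variates
and permutation-tested by shuffling test-set behaviour scores (one-sided,
add-one convention). The omnibus rule declares generalization when the
minimal per-split p is below α/n_splits (Bonferroni over splits). The
split count, fraction, inner permutation count and omnibus rule are all
configurable; these defaults follow the structure of the multiple
hold-out framework for two-view latent-variable models rather than any
single published parameterization.

Out-of-sample canonical correlations are *attenuated*: weights estimated
on n_train subjects align imperfectly with the population directions, so
test correlations sit systematically below the population value while
training correlations sit above it. The size of the attenuation grows
with p/n_train and shrinks with signal strength. For one planted mode
with population correlation 0.6, p = q = 60, n = 300 (n_train = 240), the
per-variable signal eigenvalue 1 + a² = 2.5 sits barely above the
Marchenko–Pastur bulk edge (1 + √(p/n_train))² ≈ 2.25, and the mean
hold-out test correlation is ≈ 0.49–0.50 across simulated datasets,
essentially independent of d ∈ {1, 2, 3, 5}. Hold-out results should be
read as a generalizability bound, not an unbiased effect-size estimate.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with ground truth for every downstream test:

    x_i = Σ_k a_xk w_xk z_ik + site + motion + σ_x ε,   (behaviour alike)

with shared latent scores z ~ N(0,1), orthonormal loading directions
(QR of a Gaussian matrix, sign-fixed) and isotropic Gaussian noise. Under
this model the population canonical correlation has the closed form
ρ_k = a_xk a_yk / √((a_xk² + σ_x²)(a_yk² + σ_y²)), validated in the test
suite against an empirical CCA oracle at n = 10⁵ (±0.01). Confounds are a
3-level site (multinomial) with per-variable Gaussian effects and a
log-normal mean-FD (median ≈ 0.12 mm) with a per-variable linear effect;
missingness is completely at random (consistent with median imputation's
assumption) in the behaviour view only; near-constant items carry a
minority value in 2% of subjects (modal share 98%).

Defaults are scaled study conditions chosen once: 306 subjects, 150 brain
edges and 60 behaviour items (desk-scale stand-ins for 60378 and 364),
K = 2 modes with population correlations 0.62 and 0.58, effect scales
0.5, 5% missingness, 8 near-constant items. What the generator does *not*
emulate: the long-range correlation structure of real connectomes
(directions are orthonormal, noise isotropic), ordinal/skewed item
distributions, informative missingness, and site-by-variance interactions
— so passing tests demonstrate correctness of the machinery and
calibration under the stated model, not robustness to every property of
real data.

## Numerical choices and edge cases

- Symmetry tolerance for connectivity matrices: 1e−8 absolute; larger
  asymmetry is an error (never silently averaged). Unit diagonal checked
  to 1e−6.
- Edge ordering is fixed to the row-major upper triangle; the
  vectorize/devectorize round trip is exact.
- Rank deficiency in CCA inputs or the confound design raises an error
  (with a hint to drop a redundant one-hot column) instead of producing
  pseudo-inverse artifacts.
- Degenerate cases are errors with named variables: constant time-series,
  fully missing items, zero-variance columns at standardization or
  loading time.
- All randomness flows through `numpy.random.Generator` seeded via
  `SeedSequence.spawn`, so every result — including the full CLI pipeline
  — is bit-reproducible from its seed; rerunning a pipeline writes
  byte-identical result files (only the wall-clock log differs).
- Simulation-based tests are sized to run on a single CPU in minutes:
  FWE calibration uses 200 null datasets (n = 120, p = q = 40, d = 5,
  200 permutations), recovery uses 20 datasets (n = 300, p = q = 60);
  these sizes are the package's validation conditions and are stated in
  the tests themselves.

## Known limitations

- The naive permutation scheme (the published construction) is slightly
  anti-conservative after shared confound regression at small n; the
  projection scheme is the default for that reason (see above).
- Loadings-based selection inherits the instability of extreme order
  statistics: near-tied correlations make "top 20" membership fragile
  even when the overall ranking is stable.
- Median imputation before confound regression leaves a small nonlinear
  confound residue in imputed entries; at the default 5% missingness this
  is negligible, at high missingness it is not.
- Sparse/regularized CCA variants and exchangeability-block permutations
  (for family structure) are out of scope.
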