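# Methods

## Scope and data model

The package analyzes three participant-aligned data blocks — an 11-column
physical-activity (PA) feature table, a brain image-derived phenotype
(IDP) block (1485 Fisher-z functional-connectivity edges from a 55×55
netmat, or 139 regional gray-matter volumes), and binary disease outcomes
— each with its own confounder table. Alignment is always by explicit
participant identifier, never row order, and complete-case filtering drops
any participant missing a value in any variable of the configured
analysis. Raw-signal accelerometer calibration, epoching, non-wear
handling and all MRI preprocessing are upstream of this package: inputs
are clean minute-level ENMO traces and tabulated IDPs.

## PA feature derivation

Eleven summaries are computed per participant from minute-level ENMO
(milli-g), per day and averaged across days. Conventions, each a named
keyword with the default given:

* **Activity threshold** (`sedentary_cut`, 30 mg): a minute is active at
  or above it. LIPA covers [`sedentary_cut`, `mvpa_cut`); MVPA is at or
  above `mvpa_cut` (193 mg, the NHANES-anchored cut-point). LIPA + MVPA +
  sedentary minutes always equal 1440 per day.
* **Log acceleration** (`tlac_log`, `"log1p"`): TLAC, M10, L5 and DARE use
  log(1 + ENMO), which is defined at zero; plain log on positive minutes
  is available. This is a convention, not a cohort-pipeline fact.
* **Transitions**: ASTP = (# active→sedentary transitions) / (# active
  minutes excluding each day's final minute); SATP symmetric. A
  probability with no eligible minutes is missing (NaN), never 0.
* **Bouts**: mean length of maximal runs of one kind; missing if no run.
* **Circadian windows**: M10/L5 are means of log acceleration over the
  contiguous 600-/300-minute window per day maximizing/minimizing that
  mean; windows do not wrap midnight. RA = (M10−L5)/(M10+L5), reported as
  0 with a warning when the profile is constant (denominator 0 or
  M10 = L5 to machine precision).
* **DARE** (`daytime_window`, 08:00–20:00): daytime log-acceleration sum
  over the day's total; NaN on an all-zero day.

Quantities undefined on some days are averaged over the defined days.

## Netmat vectorization

A netmat (node-by-node partial-correlation matrix) must be symmetric to
1e-8 with off-diagonal entries in (−1, 1). Its strict lower triangle in
row-major node order is mapped element-wise by the Fisher z-transform
arctanh; the ordering is recorded by `edge_labels` and the map is exactly
invertible. A 55-node netmat gives 55·54/2 = 1485 edges.

## Bipartial CCA

Each block is residualized on its own confounder matrix by least squares
(intercept always included; rank-deficient confounders are projected via
pseudoinverse with a warning), then standardized to unit column variance
by default — CCA on the correlation scale; a `scale=False` flag gives the
covariance scale. Canonical correlations are the singular values of the
whitened cross-covariance Σxx^{−1/2} Σxy Σyy^{−1/2}, with spectral
truncation of within-block eigenvalues below 1e-10 of the maximum for
numerical stability near singularity. Variates are scaled to unit sample
variance, and each mode is oriented so the largest-magnitude X-side
structure loading is positive (canonical signs are otherwise arbitrary;
a fixed orientation is needed to interpret loadings).

Reported alongside the correlations:

* **Variance explained**: mode j explains
  Σ_l corr(col_l, variate_j)² var(col_l) / Σ_l var(col_l) of its own
  block; over all modes of the smaller block this accumulates to 1.
* **Cross-loadings**: Pearson correlation of each variable in one block
  with the other block's variate (e.g. each PA variable against the
  primary brain variate).

### Mode inference

*Approximation test.* Bartlett's chi-square approximation to Wilks'
lambda: for mode s, Λ_s = Π_{j≥s} (1 − ρ_j²), statistic
−(n_eff − 1 − (p+q+1)/2)·log Λ_s with (p−s+1)(q−s+1) degrees of freedom.
Because residualization consumes degrees of freedom, the estimator enters
the effective sample size n_eff = n − max(confounder columns per side);
with the raw n the test is measurably anti-conservative (≈7% rejection at
α = 0.05 in null simulations at n = 500, p = 11, q = 50, versus ≈5% with
the correction). Rao's F approximation is available via `method="rao"`.
The standalone `approximation_test(rho, n, p, q)` takes whatever sample
size the caller supplies.

*Permutation test.* Rows of the residualized X block (by convention the
smaller, PA-like side) are permuted uniformly; p(mode j) =
(1 + #{ρ*_j ≥ ρ̂_j}) / (B + 1) with B ≥ 99 seeded permutations.
Residualized rows are not exactly exchangeable, which can bias modes
beyond the first; the package logs this caveat and reporting should focus
on the primary mode. Projection-based exchangeability restorations are
out of scope.

## Mass-univariate stage

Per response column, a partial F-test compares intercept+confounders
against intercept+confounders+PA (the response set "significantly related
to PA after controlling for confounders"); an overall-model F variant is
available. Benjamini–Hochberg adjustment at α = 0.05 (configurable)
defines the screened index set. Predictive correlations use repeated
shuffled K-fold CV (10 folds, 100 repetitions by default) of the linear
model; the default design is confounders+PA, with a PA-only option.

Importance engines: (i) t-tests on PA coefficients in the full linear
model, stored as −log10 p; (ii) bidirectional stepwise BIC over PA
variables with confounders forced into every candidate, starting from
confounders-only, ties broken by first candidate in fixed column order —
deterministic; (iii) random-forest permutation importance on
[confounders, PA], reported for PA columns only (impurity importance is
not used: permutation importance is less biased for correlated features).
The consensus ranking converts per-method column-mean scores to ranks and
averages them.

## Nested risk models

For each disease, logistic models M0 ⊂ {M2, M3} ⊂ M1 over standardized
blocks are evaluated by stratified 10-fold CV repeated over random splits
(stratification is necessary at 2–12% prevalence), splits shared across
models within a repetition. Unpenalized maximum-likelihood fits; rare
outcomes with wide IDP blocks make such fits ill-posed, so the IDP block
is projected onto its leading principal components (90% variance by
default) *inside each training fold*, keeping models nested and CV honest.
This reduction is an interpretation choice and is flagged as such.

Per repetition, pooled out-of-fold probabilities give one empirical ROC;
curves are vertically averaged on a 1001-point FPR grid and AUC is the
trapezoidal integral of the mean curve. Vertical segments (duplicate FPR
breakpoints) resolve to their upper TPR at the breakpoint, which makes the
grid integral match the empirical Mann–Whitney AUC to grid resolution —
the mean-curve AUC and the mean of per-repetition AUCs agree to a few
parts in 10⁴ in practice. McFadden pseudo-R² = 1 − ℓ(M)/ℓ(M0) uses
Bernoulli log-likelihoods of pooled out-of-fold probabilities, the null
model refit per training fold, probabilities clipped at 1e-12; out-of-
sample values can be negative for overfit models. On training data the
nested ordering R²(M1) ≥ R²(M2), R²(M1) ≥ R²(M3) holds exactly.

## Synthetic cohorts

A linear Gaussian factor model defines the joint distribution: each latent
factor loads one unit direction in the PA block and one in an IDP block,
with within-block direction sets orthonormalized in order (user-supplied
directions keep their leading components). For target canonical
correlation r and block noise scale σ, the loading scale is
h = σ√(r/(1−r)) on each side, giving per-side communality r and hence
population canonical correlation exactly r for that mode.
`population_canonical_correlations` recomputes the implied covariances and
whitened-cross-covariance singular values numerically, so it remains exact
for arbitrary (non-orthogonal) user directions. Defaults plant ρ = 0.50
for the FC pairing and ρ = 0.19 for GMV — the regime the analysis is
designed for.

Confounders (binary sex-like, continuous age-like and motion-like) affect
every block linearly but are independent of the latents, so
residualization leaves planted correlations intact. Presentation maps are
linear or monotone: PA columns are affinely mapped to plausible feature
scales; netmat entries are tanh(0.15·z) of the Gaussian edge signal, so
entries lie in (−1, 1) and the Fisher-z edge table is exactly 0.15·z —
linear, leaving canonical structure untouched; volumes are
ref·exp(0.08·z̃), positive by construction, with a log-scale field small
enough that raw-scale correlations are negligibly distorted (the exact
oracle checks use the FC block). Disease labels follow a logistic model
over standardized columns with the intercept solved by Brent's method to
hit target prevalences (defaults 4.5%, 2.3%, 3.3%, 12.5% for diabetes,
stroke, CHD, cancer); default coefficients make outcomes
confounder+PA-driven with activity protective, cancer only weakly related.

What the generator does **not** emulate: marginal distributions of real PA
or IDP variables (PA columns are Gaussian and can stray outside natural
ranges), longitudinal structure, site/batch effects, non-linear confounding, or
missingness beyond complete-case semantics. Passing tests
therefore demonstrate correct recovery of second-order structure and
outcome models under the stated generative assumptions, not robustness to
real-data pathologies.

## Validation strategy and problem sizes

Every estimator is checked against an independent oracle: dense
eigendecomposition and alternating-least-squares maximization for CCA;
literal step-up enumeration for Benjamini–Hochberg; statsmodels OLS for
t- and partial-F statistics; hand enumeration for PA features; closed-form
likelihood arithmetic for McFadden's measure. Simulation-based checks use
50 replicates at n = 8000 with a 210-edge block for planted-ρ recovery,
500 null simulations (n = 500, p = 11, q = 50, 199 permutations) for test
calibration, 100 CV repetitions at n = 2000 for the ROC-equivalence
property, and 40 replicates for qualitative pattern recovery — sizes
chosen so sampling error is well inside the tested tolerances while the
full suite runs in minutes.

## Known limitations

* Permutation inference beyond the primary mode inherits the
  exchangeability caveat; the package surfaces it but does not correct it.
* The IDP principal-component reduction in risk models changes the
  interpretation of M1/M3 coefficients (directions of maximal IDP
  variance, not individual edges/regions).
* Sample canonical correlations are upward-biased when the edge count is
  an appreciable fraction of n; the package reports raw estimates and
  leaves bias control to the inference layer.
* The stepwise-BIC engine is exhaustive over single add/drop moves only;
  with strongly collinear PA variables the selected set is one of several
  near-equivalent solutions (deterministic tie-breaking makes it
  reproducible).
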