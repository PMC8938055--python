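# Methods

This note documents the statistical model behind `rankpls`, the numerical
conventions, the synthetic-data generator, and the design choices that were
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model

The regression model is `y = α + Zβ + ε` with an ordinal response coded as
consecutive integer ranks 1..K and treated numerically. Components are
extracted by univariate NIPALS (weights → scores → loadings → deflation of
both Z and y), and coefficients are recovered as β̂ = W(P′W)⁻¹q with
α̂ = ȳ − Z̄β̂. P′W is solved directly; a singular P′W falls back to the
Moore–Penrose pseudo-inverse with a logged warning.

The loading weight is the pluggable part. The standard weight is the
covariance direction Z′y. The eight rank variants replace entry j with an
association coefficient between predictor column j and the response. The
Kendall-family coefficients (τ-A, τ-B, τ-C, Somers' D, Goodman–Kruskal tau
and gamma) are all functions of one set of pair tallies — concordant n_c,
discordant n_d, total n₀ = n(n−1)/2, and the tie terms n₁ = Σ tᵢ(tᵢ−1)/2,
n₂ = Σ uⱼ(uⱼ−1)/2 over tie groups of the first and second variable — so the
package computes the tallies once per column pair and derives each
coefficient from them.

### Pair counting

Tallies are computed exactly by one of two routes with identical semantics
(cross-checked in the test suite against an exhaustive O(n²) enumeration):

* contingency-table route — double cumulative sums over the r×k table of
  level co-occurrences, O(rk); used when r·k is modest (ordinal codes);
* sort route — lexicographic sort plus strict inversion counting of the
  second variable with a Fenwick tree, O(n log n); used when the level sets
  are near-continuous (deflated variables from component 2 on).

### Conventions per coefficient

* **Spearman's ρ** is Pearson correlation of midranks. For tie-free data
  this equals the classical 1 − 6Σd²/(n(n²−1)) shortcut; with ties the
  midrank form is the standard generalization (the shortcut is biased under
  ties, and ordinal survey data are heavily tied).
* **τ-B** uses the tie-adjusted denominator √((n₀−n₁)(n₀−n₂)), keeping
  |τ_B| ≤ 1.
* **τ-C** uses 2m(n_c−n_d)/(n²(m−1)) with m = min(rows, cols) of the
  contingency table.
* **Somers' D** is D(y|x) = (n_c−n_d)/(n₀−n₁): predictor-tied pairs are
  removed from the denominator, making the measure asymmetric —
  equivalently τ_A(x,y)/τ_A(x,x).
* **Goodman–Kruskal tau** has two modes. The default mode is the doubled
  tau-A, 2(n_c−n_d)/n₀, which can exceed 1 in magnitude; it is kept as the
  default for continuity with the weight family this package descends from.
  `mode="classical"` gives the proportional-reduction-in-error statistic
  τ(y|x) ∈ [0, 1].
* **Goodman–Kruskal γ** is (n_c−n_d)/(n_c+n_d): tied pairs dropped entirely.
* **Theil's U** is U(x|y) = (H(x) − H(x|y))/H(x) with natural-log entropies
  and 0·log 0 := 0 (the ratio is base-invariant).
* Degenerate inputs (constant vector, fully tied variable, zero entropy,
  no untied pairs) return 0 with a `DegenerateInputWarning` — a degenerate
  column must never abort a fit.
* Nonnegative measures (Theil's U, classical Goodman–Kruskal tau) are given
  the sign of the column's Spearman ρ before entering the weight vector,
  since PLS scores need signed directions.
* Continuous inputs: pair-based measures consume them directly (pair
  counting sees only the ordering, i.e. midranks implicitly).
  Contingency-table measures (τ-C, Theil's U, classical GK tau) bin a
  column into quintiles when it has more than 20 distinct values.

Each weight vector is scaled to unit Euclidean norm and its sign fixed so
the largest-magnitude entry is positive (reproducibility under the
sign-indeterminacy of PLS directions). An all-zero vector stops component
extraction with a logged truncation.

## Centering and scaling

Predictors and response are always centered. Unit-variance scaling of Z is
**off by default** and available via `scale=True` / `--scale`. This is a
deliberate and load-bearing choice: the covariance weight on unscaled
ordinal codes conflates a column's code variance with its relevance (a
4-level column has ≈1.4× the standard deviation of a 3-level column under
equal-probability coding), whereas every rank measure is invariant to
per-column monotone rescaling. Center-only preprocessing therefore
preserves exactly the contrast the rank-weight family exists to exploit —
and it matches the algorithm as classically stated, which introduces no
standardization step. Under full standardization the covariance weight
becomes the Pearson-correlation weight, which is close to optimal for
training fit per component; the rank variants then offer no fitting
advantage (the package's own simulation confirms both regimes).

## Deflation and later components

After the first deflation the working variables are continuous. Rank
weights for components c ≥ 2 apply the chosen measure to the deflated
variables' orderings (midranks), which the pair-counting core does
implicitly. This is logged, and it is a convention, not a theorem — one
could also re-rank explicitly or freeze the measure after c = 1; the chosen
convention keeps every component's weight rule identical.

Extraction stops early when ‖w_c‖ or t′t falls below 1e−12, with the model
flagged `truncated` and the achieved C recorded.

## Variable selection

* **LW**: per component a, scores |w_{a,j}| / max_k |w_{a,k}|; aggregated
  across components by max (most favorable evidence; mean available).
  Default threshold 0.5 on the normalized scale.
* **RC**: |β̂_j| on the preprocessed predictor scale. Default threshold:
  median |β̂| (retains the upper half).
* **SMC**: each column z_j (standardized) is decomposed into its projection
  on the normalized fitted-response direction u = Zβ̂/‖Zβ̂‖ and the
  orthogonal remainder; the importance is the mean-square ratio
  (z_j′u)² / (‖z_j − (z_j′u)u‖²/(n−2)), thresholded at the 0.95 quantile of
  F(1, n−2). A column exactly collinear with u gets a capped sentinel value.

  The F reference treats u as if it were independent of z_j. That holds
  when each column contributes negligibly to the fitted direction — in
  practice p ≫ n, the regime the null-calibration tests use. At moderate
  p/n the statistic is stochastically larger than F(1, n−2) and the 5%
  threshold rejects more than nominally; the retained set is then a
  liberal screen rather than a calibrated test. This limitation is
  intrinsic to reusing the training data for both fitting and screening.

All thresholds are configurable and a fixed top-k override is provided
(whether a retained count comes from a threshold or a fixed k is otherwise
ambiguous to downstream readers, so the applied cut is stored with the
scores). Selection runs on the training split only; the test split is
restricted to the retained columns before projection.

## Validation layer

* **AIC** (Gaussian least-squares form): n·ln(RSS/n) + 2(C+1), with C+1
  effective parameters — one per component plus the intercept. Used to
  compare weight variants at equal C, where it is a pure fit comparison.
* **70:30 Monte-Carlo splitting**: train size ⌊0.7n⌋; splits are re-drawn
  (up to 100 times) until both parts contain every response level so LDA
  stays well-posed; plain random splits available by flag. Ten iterations
  by default.
* **LDA on scores**: Fisher discriminant with pooled within-class
  covariance (n−k denominator) and count-proportional priors, implemented
  directly; a singular pooled covariance gets a ridge of 1e−6·trace/d. The
  headline metric is test-split accuracy (LDA trained on training scores,
  applied to projected test scores); leave-one-out accuracy on the training
  scores is recorded alongside. LOOCV with count priors is slightly
  pessimistic under the null — the held-out observation's class momentarily
  has one fewer member — so chance-level LOOCV accuracy sits just below
  1/K at small n.
* **Seed schedule**: every (measure, selection, iteration) derives its seed
  as crc32 of the cell label mixed with the master seed, so the grid is
  bitwise reproducible and adding a cell never perturbs the others.
* **Winner rule**: highest mean accuracy; ties broken by fewer retained
  variables, then lower AIC (parsimony first).
* **Component count**: the grid uses a fixed C (default 3) rather than
  re-choosing C by cross-validation inside every cell; a
  `choose_components()` helper implements accuracy-maximizing selection
  over C = 1..min(p, 15) for single pipelines. Fixed C keeps the 36-cell
  grid tractable and the AIC comparison interpretable (equal parameter
  counts).

## Synthetic generator

Latent-Gaussian thresholding: correlated standard-normal latents with
block-exchangeable structure (correlation ρ_b within block b, 0 between),
each column discretized at empirical equal-probability quantiles into its
assigned level count; the latent response is
effect_size·Σ(informative latents) + N(0, noise_sd²), discretized into K
ranks. Defaults: n = 1000, p = 100, fifty 3-level + fifty 4-level columns,
K = 3, blocks of 10 at ρ = 0.5, the first block (10 columns, all 3-level)
informative, effect_size = 0.5, noise_sd = 1. The effect size and signal
layout are a calibration choice — picked once so the planted signal is
comfortably detectable and the standard-vs-rank AIC ordering is exercised
in the direction of interest — not estimates of any real data.

The ANC-like preset (n = 943, p = 43) adds one tight block of 16 covariates
at ρ = 0.8 with three looser blocks at 0.3, mixed 2–5-level predictors, and
a skewed response (12 / 36 / 52 %) labelled inadequate / intermediate /
adequate, mirroring the reported distribution of antenatal-care attendance.

What the generator does **not** emulate: real survey data have non-Gaussian
dependence, informative missingness, survey weights, interactions, and
categorical (non-ordinal) factors. Passing tests on this generator show the
algorithms behave as specified under a controlled ordinal-multicollinear
model; they do not certify performance on any particular survey.

A note on the simulation comparison: at C = 1 the weight vector is the
whole model, so the AIC contrast between weight variants is sharpest there;
from C = 2 on, deflation lets the covariance weight recover from its
scale-induced misallocation and the variants converge. The replication
study therefore compares single-component fits.

## Numerical conventions and edge cases

* Tolerances: 1e−12 to stop component extraction; 1e−8 is the documented
  agreement level for score orthogonality, deflation reconstruction and
  OLS limits.
* Rows with missing cells are dropped at ingestion with a logged count;
  non-numeric cells are a format error naming row and column.
* A constant response refuses to fit; constant predictor columns get zero
  weight and a warning.
* Model serialization is JSON (exact round trip of all arrays via decimal
  repr of float64).

## Problem sizes used by the checks

The acceptance script runs the simulation AIC study at full design size
(10 replicates of 1000×100), the complete 36-cell grid on the 943×43
ANC-like data with 10 iterations, a 50-replicate chance-level calibration
at n = 300, one 200×2000 SMC null calibration, and a 30-replicate recovery
study — a few minutes end to end on one CPU. The test suite repeats the
same properties at reduced sizes chosen to keep the whole suite under a
minute except for the full-size replication tests.
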