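# Methods

## Designs and coding

Factors are handled in coded units: `coded = (natural − center)/step`, where
for three-level factors the step is the (required-equal) spacing between
adjacent levels, and for two-level screening factors the center is the
low/high midpoint. Coding makes design columns orthogonal and coefficients
directly comparable across factors; `uncode` inverts it exactly.

The 12-run Plackett–Burman design is built by cyclic rotation of the standard
11-element generator row `(+ + − + + + − − − + −)` plus a closing all-−1 row.
The generator is a convention choice — any rotation/relabeling gives an
equivalent orthogonal design, and the original study does not state which one
its software used; we fix this one for reproducibility and default to
generator order (no run randomization). Columns not assigned to real factors
are kept as *dummy* columns: on an orthogonal two-level design their
"effects" estimate pure noise, so the screening ANOVA pools them into the
residual.

The three-factor Box–Behnken design places 12 edge-midpoint runs (each factor
pair at its four ±1 combinations, third factor at 0) plus replicated center
runs. With the default five center points the run order matches the packaged
17-run table row-for-row so fixtures align; for other center counts, edge
runs come in lexicographic pair order.

## Desirability scoring

Each response is min–max normalized over the analyzed runs (Hassan's method):
`d = (y − ymin)/(ymax − ymin)` for maximized responses, `d = (ymax − y)/(ymax
− ymin)` for minimized ones, so `d_max + d_min = 1` identically. Extremes are
the observed per-column extremes of the design itself, not user bounds: this
makes OD = 1 mean "best in every column among these runs" and forces OD = 0
for any worst-in-a-column run. The composite score is the geometric mean
`OD = (∏d)^(1/k)`, computed as `exp(mean(log d))` with an explicit zero
short-circuit (no epsilon flooring — zeros are informative). The study's
score uses k = 4: particle size minimized; zeta potential, encapsulation
efficiency and drug loading maximized. The polydispersity index is not part
of the score (the source experiment did not tabulate it per run).

## Quadratic response-surface fit and ANOVA

The full second-order model (1 + m linear + m(m−1)/2 interaction + m squared
terms) is fit by OLS (statsmodels). Model-matrix column order is fixed:
intercept, linear, lexicographic interactions, squares. R² and adjusted R²
come from the SS decomposition; CV% = 100·√MS_residual / ȳ.

Per-term sums of squares are **partial (type III)**: the increase in residual
SS when that single column is dropped from the full model. On a Box–Behnken
design the linear and interaction columns are mutually orthogonal, so their
partial SS coincide with the contrast SS (`SS(Xᵢ) = 8bᵢ²` with 17 runs) — a
cross-check the tests enforce at 1e−10 — while squared terms are correlated
with the intercept and genuinely need the drop-one computation.

Residual variation splits into **pure error** (within-group SS over
replicated coded runs — here the five center points, 4 df) and **lack of
fit** (the remainder, 3 df); `F = MS_LOF / MS_PE` tests model adequacy.
p-values are upper-tail F probabilities with no multiplicity correction,
matching standard DoE-software reporting. Degenerate inputs are handled
explicitly: unreplicated designs omit the split with a warning; zero pure
error (exact replicates) leaves the lack-of-fit F undefined rather than
dividing by zero.

## Optimization of the fitted surface

The stationary point solves the linear system `H x = −b_linear` with
`H = 2 diag(bᵢᵢ) + interactions`. If it lies in the coded cube [−1, 1]^m and
H is definite in the goal's direction (eigenvalue signs at tolerance 1e−10),
it is the interior optimum; otherwise a vectorized dense grid over the cube
(default step 0.01) seeds a bounded L-BFGS-B polish and the result is
classified as a boundary optimum (or saddle-fallback when H is singular).
Natural-unit optima are reported raw and rounded half-away-from-zero to a
per-factor reporting step (default 0.1 in each factor's units) — the
convention by which a stationary point at (1.974 mg/mL, 2.258 mg/mL, ratio
1.455) is quoted as (2, 2.3, 1.5). Predicted response is always the model
value at the *unrounded* coded optimum.

## Plackett–Burman screening ANOVA

Per response: effect = mean(y at +1) − mean(y at −1); `SS = N·effect²/4`
(= 3·effect² at N = 12); residual SS = total − Σ factor SS, i.e. the dummy
columns' variation pooled, on `11 − n_factors` df; `F = SS/MS_residual`,
p from F(1, df_residual). Effects equal exactly twice the OLS slopes on the
same design (tested). With six factors the test has 5 residual df. Constant
responses yield all-zero effects and undefined (not significant) F ratios.

## Release kinetics

Cumulative release uses the standard replacement-sampling correction
`Qₙ = 100·(CₙV + v·Σ_{i<n}Cᵢ)/m`; the formula is a field convention (the
source text does not print one). Values above 100% warn but are not clipped —
silent clipping hides calibration errors.

All four model families are fit by nonlinear least squares
(scipy `curve_fit`) on the untransformed Q scale, so their R² values are
comparable. Initialization uses each model's linearization (first-order:
regression of `log(1 − Q/Q∞₀)` on t with `Q∞₀ = 1.05·max(Q)`; power law:
log–log regression), excluding t = 0 points. First-order Q∞ is bounded in
(0, 100]; rate and shape parameters are bounded positive. The Higuchi model
carries an additive intercept by default (matching how such fits are usually
quoted), with an intercept-free variant by flag; at n = 0.5 the power law and
the intercept-free Higuchi model coincide, which the tests verify via
identical SSE. Model selection takes the highest R², breaking ties (within
1e−9) toward the earlier entry of the fixed order zero-order → first-order →
Higuchi → power law, i.e. toward the structurally simpler family; this
returns Higuchi rather than the power law on exact square-root data.

## Synthetic generators

All generators are pure functions of (parameters, seed) via numpy's
`default_rng`; determinism is tested. The BBD generator evaluates a known
quadratic on the coded design and adds i.i.d. Gaussian noise; its default
noise sd 0.154 is the root residual mean square of the packaged 17-run
experiment, so simulated power and interval coverage resemble the real
study. The PBD generator adds half-effect multiples of the coded columns
plus noise. The release generator evaluates a named model family on the
dialysis grid (0, 0.25, 0.5, 0.75, 1, 2, 4, 6, 8, 12, 24, 48 h), truncates
*noisy* values into [0, 100] (noiseless model values pass through exactly so
generate→fit round trips are exact), optionally pins Q(0) = 0 and optionally
monotonizes. Real data differ in ways the generators do not emulate —
replicate-level measurement structure (the study reports triplicate means),
serially correlated release errors, and any response-surface misspecification
— so passing synthetic tests demonstrates correctness of the estimators
under their assumed models, not robustness to those violations.

## Reproducibility of the published tables from printed data

The packaged 17-run table prints responses to 1–2 decimals and OD to 4; the
original analysis ran on unrounded raw data. Consequences, quantified in the
test suite:

* Recomputing OD from the printed response columns reproduces the structural
  entries exactly (OD = 1.0000 for the best-in-all-columns center run, OD = 0
  for the two worst-in-a-column runs) and the full column to ≤ 2e−3 — the
  bound implied by propagating the print rounding — but not to 4 decimals on
  every row (max deviation 1.3e−3).
* Fitting on the printed OD column reproduces the published regression
  coefficients to within 1e−4 and the published ANOVA SS, df and p values to
  print precision; the published per-term F ratios (e.g. 6.2236 for X1) are
  not derivable even from the published SS themselves (0.1483/(0.1668/7) =
  6.2239) and agree with recomputation only to ~0.25% relative.
* The published scalar trio R² = 0.9467, adjusted R² = 0.7495, CV% = 2.86 is
  mutually inconsistent with the published ANOVA table, which implies
  R² = 0.847, adjusted R² = 0.649, CV% = 28.6; this package reports the
  values consistent with the SS decomposition.

Two strict print-precision tests in `tests/test_acceptance.py` are expected
to fail for the quantities in the first and second bullets that require
unrounded source data; they are kept strict deliberately, with the attainable
bounds asserted alongside.

## Problem sizes

The Monte-Carlo validations use 2000 simulated screening tables (null
calibration), 200–500 replicates for power and interval coverage, and 100
noisy replicates for kinetic model selection — sizes at which binomial
standard errors are several times smaller than the asserted tolerance bands.
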