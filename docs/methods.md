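# Methods

This note records the statistical model, the estimation and testing
procedures, the simulator that defines the package's study conditions, and
the numerical choices that were genuinely open.

## Model and item-fit statistic

Responses `U_ij ∈ {0, 1, missing}` of person `j` to item `i` follow the 2PL
under the hypothesized model: `P_i(θ) = logit⁻¹(a_i(θ − b_i))` with slope
`a_i > 0` and difficulty `b_i`, abilities `θ ~ N(0, 1)`, and conditional
independence of items given `θ`. Internally the slope–intercept form
`logit P = a θ + c`, `c = −ab`, is used for estimation and for posterior
draws; the slope–difficulty form is the user-facing convention.

The latent continuum is discretized on a quadrature grid, by default 81
equally spaced points on [−4, 4], with weights `φ_q` equal to the
standard-normal density normalized to sum to one. The same grid serves
calibration and item-fit analysis.

**Pseudocounts.** After calibration, person `j`'s posterior over the grid,
`x_jq ∝ φ_q · Π_{i observed} P_i(X_q)^{u_ij}(1 − P_i(X_q))^{1−u_ij}`,
normalized to sum to one, is that person's unit pseudocount vector. Per
item, the vectors of persons answering correctly (incorrectly) accumulate
into `s1_iq` (`s0_iq`); persons missing item `i` contribute to neither, so
each item's pseudocount mass conserves its valid-response counts exactly.
The observed response curve is `p_iq = s1_iq / (s1_iq + s0_iq)`; a guard
constant 0.001 enters the denominator only where the total mass is below
1e-10, which defines `p = 0` at unoccupied tail points. (The trigger
threshold is a design choice; the guard is needed only to keep `p`
identified where no respondent has posterior mass.)

**RMSD.** `RMSD_i = sqrt(Σ_q φ_q (p_iq − Π_iq)²)`, with the density
weights. The square root is part of the definition here: it puts the index
on the probability scale, which is the scale on which the population misfit
sizes (up to ≈ 0.13) and all reference values (0.01–0.05) live. The
weight vector is a pluggable argument (e.g., uniform weights), but the
normalized population density is the default and the only weighting used by
the calibration studies.

## Estimation

`fit_2pl` implements Bock–Aitkin EM on the fixed grid: the E-step computes
all persons' posteriors and the per-item expected category counts (the
E-table); the M-step maximizes each item's expected complete-data binomial
log-likelihood over `(a, c)` by damped 2×2 Newton iterations with
step-halving, which keeps the marginal log-likelihood nondecreasing.
Missing responses simply drop out of the person likelihood. Convergence is
declared when the largest parameter change falls below `tol = 1e-4`
(at most 500 cycles); starting values are `a = 1` and `c = logit` of the
clipped item proportion correct. These settings are package choices —
standard practice, and tight enough that halving `tol` moves no reported
quantity at the precisions used. Items with all-correct or all-incorrect
valid responses are inestimable and raise a named error.

**Parameter covariance.** The PP-PPMC machinery needs the sampling
covariance of all `2n` item parameters. The default computes the observed
information of the marginal log-likelihood *analytically* via Louis'
identity — complete information minus missing information, assembled from
per-person posterior moments in `O(Q N n²)` — and inverts it. A
central-difference Hessian (`method="numerical"`, small problems only) and
an outer-product-of-gradients estimate (`method="opg"`) sit behind the same
interface; the tests cross-check the analytic Hessian against the numerical
one (agreement ≈ 1e-5 relative) and against an exact Fisher-information
oracle obtained by enumerating all response patterns of a 3-item test.
If the information matrix is not positive definite, the smallest diagonal
ridge restoring definiteness is added and logged.

## PP-PPMC

The parameter posterior is approximated by `MVN(ω̂, Cov(ω̂))` on the
slope–intercept scale. For each of `L = 100` draws `ω_l` (draws containing
a slope ≤ 0.05 are rejected and redrawn, so every drawn curve is
increasing):

1. the *realized* discrepancy is the RMSD of the observed data with both
   pseudocounts and expected curves evaluated at `ω_l` (the discrepancy is
   a function of the drawn parameters, not of the MLE);
2. a replicate dataset is simulated under `ω_l` with fresh `N(0,1)`
   abilities and the *observed missingness mask copied verbatim*, keeping
   the reference distribution comparable to the observed design; its RMSD
   at `ω_l` is the *predictive* discrepancy;
3. `PPP_i` is the proportion of draws with predictive > realized, ties
   counting as non-exceedance; `PPP_i < α` (default 0.05, strict) flags
   item `i`.

## The misfit simulator

The simulator defines the package's study conditions; its defaults are not
tuning knobs.

*Fitting items*: slopes lognormal with log-mean 0 and log-variance 0.5,
truncated by redraw to [0.25, 4.00] — exactly the 2.5th/97.5th percentiles
of that distribution — and difficulties `N(0, 1)` truncated to
[−1.96, 1.96].

*Misfitting items*: the LMPA family
`P(θ) = g + (1 − g) logit⁻¹(δ + f(θ))`, where `f` is the odd polynomial of
order `2k+1` with derivative
`exp(ω) Π_s (1 − 2α_s θ + (α_s² + exp(τ_s)) θ²)`; each quadratic factor has
discriminant `−4 exp(τ_s) < 0`, so every member is strictly monotone. The
coefficients follow by expanding this derivative and integrating term-wise
with `f(0) = 0` (for `k = 1`: `b = (e^ω, −e^ω α, e^ω(α² + e^τ)/3)`). For
`k = 0` the family is the 3PL with slope `exp(ω)`.

A deterministic preliminary analysis enumerates
`k=0`: g ∈ {0.1, 0.2, 0.3} × ω at the nine exact N(0,1) deciles × δ from
−1.6 to 1.6 by 0.4 (243 combinations), and
`k=1`: g ∈ {0, 0.1, 0.2, 0.3} × ω(9) × δ(9) × α from −0.99 to 0.99 by 0.22
× exp(τ) from 0.01 to 1.21 by 0.2 (22,680 combinations). (`exp(ω)` at the
deciles spans 0.278–3.602.) For each combination the best density-weighted
2PL approximation is found by weighted least squares on the probability
scale (multi-start damped Gauss–Newton, vectorized across combinations;
verified against a brute-force grid search). Combinations whose fitted
slope leaves the ±2 SD log-scale box `|log a| ≤ 2√0.5` or whose fitted
difficulty leaves [−2, 2] are discarded as implausible; of the rest, those
with **population RMSD** (the minimized weighted deviation, an
estimation-error-free effect size) above 0.05 form the misfit pool —
7,705 combinations, with the box-filtered population RMSD spanning
0.001–0.129 (mean 0.047, SD 0.021). The loss scale (probability, not logit
or KL) is a sensitivity point: the pool boundary shifts slightly under
other losses, which is why the exact pool count is treated as an
order-of-magnitude check only.

*Datasets*: `round(prop_misfit × n)` items (ties to even) are drawn
uniformly from the pool and placed at random positions; abilities are
`N(0,1)`; responses Bernoulli from each item's true curve. Missingness
removes an exact count `round(prop × n)` of responses per person, chosen
uniformly without replacement — matching designs that impose a fixed
missing share per person — with regeneration (up to 10 attempts) if an
item would lose a whole response category.

What the generator does *not* emulate: multidimensionality, local
dependence, non-normal ability distributions, nonmonotone misfit, or
informative (MNAR) missingness. Passing tests therefore speak to the
method's behavior under clean unidimensional data with random missingness,
not to robustness against those violations.

## Reference values

For a given `(N, n)`, per-item RMSDs from replicated null (2PL-generated)
and misfit (LMPA-generated) items are pooled; candidate thresholds form an
arithmetic grid of step 0.001 spanning the observed range; an item is
flagged when RMSD ≥ threshold (the ≥ is a determinism choice, immaterial at
grid resolution). The recommended reference value is the lower bound of the
contiguous threshold interval maximizing Youden's `J = Se + Sp − 1` — the
lower bound because missingness shrinks misfit RMSDs while leaving null
RMSDs stable, so the low end protects sensitivity. If several disjoint
regions tie (possible in small samples), the lowest threshold is
recommended and the discontinuity reported. The Euclidean-distance
criterion `min (1−Se)² + (1−Sp)²` is available as an alternative objective
for comparison, but Youden is the default because it directly maximizes
the correct-classification rate.

Optimized cutoffs depend strongly on `N` and `n`, so a polynomial
regression (response surface) interpolates them: candidate predictor sets
range from `{√n, √N}` to `{√n, √N, n, N, n^{3/2}, N^{3/2}}` plus one
interaction, and the set with the highest adjusted R² is selected. The
shipped default model (id 4, predictors `√n, √N, n, N, n^{3/2}, N^{3/2}`,
adjusted R² 0.942) carries the published coefficients, stored at full
precision; `predict_reference_value` evaluates it, floors negative
extrapolations at zero with a warning, and reports at the 3-decimal
precision used for cutoffs. Refitting this model from a user's own
simulated cutoffs goes through `fit_surface_model`/`select_surface_model`.

## Problem sizes used by tests and the acceptance script

The benchmark quantities are recomputed at reduced replication counts,
chosen so that Monte Carlo error stays within the comparison tolerances:
PP-PPMC power from 5 replications of (N=5,000, n=100, 5% misfit, L=100);
Youden cutoffs from 10 replications at (5,000, 100) and 200 at (500, 20);
RMSD magnitudes from 5 replications at (10,000, 100), with the same
datasets refitted after removing 80 of each person's 100 responses. The
original studies used replication counts 10–100× larger; at the reduced
scale the binomial/MC standard errors (≈ 0.001–0.003 for the means and
cutoffs) are the dominant source of disagreement.

## Known limitations

* Calibration supports the 2PL only; the 3PL appears solely as a
  data-generating model (`k = 0` LMPA). Polytomous items are out of scope.
* The normal posterior approximation underlying PP-PPMC degrades for very
  small samples (a few hundred persons), where its draws can include
  near-boundary slopes; rejection keeps draws valid but a rejection rate
  above 50% triggers a warning that the approximation is strained.
* Reference values optimized for model-fit screening do not transfer to
  DIF/measurement-invariance uses of the RMSD.
* EM convergence slows markedly for ill-identified items (slopes near the
  truncation floor with extreme difficulties); the `converged=False` path
  returns the last iterate with a warning rather than failing.
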