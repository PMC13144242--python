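# Methods

## Model

The data-generating and fitted model is a linear latent growth model for a
latent response `y*_it = eta_0i + eta_1i lambda_t + e_it`, observed only
through `y_it = c` iff `tau_c < y*_it <= tau_{c+1}` with occasion-invariant
thresholds. Loadings are `lambda_t = t - 1` over `T = 4` occasions. The
implied moments are the standard linear-growth forms (see README); all
moment algebra lives in `catlgm.model` and is shared by the generator and
the estimator's truth values.

## Scaling calculus (`catlgm.scaling`)

Per-occasion z-scale thresholds are normal quantiles of cumulative category
proportions. Unit lengths: ordinal variables use the gap between two
thresholds (default: the first two; any pair can be selected), binary
variables use `w_t = sqrt(1/(p_t(1-p_t)))`, the inverse Bernoulli SD. A
common scale anchors the first threshold at 0 and the first occasion at
`sqrt(s*) = 1`; conservation `w_t sqrt(s*_t) = w` then gives
`sqrt(s*_t) = w_1 / w_t` and `ybar*_t = -sqrt(s*_t) tau^z_{1,t}`. This
mirrors the delta parameterization used in estimation (first-occasion
variance fixed). Degenerate proportions (a cumulative proportion of 0 or 1)
raise `DegenerateCategoryError` rather than being clipped, so the study
layer can count them as difficulties.

A note on one published worked value: for a 70% first-category rate the
binary unit is sometimes quoted as 4.76, which equals `1/(p(1-p))`; the
defining formula with the square root gives `sqrt(1/0.21) = 2.18`. The
package implements the square-root form throughout, which is the one
consistent with `w` being an inverse standard deviation.

## Synthetic data (`catlgm.simulate`)

Latent trajectories are drawn directly from the implied multivariate normal
(mean vector from the pattern/slope cell, covariance from
`psi_00 = 0.5, psi_11 = 0.1, psi_10 = 0, theta = (0.5, 0.6, 0.9, 1.4)`),
which is distributionally identical to composing factor draws and errors.
Discretisation uses thresholds 0 (binary), ±0.83 (3 categories),
(±1.25, 0) (4 categories); a value exactly at a cut goes to the upper
category (probability-zero tie, fixed for determinism). The design emulates
panels whose response rates drift over time in three patterns (shift /
increase / decrease) at slope means 0.40 and 0.10 and N ∈ {100, 200, 1000}
— 54 cells. What the generator does **not** emulate: missing data,
non-linear growth, time-varying thresholds, non-normal latent
distributions; passing tests therefore say nothing about robustness to
those features of real data.

Seeding: each (condition, replicate) pair gets an independent
`SeedSequence(entropy=base_seed, spawn_key=(pattern, slope, C, N, rep))`
stream, so any replicate is reproducible in isolation and results are
independent of execution order and worker count.

## Estimation (`catlgm.moments`, `catlgm.estimator`)

Stage 1: probit thresholds per occasion. Stage 2: pairwise polychoric
correlations by scalar ML with stage-1 thresholds fixed; rectangle
probabilities use an exact Owen's-T bivariate normal CDF (`catlgm.bvn`,
validated against scipy's generic MVN integrator to ~1e-9) and Plackett's
identity supplies the score. Estimates pinned at |rho| = 0.999 are flagged
as boundary cases and make the replicate a difficulty.

Diagonal weights are the estimated asymptotic variances of the stacked
statistics: binomial delta method for thresholds
(`p(1-p)/(n phi(tau)^2)`), and for each polychoric the full two-stage
influence-function variance — the ML score term plus propagation of the
threshold noise, with curvatures obtained through the information equality.
The polychoric variance was validated against the empirical sampling
variance of the two-stage estimator (agreement within ~2% at n = 500 for
tetrachoric and 3x3 cases). Entries that come out non-positive fall back to
unit weights with a warning.

Stage 3 minimises `(s - sigma(theta))' W^{-1} (s - sigma(theta))` by
L-BFGS-B on the transformed vector `[tau_1, log-gaps, alpha_10, psi_00,
psi_10, psi_11, log Delta_2..T]`. The mean structure is identified by fixing
`alpha_00 = 0` with free invariant thresholds (the reported slope parameters
are unaffected); `Delta_1 = 1`. Convergence tolerances: gradient 1e-8,
relative f 1e-12, 500 iterations, with up to three deterministic perturbed
restarts. Box bounds (|tau|, |coefficients| ≤ 6; log Delta ∈ ±2.5) are
generous relative to any plausible latent scale; a solution pinned at a
bound is a runaway on the weak-identification ridge that binary data can
produce and is classified **nonconverged**.

Solution classification: `improper` when a factor variance is negative, the
factor covariance is non-PSD, or any implied residual variance
`1/Delta_t^2 - (psi_00 + 2 lambda_t psi_10 + lambda_t^2 psi_11)` is
negative (the Heywood case — the inadmissible-solution warning SEM software
raises). `degenerate` when an empty category makes the statistics
undefined. Relative bias and RMSE aggregate over converged proper
replicates by default (`include_improper` switches the denominator), since
that is the only definition under which high-difficulty cells can report
estimates at all.

## Design choices that were genuinely open

* **Ordinal unit pair**: with 4+ categories any threshold pair could define
  the unit; the first two are used (matching the two-threshold anchoring
  convention), exposed as an option.
* **Improper definition**: the Heywood residual-variance check is included
  alongside the factor-covariance checks; without it, rare drifted binary
  solutions (slope estimates 2-4x the truth with collapsed scale factors)
  count as converged and dominate the bias at N = 1000.
* **Difficulty rates are implementation-specific**: convergence criteria of
  proprietary software cannot be replicated exactly, so difficulty
  percentages are comparable only directionally (binary >> ordinal in
  small-slope cells); the package reports degenerate-data counts separately
  from optimizer failures.
* **Two-stage, not joint**: polychorics condition on stage-1 thresholds;
  the weights account for that conditioning explicitly.

## Problem sizes

Unit and property tests run at n ≤ 5000 in seconds. The Monte Carlo
reproduction tests and `scripts/acceptance.py` use 200 replicates per
condition — the package's desk-scale default, with the Monte Carlo standard
error of every relative-bias estimate reported next to it so that
tolerances remain principled at reduced replication counts. The full
54-condition, 1000-replicate study runs via `catlgm run --reps 1000` in a
few hours on one CPU.

## Known limitations

* Point estimation only: no chi-square/fit statistics (the mean-and-
  variance adjustment of WLSMV affects test statistics, not estimates), no
  standard-error calibration.
* Delta parameterization only (no theta parameterization), probit link only.
* Binary difficulty/bias figures depend on the convergence and
  admissibility rules above; they reproduce the qualitative and most
  quantitative findings, but difficulty rates are not expected to match any
  other implementation cell by cell.
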