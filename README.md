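# catlgm

Latent growth models (LGMs) for **categorical** longitudinal data — and the
scaling reason why *binary* indicators behave fundamentally worse than
*ordinal* ones.

## The problem

A categorical LGM models an observed ordinal or binary response `y_it` as a
coarsened version of a continuous latent response `y*_it` following a linear
growth trajectory

    y*_it = eta_0i + eta_1i * lambda_t + e_it,

with growth-factor means `(alpha_00, alpha_10)`, covariances
`(psi_00, psi_11, psi_10)`, loadings `lambda_t = t - 1` and error variances
`theta_t`, so that

    mu*_t     = alpha_00 + alpha_10 * lambda_t
    sigma*_t  = psi_00 + 2 lambda_t psi_10 + lambda_t^2 psi_11 + theta_t
    sigma*_tu = psi_00 + (lambda_t + lambda_u) psi_10 + lambda_t lambda_u psi_11.

Because `y*` has no metric, every occasion's scale must be fixed from
observed quantities. With 3+ categories, two thresholds fix origin *and*
unit, and the unit is independent of the origin. With binary data there is
one threshold, and the unit has to come from the Bernoulli standard
deviation: `w_t = sqrt(1 / (p_t (1 - p_t)))` — a deterministic function of
the response rate itself. Propagating either unit across occasions under
threshold invariance (`w_t * sqrt(s*_t) = w`) shows that the binary
common-scale SDs are distorted whenever response rates trend over time,
which biases binary growth-model estimates in ways ordinal ones escape.

`catlgm` implements, from the ground up:

* **`catlgm.scaling`** — the observed-scale-reference calculus: z-scale
  thresholds from category proportions, binary/ordinal unit lengths,
  common-scale SDs (`sqrt(s*_t) = w_ref / w_t`) and means
  (`ybar*_t = tau_anchor - sqrt(s*_t) tau^z_t`);
* **`catlgm.simulate`** — synthetic panels from the growth model's implied
  multivariate normal, discretised at fixed thresholds (the 54-condition
  design: 3 change patterns x 2 slope levels x 2/3/4 categories x
  N in {100, 200, 1000});
* **`catlgm.moments` / `catlgm.estimator`** — two-stage estimation
  (probit thresholds, pairwise polychoric ML on an Owen's-T bivariate
  normal kernel, influence-function asymptotic variances) and the
  diagonally weighted least squares fit under the delta parameterization
  (`Delta_1 = 1`, scale factors `Delta_t = 1/sd(y*_t)` free);
* **`catlgm.study`** — the Monte Carlo driver: difficulty classification
  (non-convergence, improper/Heywood solutions, degenerate data), relative
  bias and RMSE per condition, and paper-style report tables.

## Worked example

```sh
python examples/generate_and_fit.py
```

```
panel: 1000 subjects x 4 occasions, 3 categories
...
status: converged (discrepancy 2.438)
slope mean      alpha10 = 0.426   (true 0.4)
slope variance  psi11   = 0.124   (true 0.1)
scale factors   Delta_t = [1.    0.937 0.697 0.597]   (true [1.    0.913 0.745 0.598] )
```

The fit recovers the slope mean, slope variance and the inverse-SD scale
factors of a 1000-subject ordinal panel. `examples/scale_divergence.py`
prints the scaling asymmetry itself (ordinal common-scale SDs flat at 1,
binary humped at 1.369), and `examples/mini_study.py` runs a 50-replicate
binary-vs-ordinal comparison:

```
shift-small-c2-n200: difficulties 42.0% (converged 29/50)
   RB(alpha10) = +0.357 +- 0.163 (MC SE)
shift-small-c3-n200: difficulties 8.0% (converged 46/50)
   RB(alpha10) = +0.021 +- 0.064 (MC SE)
```

A thin CLI covers the same flows:

```sh
catlgm generate --pattern shift --slope large --categories 2 --n 200 --seed 42 --out panel.csv
catlgm fit --panel panel.csv
catlgm run --grid full --reps 200 --seed 7 --out results/
catlgm report results/
```

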