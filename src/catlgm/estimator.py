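"""Diagonally weighted least squares fit of the categorical growth model.

The structural model is fitted to the stage-1/2 statistics (thresholds and
polychoric correlations) under the delta parameterization: scale factors
``Delta_t`` — the inverse standard deviations of the latent responses — are
free parameters for t >= 2 with ``Delta_1`` fixed at 1.  Free parameters:

* invariant thresholds tau_c (C - 1), with the intercept mean alpha00 fixed
  at 0 for mean-structure identification,
* slope mean alpha10,
* growth-factor covariances psi00, psi10, psi11 (unconstrained, so improper
  solutions with negative variance estimates can occur and be detected),
* log Delta_t for t >= 2 (positivity enforced by the log transform).

Implied statistics:

    tau*_{c,t}  = Delta_t * (tau_c - alpha10 * lambda_t)
    rho*_{tu}   = Delta_t * Delta_u * (psi00 + (lambda_t + lambda_u) psi10
                                       + lambda_t lambda_u psi11)

and the fit minimises (s - sigma(theta))' W^{-1} (s - sigma(theta)) with W
the diagonal of estimated asymptotic variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import GrowthSpec, implied_moments, population_z_thresholds
from .moments import SampleMoments, sample_moments
from .simulate import CategoricalPanel, ThresholdSet

__all__ = [
    "LgmModelSpec",
    "LgmFit",
    "FitOptions",
    "model_implied_statistics",
    "fit_dwls",
    "fit_panel",
    "analytic_sample_moments",
]


@dataclass(frozen=True)
class LgmModelSpec:
    """Shape of the fitted model: occasions, loadings and category count."""

    n_times: int
    n_categories: int
    loadings: tuple[float, ...] = None

    def __post_init__(self):
        if self.n_times < 2 or self.n_categories < 2:
            raise ValueError("need T >= 2 and C >= 2")
        loadings = self.loadings
        if loadings is None:
            loadings = tuple(float(t) for t in range(self.n_times))
        else:
            loadings = tuple(float(v) for v in loadings)
            if len(loadings) != self.n_times:
                raise ValueError("loadings length must equal n_times")
        object.__setattr__(self, "loadings", loadings)

    @property
    def n_parameters(self) -> int:
        return (self.n_categories - 1) + 1 + 3 + (self.n_times - 1)

    @property
    def n_statistics(self) -> int:
        return self.n_times * (self.n_categories - 1) + self.n_times * (self.n_times - 1) // 2


@dataclass(frozen=True)
class FitOptions:
    max_iter: int = 500
    gtol: float = 1e-8
    ftol: float = 1e-12
    n_starts: int = 4
    # box constraints on the transformed parameter vector, generous relative
    # to any plausible latent-response scale: |tau|, |alpha10|, |psi| <= 6,
    # log-gaps in [-4, 2.5], log Delta in [-2.5, 2.5].  A solution pinned at
    # a bound is a runaway, not an estimate, and is classified nonconverged.
    tau_bound: float = 6.0
    coef_bound: float = 6.0
    log_gap_bounds: tuple[float, float] = (-4.0, 2.5)
    log_delta_bound: float = 2.5


@dataclass(frozen=True)
class LgmFit:
    """Point estimates and convergence status of one model fit."""

    tau: np.ndarray
    alpha10: float
    psi00: float
    psi11: float
    psi10: float
    deltas: np.ndarray          # length T, deltas[0] == 1
    status: str                 # converged | nonconverged | improper
    iterations: int
    discrepancy: float
    spec: LgmModelSpec = field(repr=False, default=None)

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    @property
    def factor_cov_psd(self) -> bool:
        return (
            self.psi00 >= 0
            and self.psi11 >= 0
            and self.psi00 * self.psi11 - self.psi10 ** 2 >= -1e-12
        )

    def estimates(self) -> dict:
        out = {f"tau_{c + 1}": float(v) for c, v in enumerate(self.tau)}
        out.update(
            alpha10=float(self.alpha10),
            psi00=float(self.psi00),
            psi11=float(self.psi11),
            psi10=float(self.psi10),
        )
        out.update({f"delta_{t + 1}": float(v) for t, v in enumerate(self.deltas)})
        return out

    def to_text(self) -> str:
        """Flat key=value serialization for the simulation driver / CLI."""
        lines = [f"status={self.status}", f"iterations={self.iterations}",
                 f"discrepancy={self.discrepancy!r}"]
        lines += [f"{k}={v!r}" for k, v in self.estimates().items()]
        return "\n".join(lines) + "\n"


def model_implied_statistics(
    spec: LgmModelSpec,
    tau: np.ndarray,
    alpha10: float,
    psi00: float,
    psi10: float,
    psi11: float,
    deltas: np.ndarray,
) -> np.ndarray:
    """Implied stacked statistics (thresholds time-major, then correlations).

    ``deltas`` must be length T with ``deltas[0] == 1`` and all entries
    positive; at t = 1 the implied thresholds reduce to tau_c - mu*_1 = tau_c.
    """
    lam = np.asarray(spec.loadings)
    deltas = np.asarray(deltas, dtype=float)
    if deltas.shape != (spec.n_times,) or abs(deltas[0] - 1.0) > 1e-12:
        raise ValueError("deltas must be length T with deltas[0] = 1")
    if np.any(deltas <= 0):
        raise ValueError("scale factors must be positive")
    mu = alpha10 * lam
    tau = np.asarray(tau, dtype=float)
    thr = deltas[:, None] * (tau[None, :] - mu[:, None])
    cov = (
        psi00
        + np.add.outer(lam, lam) * psi10
        + np.outer(lam, lam) * psi11
    )
    iu = np.triu_indices(spec.n_times, k=1)
    rho = (np.outer(deltas, deltas) * cov)[iu]
    return np.concatenate([thr.ravel(), rho])


# ---------------------------------------------------------------------------
# parameter vector packing: [tau_1, log-gaps (C-2), alpha10, psi00, psi10,
# psi11, log Delta_2..T] — log-gaps keep thresholds ordered, log Deltas > 0.

def _pack(tau, alpha10, psi00, psi10, psi11, deltas) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    gaps = np.diff(tau)
    return np.concatenate(
        [[tau[0]], np.log(gaps), [alpha10, psi00, psi10, psi11], np.log(deltas[1:])]
    )


def _unpack(x: np.ndarray, spec: LgmModelSpec):
    cm1 = spec.n_categories - 1
    tau = np.empty(cm1)
    tau[0] = x[0]
    if cm1 > 1:
        tau[1:] = tau[0] + np.cumsum(np.exp(x[1:cm1]))
    alpha10, psi00, psi10, psi11 = x[cm1 : cm1 + 4]
    deltas = np.concatenate([[1.0], np.exp(x[cm1 + 4 :])])
    return tau, alpha10, psi00, psi10, psi11, deltas


def _objective(x: np.ndarray, spec: LgmModelSpec, s: np.ndarray, w: np.ndarray) -> float:
    tau, a10, p00, p10, p11, deltas = _unpack(x, spec)
    implied = model_implied_statistics(spec, tau, a10, p00, p10, p11, deltas)
    r = s - implied
    val = float(np.sum(r * r / w))
    # keep implied correlations inside (-1, 1); smooth penalty lets the
    # optimizer retreat instead of raising on a non-PSD implied structure
    n_thr = spec.n_times * (spec.n_categories - 1)
    excess = np.abs(implied[n_thr:]) - 0.999
    if np.any(excess > 0):
        val += 1e3 * float(np.sum(np.maximum(excess, 0.0) ** 2))
    return val


def _start_values(moments: SampleMoments, spec: LgmModelSpec) -> list[np.ndarray]:
    """Deterministic start points: statistics-based defaults, then perturbations."""
    lam = np.asarray(spec.loadings)
    tau0 = moments.thresholds[0]
    # crude occasion means assuming Delta ~ 1
    mu = np.mean(tau0[None, :] - moments.thresholds, axis=1)
    denom = float(np.sum(lam * lam))
    a10 = float(np.sum(lam * mu) / denom) if denom > 0 else 0.0
    r = moments.correlations
    p00 = float(np.clip(r[0, 1], 0.05, 0.95))
    T = spec.n_times
    p11 = float(np.clip((r[T - 2, T - 1] - r[0, 1]) / max(lam[T - 2] * lam[T - 1], 1.0), 0.02, 0.5))
    base = _pack(tau0, a10, p00, 0.0, p11, np.ones(T))
    starts = [base]
    for scale_a, dlog in ((0.5, 0.2), (1.5, -0.2), (0.0, 0.0)):
        x = base.copy()
        cm1 = spec.n_categories - 1
        x[cm1] *= scale_a
        x[cm1 + 4 :] += dlog
        starts.append(x)
    return starts


def fit_dwls(
    moments: SampleMoments,
    spec: LgmModelSpec,
    options: FitOptions = FitOptions(),
) -> LgmFit:
    """Minimise the diagonally weighted least-squares discrepancy.

    Deterministic given the moments and options: start points are derived
    from the statistics, with fixed perturbed restarts before declaring
    non-convergence.  A converged solution with a negative factor variance
    (or a non-PSD factor covariance) is classified ``improper``.
    """
    s = moments.stacked
    w = np.asarray(moments.asymptotic_variances, dtype=float)
    cm1 = spec.n_categories - 1
    bounds = (
        [(-options.tau_bound, options.tau_bound)]
        + [options.log_gap_bounds] * (cm1 - 1)
        + [(-options.coef_bound, options.coef_bound)] * 4
        + [(-options.log_delta_bound, options.log_delta_bound)] * (spec.n_times - 1)
    )
    best = None
    n_iter = 0
    for x0 in _start_values(moments, spec)[: options.n_starts]:
        x0 = np.clip(x0, [lo for lo, _ in bounds], [hi for _, hi in bounds])
        res = minimize(
            _objective,
            x0,
            args=(spec, s, w),
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": options.max_iter,
                "gtol": options.gtol,
                "ftol": options.ftol,
            },
        )
        n_iter += int(res.nit)
        at_bound = any(
            x - lo < 1e-6 or hi - x < 1e-6 for x, (lo, hi) in zip(res.x, bounds)
        )
        if res.success and not at_bound:
            best = res
            break
    if best is None:
        # report the parameters anyway so failures can be inspected
        tau, a10, p00, p10, p11, deltas = _unpack(res.x, spec)
        return LgmFit(
            tau=tau, alpha10=a10, psi00=p00, psi11=p11, psi10=p10, deltas=deltas,
            status="nonconverged", iterations=n_iter, discrepancy=float(res.fun),
            spec=spec,
        )
    tau, a10, p00, p10, p11, deltas = _unpack(best.x, spec)
    status = "converged"
    if p00 < 0 or p11 < 0 or p00 * p11 - p10 ** 2 < -1e-12:
        status = "improper"
    else:
        # Heywood check: under the delta parameterization the implied total
        # variance of y*_t is 1/Delta_t^2, so the implied residual variance
        # is 1/Delta_t^2 minus the growth-structure variance; a negative
        # value is an inadmissible (improper) solution
        lam = np.asarray(spec.loadings)
        resid = 1.0 / deltas ** 2 - (p00 + 2 * lam * p10 + lam ** 2 * p11)
        if np.any(resid < 0):
            status = "improper"
    return LgmFit(
        tau=tau, alpha10=a10, psi00=p00, psi11=p11, psi10=p10, deltas=deltas,
        status=status, iterations=n_iter, discrepancy=float(best.fun), spec=spec,
    )


def fit_panel(
    panel: CategoricalPanel,
    options: FitOptions = FitOptions(),
) -> LgmFit:
    """Convenience wrapper: stage-1/2 statistics then the DWLS fit.

    Raises :class:`DegenerateCategoryError` on panels with empty categories;
    the simulation driver catches this and records a difficulty.
    """
    moments = sample_moments(panel)
    spec = LgmModelSpec(n_times=panel.n_times, n_categories=panel.n_categories)
    return fit_dwls(moments, spec, options)


def analytic_sample_moments(
    growth: GrowthSpec, thresholds: ThresholdSet, n: int = 1_000_000
) -> SampleMoments:
    """Exact population statistics in `SampleMoments` form (no sampling).

    Thresholds are the population z-scale cut points and the correlations the
    population latent correlation matrix; unit asymptotic variances are used
    since the fit residual is identically zero at the generating parameters.
    Useful as a parameter-identification oracle.
    """
    thr = population_z_thresholds(growth, thresholds.cuts)
    corr = implied_moments(growth).correlation
    spec = LgmModelSpec(
        n_times=growth.n_times,
        n_categories=thresholds.n_categories,
        loadings=growth.loadings,
    )
    return SampleMoments(
        thresholds=thr,
        correlations=corr,
        asymptotic_variances=np.ones(spec.n_statistics),
        n=n,
    )
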