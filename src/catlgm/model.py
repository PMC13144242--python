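"""Linear latent growth model: population parameters and implied moments.

The individual trajectory is ``y*_it = eta0_i + eta1_i * lambda_t + e_it``
with growth-factor means (alpha00, alpha10), covariance matrix
[[psi00, psi10], [psi10, psi11]], time-specific error variances theta_t and
loadings lambda_t (default t - 1).  The implied moments are

    mu*_t     = alpha00 + alpha10 * lambda_t
    sigma*_t  = psi00 + 2 lambda_t psi10 + lambda_t^2 psi11 + theta_t
    sigma*_tu = psi00 + (lambda_t + lambda_u) psi10 + lambda_t lambda_u psi11
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidSpecError

__all__ = [
    "GrowthSpec",
    "PopulationMoments",
    "implied_moments",
    "population_z_thresholds",
    "population_proportions",
    "population_polychoric",
    "true_deltas",
]


@dataclass(frozen=True)
class GrowthSpec:
    """Population parameters of a linear latent growth model."""

    alpha00: float
    alpha10: float
    psi00: float
    psi11: float
    psi10: float
    theta: tuple[float, ...]
    loadings: tuple[float, ...] = field(default=None)

    def __post_init__(self):
        theta = tuple(float(v) for v in self.theta)
        if len(theta) < 2:
            raise InvalidSpecError("need at least T = 2 time points")
        if any(v <= 0 for v in theta):
            raise InvalidSpecError("error variances must be positive")
        if self.psi00 < 0 or self.psi11 < 0:
            raise InvalidSpecError("factor variances must be non-negative")
        if self.psi00 * self.psi11 - self.psi10 ** 2 < -1e-12:
            raise InvalidSpecError("growth-factor covariance matrix is not PSD")
        loadings = self.loadings
        if loadings is None:
            loadings = tuple(float(t) for t in range(len(theta)))
        else:
            loadings = tuple(float(v) for v in loadings)
            if len(loadings) != len(theta):
                raise InvalidSpecError("loadings and theta must have equal length")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "loadings", loadings)

    @property
    def n_times(self) -> int:
        return len(self.theta)

    @property
    def factor_cov(self) -> np.ndarray:
        return np.array([[self.psi00, self.psi10], [self.psi10, self.psi11]])


@dataclass(frozen=True)
class PopulationMoments:
    """Implied per-time means and the full T x T covariance of y*."""

    means: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.means, dtype=float)
        c = np.asarray(self.covariance, dtype=float)
        if c.shape != (m.size, m.size):
            raise ValueError("covariance shape must match means length")
        if np.max(np.abs(c - c.T)) > 1e-12:
            raise ValueError("covariance must be symmetric")
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError as exc:
            raise InvalidSpecError("implied covariance is not positive definite") from exc
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "covariance", c)

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.covariance)

    @property
    def correlation(self) -> np.ndarray:
        sd = np.sqrt(self.variances)
        return self.covariance / np.outer(sd, sd)


def implied_moments(spec: GrowthSpec) -> PopulationMoments:
    """Model-implied means and covariance of the latent responses."""
    lam = np.asarray(spec.loadings)
    means = spec.alpha00 + spec.alpha10 * lam
    cov = (
        spec.psi00
        + np.add.outer(lam, lam) * spec.psi10
        + np.outer(lam, lam) * spec.psi11
    )
    cov = cov + np.diag(spec.theta)
    return PopulationMoments(means=means, covariance=cov)


def population_z_thresholds(spec: GrowthSpec, thresholds) -> np.ndarray:
    """Population z-scale thresholds (tau_c - mu*_t) / sd(y*_t), shape (T, C-1)."""
    mom = implied_moments(spec)
    tau = np.asarray(thresholds, dtype=float)
    sd = np.sqrt(mom.variances)
    return (tau[None, :] - mom.means[:, None]) / sd[:, None]


def population_proportions(spec: GrowthSpec, thresholds) -> np.ndarray:
    """Population category proportions per time, shape (T, C)."""
    from scipy.special import ndtr

    tz = population_z_thresholds(spec, thresholds)
    cum = np.concatenate(
        [np.zeros((tz.shape[0], 1)), ndtr(tz), np.ones((tz.shape[0], 1))], axis=1
    )
    return np.diff(cum, axis=1)


def population_polychoric(spec: GrowthSpec) -> np.ndarray:
    """Population correlation matrix of the latent responses."""
    return implied_moments(spec).correlation


def true_deltas(spec: GrowthSpec) -> np.ndarray:
    """Population scale factors under the delta parameterization with the
    first occasion as reference: Delta_t = sqrt(sigma*_1 / sigma*_t)."""
    v = implied_moments(spec).variances
    return np.sqrt(v[0] / v)
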