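"""Stage 1/2 sample statistics: thresholds, polychoric correlations, weights.

Categorical SEM point estimation proceeds in stages: univariate thresholds
from cumulative category proportions, then pairwise polychoric correlations
by maximum likelihood with the stage-1 thresholds held fixed, and finally the
structural fit (see `catlgm.estimator`) weighted by estimated asymptotic
variances of the stacked statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtri
from scipy.stats import norm

from .bvn import rectangle_probabilities, rectangle_probability_derivatives
from .exceptions import DegenerateCategoryError
from .simulate import CategoricalPanel

__all__ = [
    "SampleMoments",
    "PolychoricResult",
    "estimate_sample_thresholds",
    "polychoric_correlation",
    "polychoric_full",
    "contingency_table",
    "asymptotic_weights",
    "sample_moments",
]

_RHO_BOUND = 0.999
_PROB_FLOOR = 1e-12


def estimate_sample_thresholds(panel: CategoricalPanel) -> list[np.ndarray]:
    """Per-time z-scale thresholds: normal quantiles of empirical cumulative
    proportions.  Requires every category to be observed at every time point."""
    counts = panel.category_counts()
    if np.any(counts == 0):
        bad = np.argwhere(counts == 0)
        raise DegenerateCategoryError(
            f"empty categories (time, category): {bad.tolist()}"
        )
    cum = np.cumsum(counts, axis=1)[:, :-1] / panel.n_subjects
    return [ndtri(row) for row in cum]


def contingency_table(x: np.ndarray, y: np.ndarray, cx: int, cy: int) -> np.ndarray:
    """(cx, cy) cross-tabulation of two integer-coded columns."""
    idx = np.asarray(x, dtype=np.int64) * cy + np.asarray(y, dtype=np.int64)
    return np.bincount(idx, minlength=cx * cy).reshape(cx, cy).astype(float)


@dataclass(frozen=True)
class PolychoricResult:
    rho: float
    converged: bool
    boundary: bool
    loglik: float


def _neg_loglik(rho: float, table: np.ndarray, tx, ty) -> float:
    probs = np.maximum(rectangle_probabilities(tx, ty, rho), _PROB_FLOOR)
    return -float(np.sum(table * np.log(probs)))


def polychoric_full(x, y, tx, ty) -> PolychoricResult:
    """Two-stage polychoric (tetrachoric for 2x2) correlation.

    Maximises the bivariate-normal likelihood of the cross-tabulation over
    rho with the univariate thresholds held fixed at their stage-1 values.
    A solution pinned against |rho| = 0.999 is flagged as a boundary case
    (perfect-association tables drive the MLE to +-1).
    """
    tx = np.asarray(tx, dtype=float)
    ty = np.asarray(ty, dtype=float)
    # canonical argument order makes the estimate exactly symmetric in (x, y)
    if (tx.size, tuple(tx)) < (ty.size, tuple(ty)):
        x, y, tx, ty = y, x, ty, tx
    table = contingency_table(x, y, tx.size + 1, ty.size + 1)
    res = minimize_scalar(
        _neg_loglik,
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        args=(table, tx, ty),
        method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    boundary = abs(rho) >= _RHO_BOUND - 1e-4
    return PolychoricResult(
        rho=rho, converged=bool(res.success), boundary=boundary, loglik=-float(res.fun)
    )


def polychoric_correlation(x, y, tx, ty) -> float:
    """Polychoric correlation point estimate (see `polychoric_full`)."""
    return polychoric_full(x, y, tx, ty).rho


@dataclass(frozen=True)
class SampleMoments:
    """Stage-1/2 statistics for one panel.

    ``thresholds`` is a (T, C-1) array, ``correlations`` the T x T polychoric
    matrix, and ``asymptotic_variances`` the estimated variances of the
    stacked statistic vector (thresholds time-major, then the upper-triangle
    correlations in pair order (1,2), (1,3), ..., (T-1,T)).
    """

    thresholds: np.ndarray
    correlations: np.ndarray
    asymptotic_variances: np.ndarray
    n: int
    boundary: bool = False

    def __post_init__(self):
        r = np.asarray(self.correlations, dtype=float)
        if np.max(np.abs(r - r.T)) > 1e-12 or np.max(np.abs(np.diag(r) - 1)) > 1e-12:
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        if np.any(np.asarray(self.asymptotic_variances) <= 0):
            raise ValueError("asymptotic variances must be positive")

    @property
    def n_times(self) -> int:
        return self.thresholds.shape[0]

    @property
    def stacked(self) -> np.ndarray:
        """Thresholds (time-major) followed by unique correlations."""
        T = self.n_times
        iu = np.triu_indices(T, k=1)
        return np.concatenate([self.thresholds.ravel(), self.correlations[iu]])


def _threshold_variances(thresholds: np.ndarray, counts: np.ndarray, n: int) -> np.ndarray:
    """Delta-method variance of each estimated threshold.

    tau_hat = Phi^{-1}(p_hat) with p_hat a cumulative proportion, so
    Var(tau_hat) = p(1-p) / (n * phi(tau)^2).
    """
    cum = np.cumsum(counts, axis=1)[:, :-1] / n
    dens = norm.pdf(thresholds)
    return cum * (1.0 - cum) / (n * dens ** 2)


def _rho_variance(table: np.ndarray, tx, ty, rho: float) -> float:
    """Two-stage delta-method variance of the polychoric estimate.

    The estimate solves the score equation of the bivariate-normal likelihood
    in rho with stage-1 thresholds plugged in, so its influence function has
    a direct score term plus correction terms that propagate the sampling
    noise of each threshold (whose own influence is the centred indicator
    divided by the normal density).  The returned value is the variance of
    the per-subject influence divided by n; returns NaN when the observed
    curvature is not positive (degenerate tables).
    """
    from .bvn import rectangle_probability_cut_derivatives

    n = table.sum()
    phat = table / n
    tx = np.asarray(tx, float)
    ty = np.asarray(ty, float)
    probs = np.maximum(rectangle_probabilities(tx, ty, rho), _PROB_FLOOR)
    s_rho = rectangle_probability_derivatives(tx, ty, rho) / probs
    info = float(np.sum(phat * s_rho ** 2))
    if not np.isfinite(info) or info <= 0:
        return np.nan
    # curvature of the mean score in each threshold (information equality)
    da = rectangle_probability_cut_derivatives(tx, ty, rho) / probs[None]
    db = rectangle_probability_cut_derivatives(ty, tx, rho) / probs.T[None]
    g_a = -np.sum(phat[None] * s_rho[None] * da, axis=(1, 2))
    g_b = -np.sum(phat.T[None] * s_rho.T[None] * db, axis=(1, 2))
    # threshold influences: d a_p / d p_kl = 1{k <= p} / phi(a_p)
    dens_a = norm.pdf(tx)
    dens_b = norm.pdf(ty)
    K = np.arange(tx.size + 1)
    L = np.arange(ty.size + 1)
    u = (K[None, :] <= np.arange(tx.size)[:, None]).astype(float) / dens_a[:, None]
    v = (L[None, :] <= np.arange(ty.size)[:, None]).astype(float) / dens_b[:, None]
    psi = (
        s_rho
        + np.einsum("p,pk->k", g_a, u)[:, None]
        + np.einsum("q,ql->l", g_b, v)[None, :]
    ) / info
    mean_psi = float(np.sum(phat * psi))
    var = float(np.sum(phat * (psi - mean_psi) ** 2))
    if not np.isfinite(var) or var <= 0:
        return np.nan
    return var / n


def asymptotic_weights(
    panel: CategoricalPanel,
    thresholds: list[np.ndarray],
    correlations: np.ndarray,
) -> np.ndarray:
    """Estimated asymptotic variances of the stacked statistics.

    Falls back to unit weights (with a warning) for any entry whose variance
    estimate is non-finite or non-positive.
    """
    counts = panel.category_counts().astype(float)
    tau = np.vstack(thresholds)
    var_tau = _threshold_variances(tau, counts, panel.n_subjects)
    T = panel.n_times
    var_rho = []
    for t in range(T):
        for u in range(t + 1, T):
            table = contingency_table(
                panel.data[:, t], panel.data[:, u], panel.n_categories, panel.n_categories
            )
            var_rho.append(
                _rho_variance(table, thresholds[t], thresholds[u], correlations[t, u])
            )
    out = np.concatenate([var_tau.ravel(), np.asarray(var_rho)])
    bad = ~np.isfinite(out) | (out <= 0)
    if np.any(bad):
        warnings.warn(
            "non-positive or non-finite asymptotic variance; using unit weight",
            RuntimeWarning,
            stacklevel=2,
        )
        out = np.where(bad, 1.0, out)
    return out


def sample_moments(panel: CategoricalPanel) -> SampleMoments:
    """Full stage-1/2 summary of a panel: thresholds, polychoric correlation
    matrix and asymptotic-variance weights.

    Raises :class:`DegenerateCategoryError` on panels with empty categories;
    boundary polychoric solutions are flagged, not raised.
    """
    thresholds = estimate_sample_thresholds(panel)
    T = panel.n_times
    corr = np.eye(T)
    boundary = False
    for t in range(T):
        for u in range(t + 1, T):
            res = polychoric_full(
                panel.data[:, t], panel.data[:, u], thresholds[t], thresholds[u]
            )
            corr[t, u] = corr[u, t] = res.rho
            boundary = boundary or res.boundary or not res.converged
    weights = asymptotic_weights(panel, thresholds, corr)
    return SampleMoments(
        thresholds=np.vstack(thresholds),
        correlations=corr,
        asymptotic_variances=weights,
        n=panel.n_subjects,
        boundary=boundary,
    )
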