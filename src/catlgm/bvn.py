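"""Standard bivariate normal CDF and density.

The CDF uses Owen's T-function identity

    Phi2(h, k; rho) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - beta,

with ``a_h = (k - rho*h) / (h*sqrt(1-rho^2))`` (and symmetrically for
``a_k``) and ``beta = 1/2`` when ``h*k < 0``.  Owen's T is evaluated by
``scipy.special.owens_t``, so every call is vectorised and exact to machine
precision; this matters because polychoric likelihoods evaluate rectangle
probabilities thousands of times per fit.

Arguments exactly at zero are nudged by 1e-13 (the identity's beta term is
discontinuous there although the CDF itself is continuous); the induced
error is below 1e-13.  Infinite arguments reduce to the univariate CDF.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

_RHO_CAP = 1.0 - 1e-12


def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    ``h`` and ``k`` broadcast; ``rho`` is a scalar in [-1, 1].
    """
    from scipy.special import owens_t

    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    if rho >= _RHO_CAP:
        return ndtr(np.minimum(h, k))
    if rho <= -_RHO_CAP:
        return np.clip(ndtr(h) + ndtr(k) - 1.0, 0.0, 1.0)

    with np.errstate(all="ignore"):
        hn = np.where(np.abs(h) < 1e-13, 1e-13, h)
        kn = np.where(np.abs(k) < 1e-13, 1e-13, k)
        s = np.sqrt(1.0 - rho * rho)
        # slope arguments of Owen's T; clipped so h -> 0 limits stay finite
        ah = np.clip(np.nan_to_num((kn - rho * hn) / (hn * s)), -1e15, 1e15)
        ak = np.clip(np.nan_to_num((hn - rho * kn) / (kn * s)), -1e15, 1e15)
        beta = np.where(hn * kn > 0, 0.0, 0.5)
        out = 0.5 * (ndtr(hn) + ndtr(kn)) - owens_t(hn, ah) - owens_t(kn, ak) - beta
    # infinite bounds: reduce to the univariate CDF (owens_t returns nan there)
    out = np.where(np.isneginf(h) | np.isneginf(k), 0.0, out)
    out = np.where(np.isposinf(h), ndtr(k), out)
    out = np.where(np.isposinf(k) & ~np.isposinf(h) & ~np.isneginf(h), ndtr(h), out)
    return np.clip(out, 0.0, 1.0)


def bvn_pdf(h, k, rho: float):
    """Standard bivariate normal density phi2(h, k; rho); 0 at infinite args."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = float(np.clip(rho, -_RHO_CAP, _RHO_CAP))
    s2 = 1.0 - rho * rho
    finite = np.isfinite(h) & np.isfinite(k)
    hf = np.where(finite, h, 0.0)
    kf = np.where(finite, k, 0.0)
    z = (hf * hf - 2.0 * rho * hf * kf + kf * kf) / s2
    dens = np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(s2))
    return np.where(finite, dens, 0.0)


def rectangle_probabilities(tx, ty, rho: float):
    """Cell probabilities of a bivariate normal cut by two threshold lists.

    ``tx`` (length Cx-1) and ``ty`` (length Cy-1) are strictly increasing cut
    points; returns the (Cx, Cy) matrix of rectangle probabilities obtained by
    double-differencing the CDF over the grid augmented with +/- infinity.
    """
    gx = np.concatenate(([-np.inf], np.asarray(tx, float), [np.inf]))
    gy = np.concatenate(([-np.inf], np.asarray(ty, float), [np.inf]))
    H, K = np.meshgrid(gx, gy, indexing="ij")
    F = bvn_cdf(H, K, rho)
    P = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(P, 0.0, 1.0)


def rectangle_probability_derivatives(tx, ty, rho: float):
    """d/d(rho) of `rectangle_probabilities` (Plackett's identity).

    Uses dPhi2(h,k;rho)/drho = phi2(h,k;rho), so each cell derivative is the
    double difference of the bivariate density over the threshold grid.
    """
    gx = np.concatenate(([-np.inf], np.asarray(tx, float), [np.inf]))
    gy = np.concatenate(([-np.inf], np.asarray(ty, float), [np.inf]))
    H, K = np.meshgrid(gx, gy, indexing="ij")
    D = bvn_pdf(H, K, rho)
    return D[1:, 1:] - D[:-1, 1:] - D[1:, :-1] + D[:-1, :-1]


def rectangle_probability_cut_derivatives(tx, ty, rho: float):
    """d(cell probability)/d(tx_p) for every x-cut p.

    Moving cut ``a_p`` transfers density between row cells p and p + 1:
    ``d pi_{p,j} / d a_p = phi(a_p) * [Phi(z(b_j | a_p)) - Phi(z(b_{j-1} | a_p))]``
    with ``z(k | h) = (k - rho h) / sqrt(1 - rho^2)`` the conditional
    standardisation, and the same quantity with a minus sign for row p + 1.
    Returns an array of shape (len(tx), len(tx) + 1, len(ty) + 1).
    """
    from scipy.stats import norm

    tx = np.asarray(tx, float)
    ty = np.asarray(ty, float)
    rho = float(np.clip(rho, -_RHO_CAP, _RHO_CAP))
    s = np.sqrt(1.0 - rho * rho)
    gy = np.concatenate(([-np.inf], ty, [np.inf]))
    # conditional band masses at each cut: (P, Q+1)
    z = (gy[None, :] - rho * tx[:, None]) / s
    band = np.diff(ndtr(z), axis=1) * norm.pdf(tx)[:, None]
    P, Q1 = tx.size, ty.size + 1
    out = np.zeros((P, P + 1, Q1))
    for p in range(P):
        out[p, p, :] = band[p]
        out[p, p + 1, :] = -band[p]
    return out
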