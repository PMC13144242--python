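"""Observed-scale-reference calculus for categorical latent growth models.

Categorical SEM treats each observed ordinal/binary response as a coarsened
version of a continuous latent response variable y*.  Because y* has no
metric of its own, its origin and unit must be fixed from quantities that are
actually observable ("observed scale references").  The two cases differ:

* **ordinal** (3+ categories): the z-scale thresholds implied by the category
  proportions provide both the origin (first threshold) and the unit (the gap
  between two thresholds), so the unit is determined *after* and independently
  of the origin;
* **binary**: a single threshold fixes the origin, and the unit has to come
  from the standard deviation of the observed 0/1 variable,
  ``w_t = sqrt(1 / (p_t (1 - p_t)))`` with ``p_t`` the success probability —
  so the unit is a deterministic function of the origin.

Propagating either unit across time under threshold invariance gives the
common-scale standard deviations via the conservation identity
``w_t * sqrt(s*_t) = w`` and the common-scale means via
``ybar*_t = tau_anchor - sqrt(s*_t) * tau^z_t``.  The divergence between the
two constructions over time is what makes binary growth models behave
differently from ordinal ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .exceptions import BinaryCaseError, DegenerateCategoryError

__all__ = [
    "ProportionProfile",
    "ScaleSummary",
    "thresholds_from_proportions",
    "binary_unit_length",
    "ordinal_unit_length",
    "common_scale_sds",
    "common_scale_means",
    "scale_summary",
]

_SUM_TOL = 1e-10


@dataclass(frozen=True)
class ProportionProfile:
    """Per-time category proportions for a longitudinal categorical variable.

    ``proportions`` is a (T, C) array; each row sums to 1 and every entry is
    strictly positive.  Zero-frequency categories are a precondition failure
    (they imply infinite thresholds), never silently repaired.
    """

    proportions: np.ndarray

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.proportions, dtype=float))
        if p.shape[0] < 2 or p.shape[1] < 2:
            raise ValueError(
                f"need T >= 2 time points and C >= 2 categories, got shape {p.shape}"
            )
        if np.any(p <= 0.0):
            raise DegenerateCategoryError(
                "all category proportions must be strictly positive"
            )
        if np.any(np.abs(p.sum(axis=1) - 1.0) > _SUM_TOL):
            raise ValueError("each time point's proportions must sum to 1")
        object.__setattr__(self, "proportions", p)

    @property
    def n_times(self) -> int:
        return self.proportions.shape[0]

    @property
    def n_categories(self) -> int:
        return self.proportions.shape[1]

    @property
    def is_binary(self) -> bool:
        return self.n_categories == 2


def thresholds_from_proportions(profile: ProportionProfile, time: int) -> np.ndarray:
    """z-scale thresholds at one time point: normal quantiles of the C-1
    cumulative category proportions.

    Raises :class:`DegenerateCategoryError` if any cumulative proportion hits
    0 or 1 (an unusable replicate), and guarantees a strictly increasing
    result otherwise.
    """
    p = profile.proportions[time]
    cum = np.cumsum(p)[:-1]
    if np.any(cum <= 0.0) or np.any(cum >= 1.0):
        raise DegenerateCategoryError(
            f"cumulative proportions at time {time} reach 0 or 1"
        )
    return ndtri(cum)


def binary_unit_length(p: float) -> float:
    """Unit length of the latent response scale fixed by a binary variable.

    ``w = sqrt(1 / (p (1 - p)))`` where ``p`` is the success probability;
    the inverse of the Bernoulli standard deviation.  Minimised (w = 2) at
    p = 0.5 and growing as p drifts toward either boundary, which is exactly
    why the binary unit cannot stay constant when response rates trend.
    """
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie strictly inside (0, 1), got {p}")
    return float(np.sqrt(1.0 / (p * (1.0 - p))))


def ordinal_unit_length(thresholds, pair: tuple[int, int] = (0, 1)) -> float:
    """Unit length fixed by an ordinal variable: the gap between two z-scale
    thresholds (by default the first two, matching the convention that the
    first threshold is pinned to 0 and the second to 1)."""
    t = np.asarray(thresholds, dtype=float)
    if t.size < 2:
        raise BinaryCaseError(
            "a single threshold carries no inter-threshold distance; "
            "use binary_unit_length for binary variables"
        )
    if np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    i, j = pair
    if not (0 <= i < j < t.size):
        raise ValueError(f"invalid threshold pair {pair} for {t.size} thresholds")
    return float(t[j] - t[i])


def common_scale_sds(unit_lengths, reference: int = 0) -> np.ndarray:
    """Common-scale standard deviations sqrt(s*_t) from per-time unit lengths.

    Solves the conservation identity ``w_t * sqrt(s*_t) = w`` with the
    reference time anchored at sqrt(s*) = 1, i.e. ``sqrt(s*_t) = w_ref / w_t``.
    A time point whose z-scale unit is shorter than the reference's therefore
    gets a *larger* common-scale standard deviation.
    """
    w = np.asarray(unit_lengths, dtype=float)
    if np.any(w <= 0):
        raise ValueError("unit lengths must be positive")
    return w[reference] / w


def common_scale_means(sds, z_thresholds, anchor: float = 0.0) -> np.ndarray:
    """Common-scale means ``ybar*_t = anchor - sqrt(s*_t) * tau^z_t``.

    ``z_thresholds`` holds one threshold per time point (the cut that is
    pinned to ``anchor`` on the common scale, by default the first threshold
    at 0).  The result satisfies the invariance identity
    ``ybar*_t + sqrt(s*_t) * tau^z_t = anchor`` for every t.
    """
    s = np.asarray(sds, dtype=float)
    tz = np.asarray(z_thresholds, dtype=float)
    if s.shape != tz.shape:
        raise ValueError("sds and z_thresholds must have matching lengths")
    return anchor - s * tz


@dataclass(frozen=True)
class ScaleSummary:
    """Complete common-scale description of a longitudinal categorical variable.

    Invariants (checked on construction): thresholds strictly increasing
    within each time point; ``unit_lengths[t] * sqrt_s_star[t]`` constant and
    equal to ``common_unit``; ``sqrt_s_star[reference] == 1`` under reference
    anchoring.
    """

    z_thresholds: np.ndarray        # (T, C-1)
    unit_lengths: np.ndarray        # (T,)
    common_unit: float              # w
    sqrt_s_star: np.ndarray         # (T,)
    ybar_star: np.ndarray           # (T,)
    reference: int = 0
    anchor: float = 0.0
    anchor_category: int = field(default=0, repr=False)

    def __post_init__(self):
        tz = np.atleast_2d(np.asarray(self.z_thresholds, dtype=float))
        w = np.asarray(self.unit_lengths, dtype=float)
        s = np.asarray(self.sqrt_s_star, dtype=float)
        m = np.asarray(self.ybar_star, dtype=float)
        if tz.shape[1] > 1 and np.any(np.diff(tz, axis=1) <= 0):
            raise ValueError("z-scale thresholds must increase within each time")
        prod = w * s
        if np.any(np.abs(prod - self.common_unit) > _SUM_TOL * max(1.0, self.common_unit)):
            raise ValueError("unit-length conservation w_t * sqrt(s*_t) = w violated")
        if abs(s[self.reference] - 1.0) > _SUM_TOL:
            raise ValueError("sqrt(s*) at the reference time must equal 1")
        object.__setattr__(self, "z_thresholds", tz)
        object.__setattr__(self, "unit_lengths", w)
        object.__setattr__(self, "sqrt_s_star", s)
        object.__setattr__(self, "ybar_star", m)

    def to_frame(self):
        """Tabular view: one row per time point."""
        import pandas as pd

        T, Cm1 = self.z_thresholds.shape
        data = {"time": np.arange(1, T + 1)}
        for c in range(Cm1):
            data[f"tau_z_{c + 1}"] = self.z_thresholds[:, c]
        data["w_t"] = self.unit_lengths
        data["sqrt_s_star"] = self.sqrt_s_star
        data["ybar_star"] = self.ybar_star
        return pd.DataFrame(data)


def scale_summary(
    profile: ProportionProfile,
    reference: int = 0,
    pair: tuple[int, int] = (0, 1),
    anchor: float = 0.0,
    anchor_category: int = 0,
) -> ScaleSummary:
    """Build the full common-scale summary from observed category proportions.

    Binary profiles use the Bernoulli-SD unit; ordinal profiles use the
    inter-threshold gap for the ``pair`` of thresholds.  The common scale is
    anchored so that threshold ``anchor_category`` sits at ``anchor`` and the
    ``reference`` time point keeps sqrt(s*) = 1.
    """
    tz = np.vstack(
        [thresholds_from_proportions(profile, t) for t in range(profile.n_times)]
    )
    if profile.is_binary:
        # success probability = probability of the upper category
        p_success = profile.proportions[:, 1]
        w = np.array([binary_unit_length(p) for p in p_success])
    else:
        w = np.array([ordinal_unit_length(row, pair) for row in tz])
    sds = common_scale_sds(w, reference)
    means = common_scale_means(sds, tz[:, anchor_category], anchor)
    return ScaleSummary(
        z_thresholds=tz,
        unit_lengths=w,
        common_unit=float(w[reference]),
        sqrt_s_star=sds,
        ybar_star=means,
        reference=reference,
        anchor=anchor,
        anchor_category=anchor_category,
    )


def proportions_from_normal(mean, sd, thresholds) -> np.ndarray:
    """Category proportions implied by a normal y* cut by fixed thresholds.

    Utility for round-tripping: feeding the result through
    `thresholds_from_proportions` recovers ``(thresholds - mean) / sd``.
    """
    t = (np.asarray(thresholds, dtype=float) - mean) / sd
    cum = np.concatenate(([0.0], ndtr(t), [1.0]))
    return np.diff(cum)
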