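"""Synthetic longitudinal categorical panels.

Latent trajectories are drawn from the multivariate normal implied by a
linear growth model and discretised by fixed, time-invariant thresholds, so
threshold invariance holds in the population by construction.  The default
study design crosses

* change pattern: ``shift`` (positively to negatively skewed), ``increase``
  (positively skewed to symmetric), ``decrease`` (symmetric to negatively
  skewed) — named for how the binary common-scale SD is expected to behave;
* slope-mean level: ``large`` (0.40) vs ``small`` (0.10);
* number of categories: 2, 3, 4 with symmetric thresholds 0 / +-0.83 /
  (+-1.25, 0);
* sample size: 100, 200, 1000,

for 54 conditions, with growth-factor covariances psi00 = 0.5, psi11 = 0.1,
psi10 = 0 and error variances theta = (0.5, 0.6, 0.9, 1.4) so the population
SD of y* increases over time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidSpecError
from .model import GrowthSpec, implied_moments

__all__ = [
    "ThresholdSet",
    "CategoricalPanel",
    "Condition",
    "GENERATION_THRESHOLDS",
    "SLOPE_MEANS",
    "PATTERN_INTERCEPTS",
    "DEFAULT_COVARIANCES",
    "condition_to_spec",
    "generate_latent_panel",
    "categorize",
    "generate_panel",
    "condition_grid",
    "write_panel",
    "read_panel",
]

PATTERNS = ("shift", "increase", "decrease")
SLOPES = ("large", "small")
CATEGORY_COUNTS = (2, 3, 4)
SAMPLE_SIZES = (100, 200, 1000)

SLOPE_MEANS = {"large": 0.40, "small": 0.10}
#: intercept means chosen so the four occasion means follow each pattern
PATTERN_INTERCEPTS = {
    ("shift", "large"): -0.60,
    ("shift", "small"): -0.15,
    ("increase", "large"): -1.20,
    ("increase", "small"): -0.30,
    ("decrease", "large"): 0.00,
    ("decrease", "small"): 0.00,
}
DEFAULT_COVARIANCES = dict(psi00=0.5, psi11=0.1, psi10=0.0, theta=(0.5, 0.6, 0.9, 1.4))
GENERATION_THRESHOLDS = {
    2: (0.0,),
    3: (-0.83, 0.83),
    4: (-1.25, 0.0, 1.25),
}


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered cut points on the latent y* scale, shared by all occasions."""

    cuts: tuple[float, ...]

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cuts)
        if len(cuts) < 1:
            raise ValueError("need at least one threshold")
        if any(b - a <= 0 for a, b in zip(cuts, cuts[1:])):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "cuts", cuts)

    @property
    def n_categories(self) -> int:
        return len(self.cuts) + 1

    @classmethod
    def for_categories(cls, c: int) -> "ThresholdSet":
        if c not in GENERATION_THRESHOLDS:
            raise ValueError(f"no default thresholds for {c} categories")
        return cls(GENERATION_THRESHOLDS[c])


@dataclass(frozen=True)
class CategoricalPanel:
    """N x T matrix of integer-coded responses in {0, ..., C-1}."""

    data: np.ndarray
    n_categories: int

    def __post_init__(self):
        d = np.asarray(self.data)
        if d.ndim != 2 or d.shape[0] < 1 or d.shape[1] < 2:
            raise ValueError("panel must be N x T with N >= 1, T >= 2")
        if not np.issubdtype(d.dtype, np.integer):
            if not np.all(d == np.round(d)):
                raise ValueError("panel entries must be integers")
            d = d.astype(np.int64)
        if d.min() < 0 or d.max() > self.n_categories - 1:
            raise ValueError("panel entries outside {0, ..., C-1}")
        object.__setattr__(self, "data", d)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    def category_counts(self) -> np.ndarray:
        """(T, C) table of per-time category counts."""
        return np.stack(
            [
                np.bincount(self.data[:, t], minlength=self.n_categories)
                for t in range(self.n_times)
            ]
        )

    def is_degenerate(self) -> bool:
        """True when some category never occurs at some time point."""
        return bool(np.any(self.category_counts() == 0))


@dataclass(frozen=True)
class Condition:
    """One cell of the simulation design."""

    pattern: str
    slope: str
    categories: int
    n: int
    reps: int = 1000
    base_seed: int = 0

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.slope not in SLOPES:
            raise ValueError(f"unknown slope level {self.slope!r}")
        if self.categories not in GENERATION_THRESHOLDS:
            raise ValueError(f"unsupported category count {self.categories}")
        if self.n < 1 or self.reps < 1:
            raise ValueError("n and reps must be positive")

    @property
    def label(self) -> str:
        return f"{self.pattern}-{self.slope}-c{self.categories}-n{self.n}"

    def seed_sequence(self, replicate: int) -> np.random.SeedSequence:
        """Independent, reproducible stream for one replicate of this cell.

        The spawn key encodes the design coordinates, so streams are pairwise
        distinct across conditions and replicates for a given base seed.
        """
        key = (
            PATTERNS.index(self.pattern),
            SLOPES.index(self.slope),
            self.categories,
            self.n,
            replicate,
        )
        return np.random.SeedSequence(entropy=self.base_seed, spawn_key=key)

    def thresholds(self) -> ThresholdSet:
        return ThresholdSet.for_categories(self.categories)


def condition_to_spec(condition: Condition) -> GrowthSpec:
    """Growth parameters for one design cell (four occasions, loadings 0..3)."""
    alpha10 = SLOPE_MEANS[condition.slope]
    alpha00 = PATTERN_INTERCEPTS[(condition.pattern, condition.slope)]
    return GrowthSpec(
        alpha00=alpha00,
        alpha10=alpha10,
        loadings=(0.0, 1.0, 2.0, 3.0),
        **DEFAULT_COVARIANCES,
    )


def generate_latent_panel(spec: GrowthSpec, n: int, seed) -> np.ndarray:
    """Draw n i.i.d. latent trajectories from the implied multivariate normal.

    ``seed`` may be an int or a `numpy.random.SeedSequence`.  The draw is a
    fixed linear transform of standard normals (Cholesky factor of the
    implied covariance), so identical seeds give identical panels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mom = implied_moments(spec)
    try:
        chol = np.linalg.cholesky(mom.covariance)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise InvalidSpecError("implied covariance is not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, spec.n_times))
    return mom.means + z @ chol.T


def categorize(latent: np.ndarray, thresholds: ThresholdSet) -> CategoricalPanel:
    """Discretise latent values: the category is the number of thresholds at
    or below the value (a value exactly at a cut goes to the upper category)."""
    cuts = np.asarray(thresholds.cuts)
    cats = np.searchsorted(cuts, np.asarray(latent, dtype=float), side="right")
    return CategoricalPanel(data=cats.astype(np.int64), n_categories=thresholds.n_categories)


def generate_panel(condition: Condition, replicate: int = 0) -> CategoricalPanel:
    """Generate one categorical panel for a design cell and replicate index."""
    spec = condition_to_spec(condition)
    latent = generate_latent_panel(spec, condition.n, condition.seed_sequence(replicate))
    return categorize(latent, condition.thresholds())


def condition_grid(
    base_seed: int = 0,
    reps: int = 1000,
    patterns=PATTERNS,
    slopes=SLOPES,
    categories=CATEGORY_COUNTS,
    sample_sizes=SAMPLE_SIZES,
) -> list[Condition]:
    """The full factorial design (2 x 3 x 3 x 3 = 54 cells by default)."""
    return [
        Condition(pattern=p, slope=s, categories=c, n=n, reps=reps, base_seed=base_seed)
        for p, s, c, n in itertools.product(patterns, slopes, categories, sample_sizes)
    ]


def write_panel(panel: CategoricalPanel, path, metadata: dict | None = None) -> None:
    """Write a panel as CSV: '#' metadata lines, then columns t1..tT."""
    meta = {"categories": panel.n_categories}
    if metadata:
        meta.update(metadata)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        fh.write(",".join(f"t{t + 1}" for t in range(panel.n_times)) + "\n")
        np.savetxt(fh, panel.data, fmt="%d", delimiter=",")


def read_panel(path) -> tuple[CategoricalPanel, dict]:
    """Read a panel CSV written by `write_panel`; returns (panel, metadata)."""
    import pandas as pd

    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if "categories" in meta:
        c = int(meta["categories"])
        meta["categories"] = c
    else:
        c = int(df.to_numpy().max()) + 1
    return CategoricalPanel(data=df.to_numpy(dtype=np.int64), n_categories=c), meta
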