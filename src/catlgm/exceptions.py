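"""Exception types shared across the package."""


class CatLgmError(Exception):
    """Base class for all package-specific errors."""


class DegenerateCategoryError(CatLgmError):
    """A category has zero observed (or zero implied) frequency.

    Thresholds are normal quantiles of cumulative category proportions, so a
    cumulative proportion of 0 or 1 maps to an infinite threshold and the
    replicate is unusable.  Degenerate data are deliberately *not* clipped or
    repaired: the simulation layer counts them as estimation difficulties.
    """


class InvalidSpecError(CatLgmError):
    """A growth specification implies a non-positive-definite covariance."""


class BinaryCaseError(CatLgmError):
    """An ordinal-only operation was called with binary (single-threshold) input."""
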