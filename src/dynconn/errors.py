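"""Exception and warning types shared across the package."""


class DynconnError(Exception):
    """Base class for all dynconn errors."""


class FormatError(DynconnError, ValueError):
    """A file or table does not parse as the expected numeric format."""


class DimensionError(DynconnError, ValueError):
    """An input has too few rows/columns or inconsistent shape."""


class SymmetryError(DynconnError, ValueError):
    """A matrix that must be symmetric is not."""


class CohortError(DynconnError, ValueError):
    """A cohort manifest or cohort-level invariant is violated."""


class DegenerateCorrelationWarning(UserWarning):
    """A zero-variance signal was encountered; its correlations are set to 0."""


class SelectionFallbackWarning(UserWarning):
    """A feature-selection stage returned no features; fallback applied."""


class MetricsWarning(UserWarning):
    """An evaluation ratio has a zero denominator and is reported as NaN."""
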