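"""Exception types shared across the package."""


class PathageError(Exception):
    """Base class for all package-specific errors."""


class CohortFormatError(PathageError):
    """A cohort table is structurally invalid (missing/duplicate columns)."""


class CohortParseError(PathageError):
    """A cohort table cell could not be parsed (non-numeric, missing value)."""


class ConfigurationError(PathageError):
    """A parameter object violates its invariants."""


class DegenerateInputError(PathageError):
    """An input admits no meaningful answer (e.g. zero-variance vector).

    Raised instead of silently returning 0 so that degenerate regression
    fits cannot masquerade as mid-grid fitness values; the deviation search
    catches this and records a fitness of -inf for the offending candidate.
    """


class FitError(PathageError):
    """The regression solver failed to produce a usable model."""
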