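"""Exception hierarchy shared across the package."""


class DecompMetaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DecompMetaError):
    """A mandatory column is missing or the column mapping is invalid."""


class ValidationError(DecompMetaError):
    """One or more rows violate a dataset invariant.

    Carries per-row diagnostics in ``.diagnostics`` (list of strings).
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = list(diagnostics or [])


class DegenerateCellError(DecompMetaError):
    """CV is requested for a cell whose grand mean is at or below epsilon."""


class RankDeficiencyError(DecompMetaError):
    """The fixed-effect design matrix is rank deficient.

    ``.aliased`` names the offending columns when known.
    """

    def __init__(self, message, aliased=None):
        super().__init__(message)
        self.aliased = list(aliased or [])


class ConvergenceError(DecompMetaError):
    """REML optimisation failed; ``.incumbent`` carries the best fit found."""

    def __init__(self, message, incumbent=None):
        super().__init__(message)
        self.incumbent = incumbent


class AlignmentError(DecompMetaError):
    """Treatment identifiers do not match between two inputs.

    ``.offenders`` lists the unmatched identifiers.
    """

    def __init__(self, message, offenders=None):
        super().__init__(message)
        self.offenders = list(offenders or [])


class UndefinedStatisticError(DecompMetaError):
    """A statistic (e.g. Mantel r) is undefined for the given input."""
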