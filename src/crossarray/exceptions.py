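"""Exception hierarchy shared across the pipeline stages.

Each failure class maps to a distinct CLI exit code (see ``cli.EXIT_CODES``).
"""


class CrossArrayError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CrossArrayError, ValueError):
    """A function argument violates its contract (sizes, ranges, emptiness)."""


class InvalidInputError(CrossArrayError, ValueError):
    """Malformed data input: missing values, duplicate ids, p outside [0,1]."""


class InvalidSequenceError(InvalidInputError):
    """A nucleotide sequence contains characters outside {A, C, G, T}."""


class ConsistencyError(CrossArrayError):
    """Cross-table bookkeeping failure: an id referenced in one artifact is
    absent from the artifact that should define it."""


class RankDeficiencyError(CrossArrayError):
    """The design matrix is not of full column rank; carries the offending
    column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class InsufficientDFError(CrossArrayError):
    """Fewer samples than model parameters: no residual degrees of freedom."""


class DegeneratePriorError(CrossArrayError):
    """Variance-prior estimation impossible (e.g. every residual variance 0)."""
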