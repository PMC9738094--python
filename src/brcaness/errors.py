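"""Exception hierarchy for the brcaness package."""


class BrcanessError(Exception):
    """Base class for all package-specific errors."""


class CohortFormatError(BrcanessError):
    """A cohort table failed to parse under the expected dialect.

    The message names the offending file and column.
    """


class CohortValidationError(BrcanessError):
    """A cohort table violated a referential-integrity constraint."""


class DesignError(BrcanessError):
    """A simulation design contains invalid parameters."""


class AnalysisError(BrcanessError):
    """An analysis stage was called on inputs violating its preconditions."""


class NormalizationError(BrcanessError):
    """Reference normalization is undefined (missing or zero reference feature)."""
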