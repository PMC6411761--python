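"""Exception hierarchy for the bhsii package."""


class BhsiiError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BhsiiError):
    """Input data violates the instrument's structural constraints."""


class MissingItemError(ValidationError):
    """A required item is absent from a response sheet.

    Raised under the ``strict`` missing-data policy; the message names
    the offending item(s).
    """


class DegenerateInputError(BhsiiError):
    """A statistic is undefined for the given input.

    Examples: zero between-subject variance for an ICC, a constant total
    score for Cronbach's alpha, an empty group for a ROC analysis.
    """


class ConfigurationError(BhsiiError):
    """A simulation or run configuration is internally inconsistent."""
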