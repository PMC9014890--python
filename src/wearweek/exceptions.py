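"""Exception hierarchy shared across the package."""


class WearweekError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WearweekError):
    """A tabular input does not have the documented layout (e.g. a missing column)."""


class ValidationError(WearweekError):
    """Input data violate a documented invariant (ordering, sign, duplicates...)."""


class InsufficientDataError(WearweekError):
    """A precondition on the amount or balance of data is not met."""


class ConvergenceError(WearweekError):
    """A model fit failed to converge or produced a singular solution."""
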