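"""Exception hierarchy for gaitsmooth."""


class GaitSmoothError(Exception):
    """Base class for all gaitsmooth errors."""


class FormatError(GaitSmoothError):
    """Input file does not conform to the expected table layout."""


class InputError(GaitSmoothError):
    """Input data violate a precondition (non-monotonic time, too many NaNs, ...)."""


class ParameterError(GaitSmoothError):
    """A parameter value is out of its valid range."""


class DomainError(GaitSmoothError):
    """The requested quantity is undefined for the given input (e.g. all-zero profile)."""
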