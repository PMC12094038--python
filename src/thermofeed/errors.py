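"""Exception hierarchy shared across the package."""


class ThermofeedError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ThermofeedError, ValueError):
    """A configuration value or function argument is out of its valid domain."""


class DataError(ThermofeedError, ValueError):
    """Input data violate a structural precondition (empty, overlapping, non-positive...)."""


class ModelError(ThermofeedError, RuntimeError):
    """A statistical model cannot be fitted as requested."""


class CriterionError(ThermofeedError, RuntimeError):
    """No meal criterion can be extracted from a mixture fit."""
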