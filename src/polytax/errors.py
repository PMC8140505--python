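"""Exception types shared across the package."""


class PolytaxError(Exception):
    """Base class for all package-specific errors."""


class SaturationError(PolytaxError):
    """Raised when a distance correction is undefined because the
    observed substitution fractions exceed the model's domain
    (the logarithm argument is <= 0)."""


class UndefinedResultError(PolytaxError):
    """Raised when a metric has no defined value for the given inputs
    (e.g. no alignable genome fragments), as opposed to a value of 0."""


class IncompleteEvidenceError(PolytaxError):
    """Raised when a taxon evidence record is missing a field required
    by the rank decision rules."""
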