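"""Exception hierarchy shared across the package."""


class AllomorphError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AllomorphError):
    """Input table or file does not have the expected structure."""


class ValidationError(AllomorphError):
    """Input values violate a declared invariant (sign, uniqueness, vocabulary)."""


class InsufficientDataError(AllomorphError):
    """Fewer complete observations than the requested analysis needs."""


class DegenerateDataError(AllomorphError):
    """Data carry no usable variation (zero variance, perfect collinearity)."""


class TreeError(AllomorphError):
    """Phylogeny is malformed, non-ultrametric where required, or mismatched."""


class NumericalError(AllomorphError):
    """A numerical routine failed (singular covariance, optimizer breakdown)."""
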