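"""Exception hierarchy.

All errors raised by this package derive from :class:`NmfnaError` so callers
can catch package failures with a single ``except`` clause; each subclass is
also a :class:`ValueError` (or :class:`KeyError` for lookups) so generic
numeric code keeps working.
"""


class NmfnaError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NmfnaError, ValueError):
    """A data object violates a precondition (negative entries, too few samples, ...)."""


class InvalidParameterError(NmfnaError, ValueError):
    """A configuration value is out of its admissible range."""


class AlignmentError(NmfnaError, ValueError):
    """Feature or sample identifiers do not line up between paired objects."""


class ConformabilityError(NmfnaError, ValueError):
    """Matrix shapes are not mutually conformable."""


class EmptyNetworkError(NmfnaError, ValueError):
    """A similarity network ended up with no usable nodes or edges."""


class NotFoundError(NmfnaError, KeyError):
    """A requested object (e.g. the core module of an empty set) does not exist."""


class PipelineError(NmfnaError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
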