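"""Exception hierarchy for icvnorm.

All errors raised by the package derive from :class:`IcvNormError` so callers
can catch one base class at the CLI boundary.
"""


class IcvNormError(Exception):
    """Base class for all icvnorm errors."""


class FormatError(IcvNormError):
    """A file does not conform to the expected dialect (missing columns,
    missing header lines, unparseable rows)."""


class ValidationError(IcvNormError):
    """Input data violates a table invariant (duplicate ids, nonpositive
    volumes that cannot be repaired by row rejection)."""


class InsufficientDataError(IcvNormError):
    """Fewer usable observations than the operation requires."""


class IdentifiabilityError(IcvNormError):
    """The model is not identifiable on the given data (constant ICV,
    rank-deficient design)."""


class NumericError(IcvNormError):
    """A computation over- or under-flowed beyond repair."""
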