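"""Exception types shared across the package."""


class PeakgeneError(Exception):
    """Base class for all package errors."""


class RangeValidationError(PeakgeneError, ValueError):
    """A range table violates a coordinate or strand invariant."""


class GenomeMismatchError(PeakgeneError, ValueError):
    """Two range tables carry incompatible genome labels."""


class AggregatorError(PeakgeneError, ValueError):
    """An aggregation request is malformed (unknown kind or absent column)."""


class FormatError(PeakgeneError, ValueError):
    """An input file cannot be interpreted in the declared format."""
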