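"""Exception hierarchy shared across airnet modules."""


class AirnetError(Exception):
    """Base class for all airnet errors."""


class FormatError(AirnetError):
    """Malformed input file: bad cell, duplicate identifier, self-pair, ..."""


class DimensionError(AirnetError):
    """Shape constraint violated (too few samples, length mismatch)."""


class ParameterError(AirnetError):
    """Parameter outside its documented range."""


class ReferenceError_(AirnetError):
    """Identifier refers to an entity outside the declared universe."""


class UndefinedValueError(AirnetError):
    """A statistic is requested where it is mathematically undefined."""
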