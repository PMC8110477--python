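"""Exception hierarchy shared across the package."""


class DinotadError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DinotadError):
    """A text input could not be parsed; message carries the line number."""


class CoordinateError(DinotadError):
    """A genomic coordinate is off-grid or outside its chromosome."""


class GridMismatchError(DinotadError):
    """Two objects that must share a bin grid do not."""


class BalanceError(DinotadError):
    """Matrix balancing failed to converge; message names offending bins."""


class EmptyInputError(DinotadError):
    """An operation received an input with no usable content."""


class ConfigError(DinotadError):
    """A configuration document violates a constraint; message carries the field path."""


class MalformedModelError(DinotadError):
    """A transcript model violates structural assumptions (e.g. a <4 nt intron)."""


class StrandError(DinotadError):
    """An operation requiring a known strand was given an unoriented transcript."""
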