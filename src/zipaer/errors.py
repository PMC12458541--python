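"""Exception hierarchy shared across the package.

Every error raised on a contract violation derives from :class:`ZipAErError`
so callers (and the CLI) can separate usage problems from genuine bugs.
"""


class ZipAErError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ZipAErError):
    """An invalid configuration value (counts, fractions, divisibility...)."""


class SchemaError(ZipAErError):
    """A table is missing a required column, or has a wrong dtype."""


class ParseError(ZipAErError):
    """A malformed row in an input file; carries the row number when known."""


class ValidationError(ZipAErError):
    """Data violating a documented invariant (e.g. center outside its FOV)."""


class ShapeError(ZipAErError):
    """Tensor shape mismatch, or a convolution that cannot produce output."""


class SpecError(ZipAErError):
    """A model specification that cannot be instantiated or mirrored."""


class DataError(ZipAErError):
    """Empty or degenerate data where the operation requires content."""


class TrainingError(ZipAErError):
    """Non-finite loss or other failure inside a training loop."""
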