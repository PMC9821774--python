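"""Exception hierarchy.

Every error raised by cernet derives from :class:`CernetError`, so callers
(and the CLI) can distinguish parse, validation and computation failures.
"""


class CernetError(Exception):
    """Base class for all cernet errors."""


class ParseError(CernetError):
    """Malformed input file; message carries the offending location."""


class InvalidDesignError(CernetError):
    """Study design violates its invariants (conditions, replicates)."""


class ConfigurationError(CernetError):
    """Invalid simulation or pipeline configuration."""


class DegenerateSampleError(CernetError):
    """A sample column contains no counts and cannot be normalized."""


class EstimationError(CernetError):
    """Dispersion estimation has no usable features."""


class UndefinedCorrelationError(CernetError):
    """Correlation is undefined (constant input vector)."""


class AssemblyError(CernetError):
    """Network assembly found a dangling edge reference."""
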