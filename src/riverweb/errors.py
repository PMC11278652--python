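"""Typed exceptions shared across the package.

Every reader and validator raises one of these with row/column context so
that malformed inputs never produce a partially filled structure.
"""


class RiverwebError(Exception):
    """Base class for all package errors."""


class FormatError(RiverwebError):
    """A file does not conform to the expected dialect (structure-level)."""


class ValidationError(RiverwebError):
    """Parsed content violates a domain invariant (value-level)."""


class ConfigurationError(RiverwebError):
    """A parameter or specification object is inconsistent."""
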