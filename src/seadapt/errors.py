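"""Exception hierarchy.

``ValidationError`` subclasses ``ValueError`` so callers that only know the
standard library still catch the right thing; the CLI maps it to exit code 2.
"""


class SeadaptError(Exception):
    """Base class for package-specific errors."""


class ValidationError(SeadaptError, ValueError):
    """Input data violates a documented precondition."""


class FormatError(SeadaptError, ValueError):
    """A file on disk is not in the expected format."""


class ConfigurationError(SeadaptError, ValueError):
    """A configuration value is inconsistent or unsupported."""
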