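"""Exception hierarchy shared across the package."""


class GazelinkError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GazelinkError):
    """A file does not conform to the expected dialect (missing columns,
    non-integer offsets, malformed headers)."""


class ValidationError(GazelinkError, ValueError):
    """Well-formed input carrying invalid values (empty fields, bad spans,
    out-of-range parameters)."""


class InitializationError(GazelinkError):
    """Head initialization failed (e.g. a concept with a zero mean embedding)."""


class TrainingError(GazelinkError):
    """Training diverged or produced non-finite loss."""
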