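"""Exception hierarchy shared across the package."""


class CleftDnmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CleftDnmError):
    """Bad run configuration: missing samples, inconsistent pedigree, etc."""


class ParseError(CleftDnmError):
    """Malformed input file content.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(CleftDnmError):
    """Semantically invalid data (e.g. allele frequency outside [0, 1])."""


class InsufficientDataError(CleftDnmError):
    """A metric was requested on too little data to be meaningful."""
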