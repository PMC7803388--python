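"""Exception hierarchy shared across the pipeline stages."""


class CloneSiteError(Exception):
    """Base class for all package errors."""


class SamParseError(CloneSiteError, ValueError):
    """A SAM record line could not be decoded."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class MalformedCigarError(SamParseError):
    """CIGAR string violates syntax or clip-placement rules."""


class ReferenceMismatchError(CloneSiteError, ValueError):
    """An alignment or SA entry names a scaffold absent from the reference."""


class InconsistentEvidenceError(CloneSiteError, ValueError):
    """Split-read geometry contradicts the stated junction side."""


class PlacementError(CloneSiteError, ValueError):
    """A planted junction leaves no room to place reads inside the scaffold."""


class ConfigurationError(CloneSiteError, ValueError):
    """Run configuration is invalid (e.g. vector scaffold missing from header)."""
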