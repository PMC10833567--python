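"""Exception types shared across the package."""


class SrnadaptError(Exception):
    """Base class for all package-specific errors."""


class FastqParseError(SrnadaptError):
    """A FASTQ record could not be parsed; carries the 0-based record index."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index


class SampleSheetError(SrnadaptError):
    """Malformed sample sheet (missing columns, duplicate IDs)."""


class CatalogError(SrnadaptError):
    """Reference catalog could not be built or is unusable."""


class InsufficientSignalError(SrnadaptError):
    """Too few reads matched the reference to call an adapter.

    ``n_matched`` records how many matches were found before giving up.
    """

    def __init__(self, message: str, n_matched: int):
        super().__init__(message)
        self.n_matched = n_matched


class GenerationError(SrnadaptError):
    """Synthetic catalog generation failed (uniqueness unattainable)."""
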