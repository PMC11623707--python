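"""Exception hierarchy for mafkmers.

Every error raised by the library derives from :class:`MafKmersError` so
callers (notably the CLI) can map failures to exit codes without catching
bare ``Exception``.
"""


class MafKmersError(Exception):
    """Base class for all mafkmers errors."""


class MafParseError(MafKmersError):
    """A MAF file violated the format contract.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EncodingError(MafKmersError):
    """A k-mer contained a character outside the declared alphabet."""


class UnsupportedOperationError(MafKmersError):
    """Operation undefined for the given alphabet (e.g. peptide revcomp)."""


class CapacityError(MafKmersError):
    """The genome-ID registry ran out of identifiers."""


class UsageError(MafKmersError):
    """Invalid command-line arguments."""
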