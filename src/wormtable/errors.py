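"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`WormtableError`, so callers (and the CLI) can catch one type.
"""


class WormtableError(Exception):
    """Base class for all errors raised by wormtable."""


class SchemaError(WormtableError):
    """Invalid schema definition, XML dialect violation or unknown column."""


class EncodingError(WormtableError):
    """A value cannot be represented in its column's type/size."""


class DecodingError(WormtableError):
    """A stored row violates the format invariants (corruption)."""


class TableStateError(WormtableError):
    """Operation not valid in the table's current mode (e.g. append after
    finalise, open of a non-finalised directory)."""


class IndexingError(WormtableError):
    """Index construction or query error (name clash, embedded NUL in an
    indexed string, bad partial key)."""


class ConversionError(WormtableError):
    """Input file (VCF/GTF) could not be converted; carries a line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number
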