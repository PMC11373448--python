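"""Exception hierarchy.

All input-related failures derive from :class:`InputError` so callers
(pipeline, CLI) can collect them per file and report them together
instead of aborting on the first bad record.
"""


class VcfCompareError(Exception):
    """Base class for all package errors."""


class InputError(VcfCompareError):
    """A problem with user-supplied input data."""


class VcfFormatError(InputError):
    """Malformed VCF content (missing header, bad record fields)."""

    def __init__(self, path, message, line=None):
        self.path = str(path)
        self.line = line
        where = f"{self.path}:{line}" if line is not None else self.path
        super().__init__(f"{where}: {message}")


class FileSizeError(InputError):
    """Input file exceeds the configured size limit."""


class DecompressionError(InputError):
    """Compressed container could not be read (bad gzip, multi-member zip)."""


class BedFormatError(InputError):
    """Malformed BED content."""

    def __init__(self, path, message, line=None):
        self.path = str(path)
        self.line = line
        where = f"{self.path}:{line}" if line is not None else self.path
        super().__init__(f"{where}: {message}")


class MetadataError(InputError):
    """Metadata CSV violates the FILENAME schema or coverage contract."""


class UndefinedScoreError(VcfCompareError):
    """A similarity or benchmark ratio is undefined (empty operand set)."""


class ArityError(VcfCompareError):
    """Wrong number of sets for an operation (Venn supports 2-6)."""


class SpecError(VcfCompareError):
    """Inconsistent analysis specification (bad column names, pivot overlap)."""
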