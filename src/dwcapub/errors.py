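"""Exception hierarchy shared across the toolkit.

Every error raised by the library derives from :class:`DwcaError`, so
callers (including the CLI) can catch one base class.  Validation findings
are *not* exceptions — they travel as :class:`~dwcapub.validate.Issue`
values inside reports; exceptions are reserved for contract violations and
unusable inputs.
"""

from __future__ import annotations


class DwcaError(Exception):
    """Base class for all toolkit errors."""


class UsageError(DwcaError):
    """A caller violated a precondition (bad argument, empty name, ...)."""


class InputError(DwcaError):
    """An input file is unusable (missing, empty, undecodable)."""


class EncodingError(InputError):
    """Bytes could not be decoded under any accepted encoding."""

    def __init__(self, message: str, byte_offset: int | None = None):
        super().__init__(message)
        self.byte_offset = byte_offset


class ParseError(DwcaError):
    """Malformed delimited text or XML; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class SchemaError(DwcaError):
    """An extension-definition document violates the schema contract."""


class MappingError(DwcaError):
    """A mapping set is unusable (the row-level arity error carries its row)."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DescriptorError(DwcaError):
    """A meta.xml document or descriptor violates its invariants."""


class ArchiveError(DwcaError):
    """An archive package is structurally broken (missing members etc.)."""


class PackagingError(DwcaError):
    """Records could not be serialized into an archive."""


class JoinError(DwcaError):
    """The star join met a duplicate core ID on an unvalidated archive."""


class MetadataError(DwcaError):
    """Dataset metadata violates an invariant; names the offending field."""


class PublishError(DwcaError):
    """A publication event could not be recorded."""
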