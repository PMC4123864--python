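"""Darwin Core Archive codec: meta.xml model, packaging, reading, star join.

An archive is a zip (or an identically laid-out directory) holding one core
data file, zero or more extension data files, a structural descriptor
``meta.xml`` and a metadata document ``eml.xml``.  Extension rows relate
many-to-one to core rows through a ``coreid`` column, forming a star
schema; :func:`iter_star_records` performs that join.

Writer conventions, stated explicitly in every emitted meta.xml rather than
relying on format defaults: tab-delimited, UTF-8, LF-terminated data files
with one header line; the record identifier is always physical column 0
(``id`` in the core file, ``coreid`` in extensions), with term bindings
starting at column 1.  Zip members carry a fixed timestamp so identical
inputs produce byte-identical archives.
"""

from __future__ import annotations

import shutil
import tempfile
import zipfile
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from lxml import etree

from .errors import ArchiveError, DescriptorError, JoinError, PackagingError, ParseError
from .sources import ARCHIVE_DIALECT, Dialect, _iter_parsed, format_row
from .terms import Term

DWC_TEXT_NS = "http://rs.tdwg.org/dwc/text/"
_NS = "{%s}" % DWC_TEXT_NS

#: meta.xml attribute defaults from the archive text format.
_FORMAT_DEFAULTS = {
    "fieldsTerminatedBy": ",",
    "fieldsEnclosedBy": '"',
    "linesTerminatedBy": "\n",
    "ignoreHeaderLines": "0",
    "encoding": "UTF-8",
}

#: zip member timestamp pinned for reproducible bytes
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


@dataclass(frozen=True)
class ColumnBinding:
    """One data-file column bound to a term, with an optional default."""

    index: int
    term: Term
    default: str | None = None

    def __post_init__(self):
        if self.index < 0:
            raise DescriptorError("binding index must be non-negative")


@dataclass(frozen=True)
class FileDescriptor:
    """Descriptor of one data file: location, row type, dialect, bindings."""

    location: str
    row_type: str
    dialect: Dialect
    id_column: int = 0
    bindings: tuple[ColumnBinding, ...] = ()

    def __post_init__(self):
        if self.id_column < 0:
            raise DescriptorError("id column must be non-negative")
        if not self.location:
            raise DescriptorError("file descriptor lacks a location")


@dataclass(frozen=True)
class ArchiveDescriptor:
    """The meta.xml model: one core plus its extensions."""

    core: FileDescriptor
    extensions: tuple[FileDescriptor, ...] = ()
    metadata_location: str = "eml.xml"

    def __post_init__(self):
        locations = [self.core.location] + [e.location for e in self.extensions]
        if len(set(locations)) != len(locations):
            raise DescriptorError("archive locations are not unique")
        for e in self.extensions:
            if e.row_type == self.core.row_type:
                raise DescriptorError(
                    f"extension rowType duplicates the core's: {e.row_type}")


@dataclass
class StarRecord:
    """One core record with its extension rows grouped by row type."""

    core_id: str
    core_values: dict  # Term -> str
    extension_rows: dict = dc_field(default_factory=dict)  # row_type -> [dict]


# ---------------------------------------------------------------------------
# meta.xml

def _escape_ctl(s: str) -> str:
    return s.replace("\\", "\\\\").replace("\t", "\\t").replace("\r", "\\r").replace("\n", "\\n")


def _unescape_ctl(s: str) -> str:
    out, i = [], 0
    while i < len(s):
        if s[i] == "\\" and i + 1 < len(s):
            out.append({"t": "\t", "n": "\n", "r": "\r", "\\": "\\"}.get(s[i + 1], s[i + 1]))
            i += 2
        else:
            out.append(s[i])
            i += 1
    return "".join(out)


def _file_element(parent, tag: str, fd: FileDescriptor) -> None:
    d = fd.dialect
    el = etree.SubElement(parent, _NS + tag)
    el.set("rowType", fd.row_type)
    el.set("fieldsTerminatedBy", _escape_ctl(d.field_delimiter))
    el.set("fieldsEnclosedBy", d.quote_character or "")
    el.set("linesTerminatedBy", _escape_ctl(d.line_terminator))
    el.set("ignoreHeaderLines", str(d.header_lines))
    el.set("encoding", d.encoding.upper())
    files = etree.SubElement(el, _NS + "files")
    etree.SubElement(files, _NS + "location").text = fd.location
    idtag = "id" if tag == "core" else "coreid"
    etree.SubElement(el, _NS + idtag).set("index", str(fd.id_column))
    for b in fd.bindings:
        f = etree.SubElement(el, _NS + "field")
        f.set("index", str(b.index))
        f.set("term", b.term.qualified_name)
        if b.default is not None:
            f.set("default", b.default)


def write_meta_xml(d: ArchiveDescriptor) -> str:
    """Serialize a descriptor to meta.xml text (UTF-8, pretty-printed)."""
    root = etree.Element(_NS + "archive", nsmap={None: DWC_TEXT_NS})
    root.set("metadata", d.metadata_location)
    _file_element(root, "core", d.core)
    for ext in d.extensions:
        _file_element(root, "extension", ext)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode("utf-8")


def _parse_file_element(el, tag: str) -> FileDescriptor:
    row_type = el.get("rowType")
    if not row_type:
        raise DescriptorError(f"{tag} element lacks rowType")
    attrs = dict(_FORMAT_DEFAULTS)
    for k in attrs:
        if el.get(k) is not None:
            attrs[k] = el.get(k)
    delim = _unescape_ctl(attrs["fieldsTerminatedBy"]) or ","
    quote = attrs["fieldsEnclosedBy"] or None
    term_raw = _unescape_ctl(attrs["linesTerminatedBy"])
    terminator = "\r\n" if term_raw == "\r\n" else "\n"
    dialect = Dialect(field_delimiter=delim, quote_character=quote,
                      line_terminator=terminator,
                      encoding=attrs["encoding"].lower(),
                      header_lines=int(attrs["ignoreHeaderLines"]))
    loc = el.find(f"{_NS}files/{_NS}location")
    if loc is None or not (loc.text or "").strip():
        raise DescriptorError(f"{tag} element ({row_type}) lacks files/location")
    idtag = "id" if tag == "core" else "coreid"
    id_el = el.find(_NS + idtag)
    if tag == "extension" and id_el is None:
        raise DescriptorError(f"extension {row_type} lacks a coreid element")
    id_column = int(id_el.get("index", "0")) if id_el is not None else 0
    bindings = []
    for f in el.findall(_NS + "field"):
        bindings.append(ColumnBinding(index=int(f.get("index")),
                                      term=Term.from_qualified(f.get("term")),
                                      default=f.get("default")))
    return FileDescriptor(location=loc.text.strip(), row_type=row_type,
                          dialect=dialect, id_column=id_column,
                          bindings=tuple(bindings))


def parse_meta_xml(xml_text: str | bytes) -> ArchiveDescriptor:
    """Parse meta.xml; absent optional attributes take the format defaults."""
    data = xml_text.encode("utf-8") if isinstance(xml_text, str) else xml_text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed meta.xml: {exc}", line=exc.lineno) from exc
    core_el = root.find(_NS + "core")
    if core_el is None:
        raise DescriptorError("meta.xml has no core element")
    core = _parse_file_element(core_el, "core")
    extensions = tuple(_parse_file_element(el, "extension")
                       for el in root.findall(_NS + "extension"))
    return ArchiveDescriptor(core=core, extensions=extensions,
                             metadata_location=root.get("metadata", "eml.xml"))


# ---------------------------------------------------------------------------
# packaging

def _location_for(row_type: str) -> str:
    return row_type.rstrip("/").rpartition("/")[2].lower() + ".txt"


def _normalize_stream(records) -> Iterator[tuple[str, Mapping]]:
    for rec in records:
        if hasattr(rec, "record_id"):
            yield ("" if rec.record_id is None else rec.record_id), rec.values
        else:
            rid, values = rec
            yield ("" if rid is None else rid), values


def _collect_terms(rows: list[tuple[str, Mapping]]) -> list[Term]:
    seen: dict[Term, None] = {}
    for _, values in rows:
        for t in values:
            seen.setdefault(t, None)
    return list(seen)


def _write_data_file(rows: list[tuple[str, Mapping]], terms: list[Term],
                     id_header: str, dialect: Dialect) -> str:
    lines = [format_row([id_header] + [t.simple_name for t in terms], dialect)]
    for rid, values in rows:
        lines.append(format_row([rid] + [values.get(t, "") for t in terms],
                                dialect))
    return dialect.line_terminator.join(lines) + dialect.line_terminator


def package_archive(core_records: Iterable, extension_streams: Mapping | None,
                    metadata, out_path: str | Path, *,
                    core_row_type: str,
                    core_terms: list[Term] | None = None,
                    extension_terms: Mapping | None = None,
                    dialect: Dialect = ARCHIVE_DIALECT,
                    metadata_only: bool = False) -> ArchiveDescriptor | None:
    """Write a complete archive zip; returns the descriptor used.

    ``core_records`` yields :class:`~dwcapub.mapping.StandardRecord` objects
    or ``(record_id, {Term: value})`` pairs; ``extension_streams`` maps an
    extension row type to a stream of ``(core_id, {Term: value})`` pairs.
    ``metadata`` is an :class:`~dwcapub.eml.EmlMetadata` or raw EML text.
    In a metadata-only package no data files and no meta.xml are written —
    the zip carries eml.xml alone — and ``None`` is returned.
    """
    out_path = Path(out_path)
    if isinstance(metadata, (str, bytes)):
        eml_text = metadata if isinstance(metadata, str) else metadata.decode("utf-8")
    else:
        from .eml import write_eml
        eml_text = write_eml(metadata)

    core_rows = list(_normalize_stream(core_records))
    if not core_rows and not metadata_only:
        raise PackagingError(
            "core record stream is empty; pass metadata_only=True to publish "
            "a metadata-only package")

    if metadata_only and not core_rows:
        with zipfile.ZipFile(out_path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr(zipfile.ZipInfo("eml.xml", _ZIP_DATE), eml_text)
        return None

    if core_terms is None:
        core_terms = _collect_terms(core_rows)
    core_fd = FileDescriptor(
        location=_location_for(core_row_type), row_type=core_row_type,
        dialect=dialect, id_column=0,
        bindings=tuple(ColumnBinding(i + 1, t) for i, t in enumerate(core_terms)))

    ext_fds: list[FileDescriptor] = []
    ext_payload: list[tuple[FileDescriptor, str]] = []
    for row_type, stream in (extension_streams or {}).items():
        rows = list(_normalize_stream(stream))
        for rid, _ in rows:
            if rid == "":
                raise PackagingError(
                    f"extension row for {row_type} carries an empty coreid")
        terms = (extension_terms or {}).get(row_type) or _collect_terms(rows)
        fd = FileDescriptor(
            location=_location_for(row_type), row_type=row_type,
            dialect=dialect, id_column=0,
            bindings=tuple(ColumnBinding(i + 1, t) for i, t in enumerate(terms)))
        ext_fds.append(fd)
        ext_payload.append((fd, _write_data_file(rows, terms, "coreid", dialect)))

    descriptor = ArchiveDescriptor(core=core_fd, extensions=tuple(ext_fds))
    core_text = _write_data_file(core_rows, core_terms, "id", dialect)

    with zipfile.ZipFile(out_path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(zipfile.ZipInfo(core_fd.location, _ZIP_DATE), core_text)
        for fd, text in ext_payload:
            zf.writestr(zipfile.ZipInfo(fd.location, _ZIP_DATE), text)
        zf.writestr(zipfile.ZipInfo("meta.xml", _ZIP_DATE), write_meta_xml(descriptor))
        zf.writestr(zipfile.ZipInfo("eml.xml", _ZIP_DATE), eml_text)
    return descriptor


# ---------------------------------------------------------------------------
# reading

class Archive:
    """An opened archive: parsed descriptor plus lazy data-file readers."""

    def __init__(self, root: Path, descriptor: ArchiveDescriptor,
                 tempdir: tempfile.TemporaryDirectory | None = None):
        self.root = Path(root)
        self.descriptor = descriptor
        self._tempdir = tempdir

    def data_path(self, fd: FileDescriptor) -> Path:
        return self.root / fd.location

    def iter_file(self, fd: FileDescriptor) -> Iterator[list[str]]:
        """Stream the data rows of one file (header lines skipped)."""
        with open(self.data_path(fd), "r", encoding=fd.dialect.encoding,
                  newline="") as fh:
            for i, row in enumerate(_iter_parsed(fh, fd.dialect)):
                if i >= fd.dialect.header_lines:
                    yield row

    def eml_text(self) -> str | None:
        p = self.root / self.descriptor.metadata_location
        return p.read_text(encoding="utf-8") if p.exists() else None

    def close(self) -> None:
        if self._tempdir is not None:
            self._tempdir.cleanup()
            self._tempdir = None

    def __enter__(self) -> "Archive":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_archive(path: str | Path) -> Archive:
    """Open a zip archive or an equivalent unzipped directory."""
    path = Path(path)
    tempdir = None
    if path.is_dir():
        root = path
    elif zipfile.is_zipfile(path):
        tempdir = tempfile.TemporaryDirectory(prefix="dwca_")
        root = Path(tempdir.name)
        with zipfile.ZipFile(path) as zf:
            for name in zf.namelist():
                target = root / Path(name).name  # flat layout, no traversal
                with zf.open(name) as src, open(target, "wb") as dst:
                    shutil.copyfileobj(src, dst)
    else:
        raise ArchiveError(f"not an archive zip or directory: {path}")

    meta = root / "meta.xml"
    if not meta.exists():
        if tempdir:
            tempdir.cleanup()
        raise ArchiveError(f"archive has no meta.xml: {path}")
    descriptor = parse_meta_xml(meta.read_bytes())
    for fd in (descriptor.core, *descriptor.extensions):
        if not (root / fd.location).exists():
            if tempdir:
                tempdir.cleanup()
            raise ArchiveError(
                f"descriptor references absent file: {fd.location}")
    return Archive(root, descriptor, tempdir)


def _row_values(row: list[str], fd: FileDescriptor) -> dict:
    values = {}
    for b in fd.bindings:
        v = row[b.index] if b.index < len(row) else ""
        if v == "" and b.default is not None:
            v = b.default
        values[b.term] = v
    return values


def _row_id(row: list[str], fd: FileDescriptor) -> str:
    return row[fd.id_column] if fd.id_column < len(row) else ""


def iter_star_records(archive: Archive) -> Iterator[StarRecord]:
    """Join extensions onto the core and yield one record per core row.

    Single pass over the core builds an in-memory ID index (memory is
    proportional to core row count), then extensions stream through it;
    join is exact string equality on IDs.  Extension rows whose coreid
    matches no core record are skipped here — they are validator findings,
    not reader output.  A duplicate core ID raises: the archive should have
    been validated first.
    """
    core_fd = archive.descriptor.core
    order: list[str] = []
    core_vals: dict[str, dict] = {}
    for row in archive.iter_file(core_fd):
        rid = _row_id(row, core_fd)
        if rid in core_vals:
            raise JoinError(f"duplicate core ID during join: {rid!r}")
        core_vals[rid] = _row_values(row, core_fd)
        order.append(rid)

    grouped: dict[str, dict[str, list[dict]]] = {rid: {} for rid in order}
    for ext_fd in archive.descriptor.extensions:
        for row in archive.iter_file(ext_fd):
            cid = _row_id(row, ext_fd)
            bucket = grouped.get(cid)
            if bucket is None:
                continue  # orphan: reported by the validator
            bucket.setdefault(ext_fd.row_type, []).append(_row_values(row, ext_fd))

    for rid in order:
        yield StarRecord(core_id=rid, core_values=core_vals[rid],
                         extension_rows=grouped[rid])
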