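"""Dataset metadata: an EML subset, data-paper export, summary page.

The modeled subset is the dataset-level profile a publishing tool actually
populates — title, creators, abstract, rights, keywords, geographic /
taxonomic / temporal coverage, methods, citation, language — not full EML.
Dublin Core documents are accepted on read and mapped into the same type,
but metadata is always written as EML, the richer of the two.  Unknown
elements inside ``dataset`` are preserved opaquely so re-serialization
never loses foreign content.

The data-paper exporter turns the metadata into a manuscript skeleton with
a fixed eleven-section order; empty optional sections are emitted with a
placeholder so authors see what remains to write.
"""

from __future__ import annotations

import html
from dataclasses import dataclass
from typing import Iterable

from lxml import etree

from .errors import MetadataError, ParseError

EML_NS = "eml://ecoinformatics.org/eml-2.1.1"
_DC_NSES = ("http://purl.org/dc/elements/1.1/", "http://purl.org/dc/terms/")

PLACEHOLDER = "[to be completed]"

DATA_PAPER_SECTIONS = (
    "Title", "Authors", "Abstract", "Keywords", "Taxonomic Coverage",
    "Geographic Coverage", "Temporal Coverage", "Methods",
    "Dataset Description", "Rights", "References",
)


@dataclass(frozen=True)
class Creator:
    name: str
    organization: str = ""
    email: str = ""


@dataclass(frozen=True)
class BoundingBox:
    west: float
    east: float
    south: float
    north: float


@dataclass(frozen=True)
class GeographicCoverage:
    description: str = ""
    bounding_box: BoundingBox | None = None


@dataclass(frozen=True)
class TemporalCoverage:
    start: str = ""  # ISO 8601 dates
    end: str = ""


@dataclass(frozen=True)
class EmlMetadata:
    """The dataset-metadata record carried inside eml.xml."""

    title: str
    creators: tuple[Creator, ...]
    abstract: str = ""
    rights: str = ""
    keywords: tuple[str, ...] = ()
    geographic_coverage: GeographicCoverage | None = None
    taxonomic_coverage: tuple[tuple[str, str], ...] = ()  # (rank, name)
    temporal_coverage: TemporalCoverage | None = None
    methods: str = ""
    citation: str = ""
    language: str = ""
    extras: tuple[str, ...] = ()  # serialized foreign dataset elements


@dataclass(frozen=True)
class DatasetStats:
    """Facts about the packaged data used by the exporter's description."""

    record_count: int = 0
    core_row_type: str = ""
    extensions: tuple[tuple[str, int], ...] = ()  # (row_type, row count)


def validate_metadata(m: EmlMetadata) -> None:
    if not m.title or not m.title.strip():
        raise MetadataError("metadata invariant violated: title is empty")
    if not m.creators:
        raise MetadataError("metadata invariant violated: creators is empty")
    bb = m.geographic_coverage.bounding_box if m.geographic_coverage else None
    if bb is not None:
        if not (-180 <= bb.west <= bb.east <= 180):
            raise MetadataError(
                "geographic_coverage: need -180 <= west <= east <= 180")
        if not (-90 <= bb.south <= bb.north <= 90):
            raise MetadataError(
                "geographic_coverage: need -90 <= south <= north <= 90")


# ---------------------------------------------------------------------------
# writer

def _sub(parent, tag: str, text: str | None = None):
    el = etree.SubElement(parent, tag)
    if text is not None:
        el.text = text
    return el


def write_eml(m: EmlMetadata) -> str:
    """Serialize to an EML document; absent optional fields are omitted."""
    validate_metadata(m)
    root = etree.Element("{%s}eml" % EML_NS, nsmap={"eml": EML_NS})
    root.set("scope", "system")
    root.set("system", "dwcapub")
    ds = _sub(root, "dataset")
    _sub(ds, "title", m.title)
    for c in m.creators:
        cr = _sub(ds, "creator")
        _sub(_sub(cr, "individualName"), "surName", c.name)
        if c.organization:
            _sub(cr, "organizationName", c.organization)
        if c.email:
            _sub(cr, "electronicMailAddress", c.email)
    if m.language:
        _sub(ds, "language", m.language)
    if m.abstract:
        _sub(_sub(ds, "abstract"), "para", m.abstract)
    if m.keywords:
        ks = _sub(ds, "keywordSet")
        for k in m.keywords:
            _sub(ks, "keyword", k)
    if m.rights:
        _sub(_sub(ds, "intellectualRights"), "para", m.rights)
    if m.geographic_coverage or m.temporal_coverage or m.taxonomic_coverage:
        cov = _sub(ds, "coverage")
        g = m.geographic_coverage
        if g is not None:
            ge = _sub(cov, "geographicCoverage")
            _sub(ge, "geographicDescription", g.description)
            if g.bounding_box is not None:
                bc = _sub(ge, "boundingCoordinates")
                _sub(bc, "westBoundingCoordinate", repr(g.bounding_box.west))
                _sub(bc, "eastBoundingCoordinate", repr(g.bounding_box.east))
                _sub(bc, "northBoundingCoordinate", repr(g.bounding_box.north))
                _sub(bc, "southBoundingCoordinate", repr(g.bounding_box.south))
        t = m.temporal_coverage
        if t is not None:
            rd = _sub(_sub(cov, "temporalCoverage"), "rangeOfDates")
            _sub(_sub(rd, "beginDate"), "calendarDate", t.start)
            _sub(_sub(rd, "endDate"), "calendarDate", t.end)
        if m.taxonomic_coverage:
            tx = _sub(cov, "taxonomicCoverage")
            for rank, name in m.taxonomic_coverage:
                tc = _sub(tx, "taxonomicClassification")
                _sub(tc, "taxonRankName", rank)
                _sub(tc, "taxonRankValue", name)
    if m.methods:
        _sub(_sub(_sub(_sub(ds, "methods"), "methodStep"), "description"),
             "para", m.methods)
    for extra in m.extras:
        el = etree.fromstring(extra.encode("utf-8"))
        el.tail = None
        ds.append(el)
    if m.citation:
        _sub(_sub(_sub(root, "additionalMetadata"), "metadata"),
             "citation", m.citation)
    return etree.tostring(root, xml_declaration=True,
                          encoding="UTF-8").decode("utf-8")


# ---------------------------------------------------------------------------
# parser

_KNOWN_DATASET_TAGS = {
    "title", "creator", "language", "abstract", "keywordSet",
    "intellectualRights", "coverage", "methods",
}


def _text(el, path: str) -> str:
    hit = el.find(path)
    return (hit.text or "") if hit is not None else ""


def _parse_creator(el) -> Creator:
    name = _text(el, "individualName/surName") or _text(el, "organizationName")
    return Creator(name=name,
                   organization=_text(el, "organizationName"),
                   email=_text(el, "electronicMailAddress"))


def parse_eml(xml_text: str | bytes) -> EmlMetadata:
    """Parse an EML (or Dublin Core) document into :class:`EmlMetadata`."""
    data = xml_text.encode("utf-8") if isinstance(xml_text, str) else xml_text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed metadata document: {exc}",
                         line=exc.lineno) from exc
    if etree.QName(root).localname != "eml":
        return _parse_dublin_core(root)
    ds = root.find("dataset")
    if ds is None:
        raise MetadataError("EML document has no dataset section")
    title = _text(ds, "title")
    if not title:
        raise MetadataError("metadata has no title")
    creators = tuple(_parse_creator(c) for c in ds.findall("creator"))
    keywords = tuple((k.text or "") for k in ds.findall("keywordSet/keyword"))

    geographic = None
    ge = ds.find("coverage/geographicCoverage")
    if ge is not None:
        bb = None
        bc = ge.find("boundingCoordinates")
        if bc is not None:
            bb = BoundingBox(
                west=float(_text(bc, "westBoundingCoordinate")),
                east=float(_text(bc, "eastBoundingCoordinate")),
                south=float(_text(bc, "southBoundingCoordinate")),
                north=float(_text(bc, "northBoundingCoordinate")))
        geographic = GeographicCoverage(
            description=_text(ge, "geographicDescription"), bounding_box=bb)

    temporal = None
    rd = ds.find("coverage/temporalCoverage/rangeOfDates")
    if rd is not None:
        temporal = TemporalCoverage(start=_text(rd, "beginDate/calendarDate"),
                                    end=_text(rd, "endDate/calendarDate"))

    taxonomic = tuple(
        (_text(tc, "taxonRankName"), _text(tc, "taxonRankValue"))
        for tc in ds.findall("coverage/taxonomicCoverage/taxonomicClassification"))

    extras = []
    for child in ds:
        if not isinstance(child.tag, str):
            continue
        if etree.QName(child).localname not in _KNOWN_DATASET_TAGS:
            clone = etree.fromstring(etree.tostring(child))
            clone.tail = None
            extras.append(etree.tostring(clone).decode("utf-8"))

    return EmlMetadata(
        title=title,
        creators=creators,
        abstract=_text(ds, "abstract/para") or _text(ds, "abstract"),
        rights=_text(ds, "intellectualRights/para") or _text(ds, "intellectualRights"),
        keywords=keywords,
        geographic_coverage=geographic,
        taxonomic_coverage=taxonomic,
        temporal_coverage=temporal,
        methods=_text(ds, "methods/methodStep/description/para"),
        citation=_text(root, "additionalMetadata/metadata/citation"),
        language=_text(ds, "language"),
        extras=tuple(extras),
    )


def _parse_dublin_core(root) -> EmlMetadata:
    """Map a flat Dublin Core record onto the same metadata type."""
    found: dict[str, list[str]] = {}
    for el in root.iter():
        if not isinstance(el.tag, str):
            continue
        q = etree.QName(el)
        if q.namespace in _DC_NSES and el.text:
            found.setdefault(q.localname, []).append(el.text)
    title = (found.get("title") or [""])[0]
    if not title:
        raise MetadataError("metadata has no title")
    creators = tuple(Creator(name=n) for n in found.get("creator", []))
    if not creators:
        raise MetadataError("metadata has no creator")
    return EmlMetadata(
        title=title, creators=creators,
        abstract=(found.get("description") or [""])[0],
        rights=(found.get("rights") or [""])[0],
        language=(found.get("language") or [""])[0])


# ---------------------------------------------------------------------------
# data-paper export

def _section(name: str, body: str) -> str:
    return f"## {name}\n\n{body.strip() or PLACEHOLDER}\n"


def export_data_paper(m: EmlMetadata, stats: DatasetStats | None = None) -> str:
    """Render a data-paper manuscript draft with the fixed 11 sections.

    The output is portable structured text (Markdown headings); every
    section is always present, with a placeholder when the metadata lacks
    the content, so the skeleton can go straight to manuscript editing.
    """
    validate_metadata(m)
    stats = stats or DatasetStats()
    authors = "; ".join(
        c.name + (f" ({c.organization})" if c.organization else "")
        for c in m.creators)
    taxonomic = "\n".join(f"- {rank}: {name}"
                          for rank, name in m.taxonomic_coverage)
    geographic = ""
    if m.geographic_coverage:
        g = m.geographic_coverage
        geographic = g.description
        if g.bounding_box:
            b = g.bounding_box
            geographic += (f"\n\nBounding box: {b.west} W to {b.east} E, "
                           f"{b.south} S to {b.north} N (decimal degrees).")
    temporal = ""
    if m.temporal_coverage:
        temporal = f"{m.temporal_coverage.start} to {m.temporal_coverage.end}"
    description = ""
    if stats.core_row_type:
        description = (f"The dataset comprises {stats.record_count} records "
                       f"of core type {stats.core_row_type}.")
        for row_type, n in stats.extensions:
            description += f"\nExtension {row_type}: {n} rows."
    bodies = (
        m.title, authors, m.abstract, ", ".join(m.keywords), taxonomic,
        geographic, temporal, m.methods, description, m.rights, m.citation,
    )
    return "\n".join(_section(name, body)
                     for name, body in zip(DATA_PAPER_SECTIONS, bodies))


# ---------------------------------------------------------------------------
# summary page

def default_citation(m: EmlMetadata, version_number: int, year: int) -> str:
    names = ", ".join(c.name for c in m.creators)
    return f"{names} ({year}). {m.title}. Version {version_number}."


def render_summary_page(m: EmlMetadata, descriptor,
                        versions: Iterable) -> str:
    """Render the self-contained HTML summary page for a published resource.

    ``versions`` are the resource's published versions (newest shown
    first); the latest one provides the download link.  With no citation in
    the metadata a fallback of the form "creators (year). title. version."
    is composed.
    """
    validate_metadata(m)
    versions = sorted(versions, key=lambda v: v.version_number, reverse=True)
    if not versions:
        raise MetadataError("cannot render a summary page with no "
                            "published version")
    latest = versions[0]
    e = html.escape
    citation = m.citation or default_citation(
        m, latest.version_number, latest.timestamp.year)
    rows = "\n".join(
        f"<tr><td>{v.version_number}</td>"
        f"<td>{e(v.timestamp.date().isoformat())}</td>"
        f"<td>{v.record_count}</td>"
        f"<td><a href=\"{e(str(v.archive_path))}\">archive</a></td></tr>"
        for v in versions)
    core_line = ""
    if descriptor is not None:
        exts = ", ".join(x.row_type for x in descriptor.extensions) or "none"
        core_line = (f"<p>Core type: <code>{e(descriptor.core.row_type)}</code>"
                     f" &middot; extensions: <code>{e(exts)}</code></p>")
    creators = "; ".join(
        e(c.name + (f" ({c.organization})" if c.organization else ""))
        for c in m.creators)
    return f"""<!DOCTYPE html>
<html lang="{e(m.language or 'en')}">
<head><meta charset="utf-8"><title>{e(m.title)}</title>
<style>body{{font-family:sans-serif;max-width:50em;margin:2em auto}}
table{{border-collapse:collapse}}td,th{{border:1px solid #999;padding:.3em .6em}}</style>
</head>
<body>
<h1>{e(m.title)}</h1>
<p>{creators}</p>
<p>{e(m.abstract)}</p>
{core_line}
<p><strong>Download latest version:</strong>
<a href="{e(str(latest.archive_path))}">version {latest.version_number}</a>
({latest.record_count} records)</p>
<h2>Citation</h2>
<blockquote>{e(citation)}</blockquote>
<h2>Version history</h2>
<table>
<tr><th>Version</th><th>Published</th><th>Records</th><th>Archive</th></tr>
{rows}
</table>
<h2>Rights</h2>
<p>{e(m.rights) or PLACEHOLDER}</p>
</body>
</html>
"""
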