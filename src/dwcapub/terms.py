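"""Darwin Core term registry.

Holds the vocabulary entries (:class:`Term`), the ordered term sets for a
row type (:class:`Schema`), the two built-in cores — Occurrence and Taxon —
plus the bundled Simple Multimedia extension, and a parser for
extension-definition documents in the GBIF resource-registry XML style
(a root element carrying a ``rowType`` attribute and repeated ``property``
elements carrying a qualified term name).

The bundled core/extension files live under ``dwcapub/data`` so the
registry works with no network access; their term membership is a fixture
of this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from lxml import etree

from .errors import ParseError, SchemaError, UsageError

log = logging.getLogger(__name__)

#: Row-type URIs of the two cores and their record-identifier terms.
OCCURRENCE_ROW_TYPE = "http://rs.tdwg.org/dwc/terms/Occurrence"
TAXON_ROW_TYPE = "http://rs.tdwg.org/dwc/terms/Taxon"
MULTIMEDIA_ROW_TYPE = "http://rs.gbif.org/terms/1.0/Multimedia"

_CORE_ID_TERMS = {
    OCCURRENCE_ROW_TYPE: "occurrenceID",
    TAXON_ROW_TYPE: "taxonID",
}

_BUNDLED_FILES = ("dwc_occurrence.xml", "dwc_taxon.xml", "simple_multimedia.xml")


def _split_qualified(qualified_name: str) -> tuple[str, str]:
    """Split a term URI into (namespace, simple name) at the last / or #."""
    for sep in ("#", "/"):
        if sep in qualified_name:
            ns, _, simple = qualified_name.rpartition(sep)
            return ns + sep, simple
    return "", qualified_name


@dataclass(frozen=True)
class Term:
    """One vocabulary entry: a qualified URI plus its short simple name.

    Two terms are equal iff their qualified names are equal; the simple
    name and namespace are derived views of the URI.
    """

    qualified_name: str
    simple_name: str
    namespace: str

    @classmethod
    def from_qualified(cls, qualified_name: str) -> "Term":
        ns, simple = _split_qualified(qualified_name)
        if not simple or any(c.isspace() for c in simple):
            raise SchemaError(f"invalid term name: {qualified_name!r}")
        return cls(qualified_name, simple, ns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Term):
            return NotImplemented
        return self.qualified_name == other.qualified_name

    def __hash__(self) -> int:
        return hash(self.qualified_name)

    def __repr__(self) -> str:  # concise in reports
        return f"Term({self.simple_name!r})"


@dataclass(frozen=True)
class Schema:
    """An ordered term set for one row type (a core or an extension)."""

    row_type: str
    terms: tuple[Term, ...]
    id_term: Term | None = None
    is_core: bool = False
    title: str = ""
    _by_qualified: dict = field(default=None, repr=False, compare=False, hash=False)

    def __post_init__(self):
        seen: dict[str, Term] = {}
        for t in self.terms:
            if t.qualified_name in seen:
                raise SchemaError(
                    f"duplicate term in schema {self.row_type}: {t.qualified_name}"
                )
            seen[t.qualified_name] = t
        if self.id_term is not None and self.id_term not in self.terms:
            raise SchemaError(
                f"id term {self.id_term.qualified_name} is not a member of "
                f"schema {self.row_type}"
            )
        object.__setattr__(self, "_by_qualified", seen)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


def lookup_term(name: str, schema: Schema) -> Term | None:
    """Resolve ``name`` within ``schema``; ``None`` when not found.

    Exact qualified-name matches win; otherwise the simple name is matched
    case-insensitively.  When several namespaces share a simple name the
    first term in schema order is returned and the ambiguity is logged.
    """
    if not name:
        raise UsageError("term name must be non-empty")
    hit = schema._by_qualified.get(name)
    if hit is not None:
        return hit
    folded = name.casefold()
    matches = [t for t in schema.terms if t.simple_name.casefold() == folded]
    if not matches:
        return None
    if len(matches) > 1:
        log.warning(
            "simple name %r is ambiguous in %s (%d candidates); using %s",
            name, schema.row_type, len(matches), matches[0].qualified_name,
        )
    return matches[0]


def parse_extension_definition(xml_text: str | bytes) -> Schema:
    """Parse a GBIF-style extension-definition document into a Schema.

    The root element must declare a ``rowType`` attribute; each child
    ``property`` element must declare a qualified term name (``qualName``).
    Terms keep document order.  Unknown attributes are ignored with a log
    line; a duplicated term or a missing rowType is a schema error.
    """
    data = xml_text.encode("utf-8") if isinstance(xml_text, str) else xml_text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed extension definition: {exc}",
                         line=exc.lineno) from exc

    row_type = root.get("rowType")
    if not row_type:
        raise SchemaError("extension definition lacks a rowType attribute")
    title = root.get("title", "")

    known_attrs = {"qualName", "name", "namespace", "required", "group",
                   "thesaurus", "description", "examples", "type"}
    terms: list[Term] = []
    seen: set[str] = set()
    for el in root:
        if not isinstance(el.tag, str) or etree.QName(el).localname != "property":
            continue
        qual = el.get("qualName")
        if not qual:
            raise SchemaError("property element lacks a qualName attribute")
        for attr in el.attrib:
            if attr not in known_attrs:
                log.info("ignoring unknown property attribute %r on %s", attr, qual)
        if qual in seen:
            raise SchemaError(f"term listed twice in definition: {qual}")
        seen.add(qual)
        terms.append(Term.from_qualified(qual))

    schema = Schema(row_type=row_type, terms=tuple(terms), title=title)
    id_simple = _CORE_ID_TERMS.get(row_type)
    if id_simple is not None:
        id_term = lookup_term(id_simple, schema)
        return Schema(row_type=row_type, terms=tuple(terms), id_term=id_term,
                      is_core=True, title=title)
    return schema


@lru_cache(maxsize=1)
def _load_builtins() -> tuple[Schema, ...]:
    out = []
    for fname in _BUNDLED_FILES:
        text = resources.files("dwcapub.data").joinpath(fname).read_bytes()
        out.append(parse_extension_definition(text))
    return tuple(out)


def builtin_schemas() -> list[Schema]:
    """The bundled schemas: Occurrence Core, Taxon Core, Simple Multimedia."""
    return list(_load_builtins())


def get_schema(row_type: str) -> Schema:
    """Fetch a bundled schema by row-type URI or by a short alias
    (``occurrence``, ``taxon``, ``multimedia``)."""
    alias = {
        "occurrence": OCCURRENCE_ROW_TYPE,
        "taxon": TAXON_ROW_TYPE,
        "multimedia": MULTIMEDIA_ROW_TYPE,
    }.get(row_type.lower(), row_type)
    for s in builtin_schemas():
        if s.row_type == alias:
            return s
    raise UsageError(f"no bundled schema for row type {row_type!r}")
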