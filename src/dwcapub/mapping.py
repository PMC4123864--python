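"""Binding source columns to Darwin Core terms.

Auto-matching follows the same-name rule: a source header maps to a term
exactly when the two names agree after case-folding and removal of spaces
and underscores — nothing fuzzier, so a column is never silently mis-mapped.
Unmatched headers are reported, not guessed.  Mappings can also bind a term
to a constant value (applied to every record) and carry a per-term default
used when the bound column is empty.

A mapping set is persisted as a small YAML document so publish runs are
reproducible from config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import MappingError, UsageError
from .terms import Schema, Term, get_schema, lookup_term


def normalize_name(name: str) -> str:
    """Normal form used for auto-matching: case-fold, drop spaces/underscores."""
    return name.strip().casefold().replace(" ", "").replace("_", "")


@dataclass(frozen=True)
class FieldMapping:
    """One term bound to either a source column or a constant value."""

    term: Term
    column: int | None = None
    constant: str | None = None
    default: str | None = None

    def __post_init__(self):
        if (self.column is None) == (self.constant is None):
            raise MappingError(
                f"mapping for {self.term.simple_name} must have exactly one "
                "of a column index or a constant value"
            )
        if self.constant is not None and self.default is not None:
            raise MappingError(
                f"constant mapping for {self.term.simple_name} cannot carry "
                "a default value"
            )


@dataclass
class MappingSet:
    """All bindings for one schema, plus the record-identifier column."""

    schema: Schema
    mappings: list[FieldMapping] = field(default_factory=list)
    id_source: int | None = None
    n_columns: int | None = None
    unmapped: tuple[str, ...] = ()


@dataclass(frozen=True)
class MappingIssue:
    kind: str          # duplicate_term | column_range | missing_id | empty_constant
    severity: str      # "error" | "warning"
    detail: str


@dataclass(frozen=True)
class StandardRecord:
    """One source row projected onto Darwin Core terms."""

    record_id: str | None
    values: dict  # Term -> str


def auto_map(headers: list[str] | tuple[str, ...], schema: Schema) -> MappingSet:
    """Map every header whose normalized name equals a term's simple name.

    When the schema's record-identifier term is among the matches, its
    column doubles as the structural ID column (``id_source``).
    """
    by_norm: dict[str, Term] = {}
    for t in schema.terms:
        by_norm.setdefault(normalize_name(t.simple_name), t)
    mappings: list[FieldMapping] = []
    unmapped: list[str] = []
    id_source = None
    for idx, header in enumerate(headers):
        term = by_norm.get(normalize_name(header))
        if term is None:
            unmapped.append(header)
            continue
        mappings.append(FieldMapping(term=term, column=idx))
        if schema.id_term is not None and term == schema.id_term:
            id_source = idx
    return MappingSet(schema=schema, mappings=mappings, id_source=id_source,
                      n_columns=len(headers), unmapped=tuple(unmapped))


def validate_mapping(ms: MappingSet, *, metadata_only: bool = False) -> list[MappingIssue]:
    """Collect mapping problems as data; never raises.

    A missing ID column is an error for core-data publication and only a
    warning for a metadata-only one.
    """
    issues: list[MappingIssue] = []
    seen: set[str] = set()
    for m in ms.mappings:
        if m.term.qualified_name in seen:
            issues.append(MappingIssue(
                "duplicate_term", "error",
                f"term {m.term.simple_name} is bound more than once"))
        seen.add(m.term.qualified_name)
        if m.term not in ms.schema.terms:
            issues.append(MappingIssue(
                "foreign_term", "error",
                f"term {m.term.simple_name} does not belong to schema "
                f"{ms.schema.row_type}"))
        if m.column is not None and ms.n_columns is not None and not (
                0 <= m.column < ms.n_columns):
            issues.append(MappingIssue(
                "column_range", "error",
                f"column {m.column} for {m.term.simple_name} is outside the "
                f"{ms.n_columns}-column source"))
        if m.constant is not None and m.constant == "":
            issues.append(MappingIssue(
                "empty_constant", "error",
                f"constant mapping for {m.term.simple_name} is empty"))
    if ms.schema.id_term is not None and ms.id_source is None:
        issues.append(MappingIssue(
            "missing_id", "warning" if metadata_only else "error",
            f"no record-identifier column designated although the schema "
            f"defines {ms.schema.id_term.simple_name}"))
    if (ms.id_source is not None and ms.n_columns is not None
            and not 0 <= ms.id_source < ms.n_columns):
        issues.append(MappingIssue(
            "column_range", "error",
            f"id column {ms.id_source} is outside the source"))
    return issues


def apply_mapping(row: list[str], ms: MappingSet,
                  row_number: int | None = None) -> StandardRecord:
    """Project one source row onto the mapped terms.

    Empty bound fields fall back to the mapping's default when one is set;
    the record ID is taken verbatim (no trimming) from the ID column.
    """
    values: dict[Term, str] = {}
    for m in ms.mappings:
        if m.constant is not None:
            values[m.term] = m.constant
            continue
        if m.column >= len(row):
            raise MappingError(
                f"row has {len(row)} fields but column {m.column} is mapped "
                f"to {m.term.simple_name}"
                + (f" (row {row_number})" if row_number is not None else ""),
                row=row_number)
        v = row[m.column]
        if v == "" and m.default is not None:
            v = m.default
        values[m.term] = v
    record_id = None
    if ms.id_source is not None:
        if ms.id_source >= len(row):
            raise MappingError(
                f"row has {len(row)} fields but the id column is {ms.id_source}"
                + (f" (row {row_number})" if row_number is not None else ""),
                row=row_number)
        record_id = row[ms.id_source]
    return StandardRecord(record_id=record_id, values=values)


# ---------------------------------------------------------------------------
# persistence

def mapping_to_dict(ms: MappingSet) -> dict:
    return {
        "rowType": ms.schema.row_type,
        "idColumn": ms.id_source,
        "columns": ms.n_columns,
        "fields": [
            {
                "term": m.term.qualified_name,
                **({"column": m.column} if m.column is not None else {}),
                **({"constant": m.constant} if m.constant is not None else {}),
                **({"default": m.default} if m.default is not None else {}),
            }
            for m in ms.mappings
        ],
    }


def mapping_from_dict(doc: dict, schema: Schema | None = None) -> MappingSet:
    if "rowType" not in doc:
        raise UsageError("mapping config lacks a rowType")
    if schema is None:
        schema = get_schema(doc["rowType"])
    mappings = []
    for f in doc.get("fields", []):
        term = lookup_term(f["term"], schema)
        if term is None:
            raise MappingError(f"unknown term in mapping config: {f['term']}")
        mappings.append(FieldMapping(
            term=term, column=f.get("column"), constant=f.get("constant"),
            default=f.get("default")))
    return MappingSet(schema=schema, mappings=mappings,
                      id_source=doc.get("idColumn"),
                      n_columns=doc.get("columns"))


def save_mapping(ms: MappingSet, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(mapping_to_dict(ms), fh, sort_keys=False,
                       allow_unicode=True)


def load_mapping(path: str, schema: Schema | None = None) -> MappingSet:
    with open(path, "r", encoding="utf-8") as fh:
        return mapping_from_dict(yaml.safe_load(fh), schema)
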