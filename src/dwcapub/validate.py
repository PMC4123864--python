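"""Publication-blocking validation and data-quality flagging.

Three kinds of structural checks guard an archive before it is published:
record-identifier uniqueness/presence (the halt rule — a dataset with a
missing or duplicated occurrenceID/taxonID must not be published), row
arity, and extension referential integrity (every extension row must point
at an existing core record).  A fourth, advisory check flags values that
stray from a controlled vocabulary — the classic example being the many
spellings of "United States" in a country field — and suggests the
canonical form without ever rewriting the data.

ID equality is exact string comparison: identifiers are opaque, and
normalizing them would mask exactly the publisher errors these checks are
meant to surface.  All issues are collected before the verdict is
rendered, so a halting report is still a complete, actionable one.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from .errors import UsageError

ERROR = "error"
WARNING = "warning"

MISSING_ID = "missing_id"
DUPLICATE_ID = "duplicate_id"
ORPHAN_EXTENSION_ROW = "orphan_extension_row"
ARITY_MISMATCH = "arity_mismatch"
VOCABULARY_FLAG = "vocabulary_flag"


@dataclass(frozen=True)
class Issue:
    """One validation finding, locatable to a file and row."""

    kind: str
    severity: str
    location: tuple[str, int | None]
    detail: str
    value: str | None = None


@dataclass
class ValidationReport:
    """A list of issues plus per-kind counts and a pass/halt verdict."""

    issues: list[Issue] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        c: Counter = Counter(i.kind for i in self.issues)
        return dict(c)

    @property
    def verdict(self) -> str:
        return "halt" if any(i.severity == ERROR for i in self.issues) else "pass"

    def extend(self, other: "ValidationReport") -> "ValidationReport":
        self.issues.extend(other.issues)
        return self

    def digest(self) -> dict:
        return {"verdict": self.verdict, "counts": self.counts,
                "n_issues": len(self.issues)}


def check_record_ids(ids: Iterable[str], filename: str = "core") -> ValidationReport:
    """Flag empty/whitespace-only IDs and every row involved in a duplicate.

    An ID occurring k >= 2 times yields k issues (one per involved row, the
    first occurrence included), so the report points at every row a
    publisher must fix.  Single streaming pass; memory is proportional to
    the number of distinct IDs.
    """
    report = ValidationReport()
    first_row: dict[str, int] = {}
    flagged: set[str] = set()
    for row_no, rid in enumerate(ids, start=1):
        if rid.strip() == "":
            report.issues.append(Issue(
                MISSING_ID, ERROR, (filename, row_no),
                "record has no identifier", value=rid))
            continue
        if rid in flagged:
            report.issues.append(Issue(
                DUPLICATE_ID, ERROR, (filename, row_no),
                f"identifier {rid!r} occurs more than once", value=rid))
        elif rid in first_row:
            flagged.add(rid)
            for r in (first_row[rid], row_no):
                report.issues.append(Issue(
                    DUPLICATE_ID, ERROR, (filename, r),
                    f"identifier {rid!r} occurs more than once", value=rid))
        else:
            first_row[rid] = row_no
    return report


def check_coreids(coreids: Iterable[str], core_ids: set[str],
                  filename: str = "extension") -> ValidationReport:
    """Flag extension coreids that are empty (error) or unresolvable
    (warning) against the set of core record IDs."""
    report = ValidationReport()
    for row_no, cid in enumerate(coreids, start=1):
        if cid == "":
            report.issues.append(Issue(
                ORPHAN_EXTENSION_ROW, ERROR, (filename, row_no),
                "extension row has an empty coreid", value=cid))
        elif cid not in core_ids:
            report.issues.append(Issue(
                ORPHAN_EXTENSION_ROW, WARNING, (filename, row_no),
                f"coreid {cid!r} matches no core record", value=cid))
    return report


def check_extension_integrity(archive) -> ValidationReport:
    """Verify every extension row's coreid resolves to a core record.

    A coreid matching no core ID is a warning (the row is unusable but the
    archive still makes sense); an empty coreid is an error (the row is
    structurally meaningless) and halts publication.
    """
    report = ValidationReport()
    core_fd = archive.descriptor.core
    core_ids = {row[core_fd.id_column] if core_fd.id_column < len(row) else ""
                for row in archive.iter_file(core_fd)}
    for ext_fd in archive.descriptor.extensions:
        coreids = (row[ext_fd.id_column] if ext_fd.id_column < len(row) else ""
                   for row in archive.iter_file(ext_fd))
        report.extend(check_coreids(coreids, core_ids, ext_fd.location))
    return report


def check_row_arity(rows: Iterable[list[str]], expected_arity: int,
                    filename: str = "core") -> ValidationReport:
    """Flag every row whose field count differs from the header's."""
    if expected_arity < 1:
        raise UsageError("expected arity must be >= 1")
    report = ValidationReport()
    for row_no, row in enumerate(rows, start=1):
        if len(row) != expected_arity:
            report.issues.append(Issue(
                ARITY_MISMATCH, ERROR, (filename, row_no),
                f"row has {len(row)} fields, expected {expected_arity}"))
    return report


# ---------------------------------------------------------------------------
# controlled-vocabulary flagging

_PUNCT_WS = re.compile(r"[\s\.\,\;\:\-\_\'\"\(\)\/]+")


def _vocab_norm(value: str) -> str:
    return _PUNCT_WS.sub("", value).casefold()


class Vocabulary:
    """A canonical value list plus a synonym table.

    Synonym matching is case-insensitive and punctuation/whitespace-
    insensitive; canonical membership is exact string equality, so a value
    like ``US.`` is still flagged even though it normalizes to a code.
    """

    def __init__(self, canonical: Iterable[str],
                 synonyms: dict[str, str] | None = None):
        self.canonical = list(canonical)
        if not self.canonical:
            raise UsageError("vocabulary must be non-empty")
        self._canon_set = set(self.canonical)
        self._norm_to_canon: dict[str, str] = {}
        for c in self.canonical:
            self._norm_to_canon.setdefault(_vocab_norm(c), c)
        for variant, canon in (synonyms or {}).items():
            self._norm_to_canon[_vocab_norm(variant)] = canon

    def is_canonical(self, value: str) -> bool:
        return value in self._canon_set

    def suggest(self, value: str) -> str | None:
        return self._norm_to_canon.get(_vocab_norm(value))

    @classmethod
    def country(cls) -> "Vocabulary":
        """The shipped demonstration vocabulary: ISO 3166-1 alpha-2 codes
        plus a synonym table of common country-name variants."""
        data = resources.files("dwcapub.data")
        canonical = [
            line.strip()
            for line in data.joinpath("country_codes.txt").read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        synonyms = {}
        for line in data.joinpath("country_synonyms.tsv").read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            variant, _, canon = line.partition("\t")
            synonyms[variant] = canon.strip()
        return cls(canonical, synonyms)


def check_vocabulary(values: Iterable[str], vocab: Vocabulary,
                     filename: str = "core"
                     ) -> tuple[ValidationReport, dict[str, str]]:
    """Flag each distinct non-canonical value once, with its row count.

    Returns the report plus a suggestion map (offending value -> canonical
    form) for values a synonym rule resolves.  Data is never rewritten.
    """
    counts: Counter = Counter()
    first_row: dict[str, int] = {}
    for row_no, v in enumerate(values, start=1):
        if not vocab.is_canonical(v):
            counts[v] += 1
            first_row.setdefault(v, row_no)
    report = ValidationReport()
    suggestions: dict[str, str] = {}
    for value, n in counts.items():
        suggestion = vocab.suggest(value)
        if suggestion is not None:
            suggestions[value] = suggestion
        report.issues.append(Issue(
            VOCABULARY_FLAG, WARNING, (filename, first_row[value]),
            f"non-canonical value {value!r} on {n} row(s)"
            + (f"; suggest {suggestion!r}" if suggestion else ""),
            value=value))
    return report, suggestions
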