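"""The publication pipeline: validate, package, version, schedule, register.

A *resource* is one dataset under management, described by a YAML config
naming its source files, mappings, metadata and schedule.  ``publish``
runs the full pipeline — read, map, validate (record IDs, row arity,
extension integrity), package, record a version.  The halt rule is strict:
any error-severity finding (a missing or duplicate record identifier, an
empty coreid) means NO archive is produced and the existing version
history is untouched; the complete report is returned instead.

Versions are immutable.  Each successful publish creates the next numbered
directory (``v1``, ``v2``, ...) holding the archive, its validation
report and the rendered summary page; re-publication never overwrites an
earlier version.  A pinned-timestamp mode makes publish runs byte-exact
reproducible.

There is no daemon: the scheduler only computes due-ness, so automatic
publication is a cron-style ``publish --if-due`` invocation.
"""

from __future__ import annotations

import calendar
import datetime as dt
import json
import uuid
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import mapping as mp
from . import validate as vd
from .archive import package_archive
from .eml import EmlMetadata, Creator, DatasetStats, parse_eml, render_summary_page
from .errors import PublishError, UsageError
from .sources import Dialect, inspect_table, iter_rows
from .terms import Schema, get_schema

INTERVALS = ("annually", "biannually", "monthly", "weekly", "daily", "off")


@dataclass(frozen=True)
class Schedule:
    interval: str = "off"
    last_published: dt.date | None = None

    def __post_init__(self):
        if self.interval not in INTERVALS:
            raise UsageError(f"unknown interval {self.interval!r}; "
                             f"expected one of {INTERVALS}")


def _add_months(d: dt.date, months: int) -> dt.date:
    """Calendar-month addition with the day clamped to the month length."""
    y, m = divmod(d.month - 1 + months, 12)
    year, month = d.year + y, m + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def next_publication_date(s: Schedule) -> dt.date | None:
    """The next automatic publication date, or None when not scheduled.

    Daily/weekly advance by days; monthly, biannually (six months) and
    annually advance by calendar months with month-end clamping.
    """
    if s.interval == "off" or s.last_published is None:
        return None
    if s.interval == "daily":
        return s.last_published + dt.timedelta(days=1)
    if s.interval == "weekly":
        return s.last_published + dt.timedelta(days=7)
    months = {"monthly": 1, "biannually": 6, "annually": 12}[s.interval]
    return _add_months(s.last_published, months)


@dataclass(frozen=True)
class PublishedVersion:
    version_number: int
    timestamp: dt.datetime
    archive_path: str
    record_count: int
    metadata_only: bool
    validation_digest: dict

    def to_json(self) -> dict:
        return {
            "version": self.version_number,
            "timestamp": self.timestamp.isoformat(),
            "archive": self.archive_path,
            "record_count": self.record_count,
            "metadata_only": self.metadata_only,
            "validation": self.validation_digest,
        }

    @classmethod
    def from_json(cls, doc: dict) -> "PublishedVersion":
        return cls(version_number=doc["version"],
                   timestamp=dt.datetime.fromisoformat(doc["timestamp"]),
                   archive_path=doc["archive"],
                   record_count=doc["record_count"],
                   metadata_only=doc["metadata_only"],
                   validation_digest=doc["validation"])


@dataclass
class ExtensionSource:
    row_type: str
    path: str
    mapping_path: str | None = None
    coreid_column: int | None = None
    dialect: Dialect | None = None


@dataclass
class ResourceConfig:
    """Everything needed to publish one resource, loaded from YAML."""

    name: str
    core_path: str | None
    core_type: str = "occurrence"
    mapping_path: str | None = None
    extensions: list[ExtensionSource] = field(default_factory=list)
    metadata: EmlMetadata | None = None
    schedule: Schedule = field(default_factory=Schedule)
    legacy_registry_id: str | None = None
    organization: str = ""
    dialect: Dialect | None = None
    metadata_only: bool = False


def _dialect_from_dict(doc: dict | None) -> Dialect | None:
    if not doc:
        return None
    return Dialect(
        field_delimiter=doc.get("delimiter", ","),
        quote_character=doc.get("quote", '"'),
        line_terminator={"LF": "\n", "CRLF": "\r\n"}.get(
            doc.get("line_terminator", "LF"), "\n"),
        encoding=doc.get("encoding", "utf-8"),
        header_lines=doc.get("header_lines", 1))


def _metadata_from_config(doc, base: Path) -> EmlMetadata:
    if isinstance(doc, str):
        return parse_eml((base / doc).read_text(encoding="utf-8"))
    creators = tuple(
        Creator(name=c["name"], organization=c.get("organization", ""),
                email=c.get("email", ""))
        for c in doc.get("creators", []))
    return EmlMetadata(
        title=doc.get("title", ""), creators=creators,
        abstract=doc.get("abstract", ""), rights=doc.get("rights", ""),
        keywords=tuple(doc.get("keywords", [])),
        methods=doc.get("methods", ""), citation=doc.get("citation", ""),
        language=doc.get("language", ""))


def load_resource_config(path: str | Path) -> ResourceConfig:
    path = Path(path)
    base = path.parent
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not doc or "name" not in doc:
        raise UsageError(f"resource config {path} lacks a name")
    core = doc.get("core") or {}
    exts = []
    for e in doc.get("extensions", []):
        exts.append(ExtensionSource(
            row_type=e.get("type", "multimedia"),
            path=str(base / e["path"]),
            mapping_path=str(base / e["mapping"]) if e.get("mapping") else None,
            coreid_column=e.get("coreid_column"),
            dialect=_dialect_from_dict(e.get("dialect"))))
    sched = doc.get("schedule") or {}
    last = sched.get("last_published")
    if isinstance(last, str):
        last = dt.date.fromisoformat(last)
    return ResourceConfig(
        name=doc["name"],
        core_path=str(base / core["path"]) if core.get("path") else None,
        core_type=core.get("type", "occurrence"),
        mapping_path=str(base / core["mapping"]) if core.get("mapping") else None,
        extensions=exts,
        metadata=_metadata_from_config(doc.get("metadata", {}), base),
        schedule=Schedule(interval=sched.get("interval", "off"),
                          last_published=last),
        legacy_registry_id=doc.get("legacy_registry_id"),
        organization=doc.get("organization", ""),
        dialect=_dialect_from_dict(core.get("dialect")),
        metadata_only=bool(doc.get("metadata_only", False)))


# ---------------------------------------------------------------------------
# version store

class VersionStore:
    """One directory per resource, numbered version subdirectories,
    plus a history index file — trivially hostable as static files."""

    def __init__(self, root: str | Path):
        self.root = Path(root)

    def resource_dir(self, name: str) -> Path:
        return self.root / name

    def history(self, name: str) -> list[PublishedVersion]:
        idx = self.resource_dir(name) / "history.json"
        if not idx.exists():
            return []
        doc = json.loads(idx.read_text(encoding="utf-8"))
        return [PublishedVersion.from_json(v) for v in doc["versions"]]

    def _append(self, name: str, version: PublishedVersion) -> None:
        rdir = self.resource_dir(name)
        rdir.mkdir(parents=True, exist_ok=True)
        versions = [v.to_json() for v in self.history(name)]
        versions.append(version.to_json())
        (rdir / "history.json").write_text(
            json.dumps({"resource": name, "versions": versions}, indent=2),
            encoding="utf-8")


def detect_coreid_column(headers: tuple[str, ...], core_schema: Schema) -> int:
    """Pick the extension column holding the core-record key: a header
    named coreid/core_id/id, else one matching the core's identifier term,
    else column 0."""
    folded = [mp.normalize_name(h) for h in headers]
    for candidate in ("coreid", "id"):
        if candidate in folded:
            return folded.index(candidate)
    if core_schema.id_term is not None:
        idn = mp.normalize_name(core_schema.id_term.simple_name)
        if idn in folded:
            return folded.index(idn)
    return 0


def _mapping_for(table, schema: Schema, mapping_path: str | None) -> mp.MappingSet:
    if mapping_path:
        ms = mp.load_mapping(mapping_path, schema)
        if ms.n_columns is None:
            ms.n_columns = len(table.headers)
        return ms
    return mp.auto_map(table.headers, schema)


def publish(config: ResourceConfig, store: VersionStore | str | Path,
            timestamp: dt.datetime | None = None
            ) -> tuple[PublishedVersion | None, vd.ValidationReport]:
    """Run one publication event; returns ``(version, report)``.

    On a halting report the version is ``None`` and nothing has been
    written.  ``timestamp`` pins the publication instant for reproducible
    builds; it defaults to the current UTC time.
    """
    if not isinstance(store, VersionStore):
        store = VersionStore(store)
    if timestamp is None:
        timestamp = dt.datetime.now(dt.timezone.utc)
    if config.metadata is None:
        raise UsageError("resource config carries no metadata")
    report = vd.ValidationReport()

    records = []
    ext_streams: dict[str, list] = {}
    ext_terms: dict[str, list] = {}
    core_schema = get_schema(config.core_type)
    descriptor_stats: list[tuple[str, int]] = []
    core_ms = None

    if config.core_path is None:
        if not config.metadata_only:
            raise UsageError("resource config names no core source and is "
                             "not marked metadata-only")
    else:
        table = inspect_table(config.core_path, config.dialect)
        ms = core_ms = _mapping_for(table, core_schema, config.mapping_path)
        bad = [i for i in mp.validate_mapping(ms) if i.severity == "error"]
        if bad:
            raise UsageError("unusable mapping: " +
                             "; ".join(i.detail for i in bad))
        rows = list(iter_rows(table))
        report.extend(vd.check_row_arity(
            rows, len(table.headers), filename=Path(config.core_path).name))
        clean_rows = [r for r in rows if len(r) == len(table.headers)]
        records = [mp.apply_mapping(r, ms, row_number=i + 1)
                   for i, r in enumerate(clean_rows)]
        report.extend(vd.check_record_ids(
            (r.record_id or "" for r in records),
            filename=Path(config.core_path).name))
        core_ids = {r.record_id for r in records if r.record_id}

        for ext in config.extensions:
            ext_schema = get_schema(ext.row_type)
            etable = inspect_table(ext.path, ext.dialect)
            ems = _mapping_for(etable, ext_schema, ext.mapping_path)
            cid_col = (ext.coreid_column if ext.coreid_column is not None
                       else detect_coreid_column(etable.headers, core_schema))
            erows = list(iter_rows(etable))
            pairs = []
            for r in erows:
                cid = r[cid_col] if cid_col < len(r) else ""
                pairs.append((cid, mp.apply_mapping(r, ems).values))
            report.extend(vd.check_coreids(
                (cid for cid, _ in pairs), core_ids,
                filename=Path(ext.path).name))
            # orphan rows are warnings: keep them out of the package but
            # do not block publication
            kept = [(cid, v) for cid, v in pairs if cid in core_ids]
            ext_streams[ext_schema.row_type] = kept
            ext_terms[ext_schema.row_type] = [m.term for m in ems.mappings]
            descriptor_stats.append((ext_schema.row_type, len(kept)))

    if report.verdict == "halt":
        return None, report

    history = store.history(config.name)
    number = history[-1].version_number + 1 if history else 1
    rdir = store.resource_dir(config.name)
    vdir = rdir / f"v{number}"
    if vdir.exists():
        raise PublishError(f"version directory {vdir} already exists; "
                           "published versions are immutable")
    vdir.mkdir(parents=True)
    archive_path = vdir / "archive.zip"

    core_term_order = ([m.term for m in core_ms.mappings]
                       if core_ms is not None else None)
    descriptor = package_archive(
        records, ext_streams, config.metadata, archive_path,
        core_row_type=core_schema.row_type,
        core_terms=core_term_order, extension_terms=ext_terms,
        metadata_only=config.metadata_only and not records)

    version = PublishedVersion(
        version_number=number, timestamp=timestamp,
        archive_path=str(archive_path), record_count=len(records),
        metadata_only=descriptor is None,
        validation_digest=report.digest())

    (vdir / "report.json").write_text(
        json.dumps({"verdict": report.verdict, "counts": report.counts,
                    "issues": [
                        {"kind": i.kind, "severity": i.severity,
                         "file": i.location[0], "row": i.location[1],
                         "detail": i.detail, "value": i.value}
                        for i in report.issues]}, indent=2),
        encoding="utf-8")
    page = render_summary_page(config.metadata, descriptor,
                               history + [version])
    (vdir / "summary.html").write_text(page, encoding="utf-8")
    store._append(config.name, version)
    return version, report


def dataset_stats(config: ResourceConfig, store: VersionStore) -> DatasetStats:
    history = store.history(config.name)
    n = history[-1].record_count if history else 0
    core_schema = get_schema(config.core_type)
    return DatasetStats(record_count=n, core_row_type=core_schema.row_type,
                        extensions=tuple(
                            (get_schema(e.row_type).row_type, 0)
                            for e in config.extensions))


def registry_record(config: ResourceConfig, store: VersionStore) -> dict:
    """Compose the registry-registration document for a resource.

    No network call is made — the document is what would be submitted.  A
    legacy identifier from a former publishing method is reused and marked
    migrated so the existing registry entry is maintained rather than
    duplicated; otherwise a stable identifier is minted deterministically
    from the resource name.
    """
    history = store.history(config.name)
    if not history:
        raise UsageError("resource has no published version to register")
    latest = history[-1]
    if config.legacy_registry_id:
        identifier, migrated = config.legacy_registry_id, True
    else:
        identifier = str(uuid.uuid5(uuid.NAMESPACE_URL,
                                    f"dwcapub:resource:{config.name}"))
        migrated = False
    return {
        "identifier": identifier,
        "migrated": migrated,
        "title": config.metadata.title if config.metadata else config.name,
        "organization": config.organization,
        "endpoint": latest.archive_path,
        "version": latest.version_number,
        "record_count": latest.record_count,
    }
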