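"""Shared fixtures and pipeline helpers for the test suite."""

from __future__ import annotations

import random
from pathlib import Path

import pytest
import yaml

from dwcapub import (
    Creator,
    EmlMetadata,
    auto_map,
    get_schema,
    inspect_table,
    iter_rows,
    package_archive,
)
from dwcapub.fixtures import ErrorSpec, FixtureSpec
from dwcapub.mapping import apply_mapping
from dwcapub.publishing import detect_coreid_column
from dwcapub.sources import Dialect

FIXTURE_DIR = Path(__file__).parent / "fixtures"

DIALECT_CHOICES = (
    Dialect(),
    Dialect(field_delimiter="\t", quote_character='"'),
    Dialect(field_delimiter=";", quote_character='"', line_terminator="\r\n"),
    Dialect(field_delimiter="|", quote_character='"'),
)


@pytest.fixture
def metadata() -> EmlMetadata:
    return EmlMetadata(
        title="Synthetic occurrence dataset",
        creators=(Creator(name="A. Tester", organization="Test Museum",
                          email="tester@example.org"),),
        abstract="Records generated for round-trip testing.",
        rights="CC0",
    )


def random_fixture_spec(rng: random.Random, *, n_max: int = 1000,
                        with_errors: bool = False,
                        with_extension: bool | None = None) -> FixtureSpec:
    """Draw a varied fixture spec: dialect, size, extensions, errors."""
    n = int(round(10 ** rng.uniform(0, rng.uniform(1, 3))))
    n = max(1, min(n, n_max))
    if with_extension is None:
        ext = rng.choice([None, 0.5, 1.0, 2.0])
    else:
        ext = 1.0 if with_extension else None
    errors = ErrorSpec()
    if with_errors:
        budget = n
        dup = rng.randint(0, min(3, budget // 2))
        budget -= 2 * dup
        missing = rng.randint(0, min(3, budget))
        budget -= missing
        ragged = rng.randint(0, min(3, budget))
        errors = ErrorSpec(
            duplicate_ids=dup, missing_ids=missing, ragged_rows=ragged,
            orphan_extension_rows=rng.randint(0, 2) if ext else 0,
            noncanonical_country_values=rng.randint(0, min(8, n)))
    return FixtureSpec(
        core_type="occurrence",
        n_records=n,
        extension_mean_rows=ext,
        errors=errors,
        seed=rng.randrange(2 ** 31),
        dialect=rng.choice(DIALECT_CHOICES),
    )


def build_archive_from_sources(files: dict, core_type: str, out_path,
                               metadata: EmlMetadata):
    """map -> package: the publish pipeline without versioning.

    Returns (records, extension_pairs_by_row_type, descriptor).
    """
    core_schema = get_schema(core_type)
    table = inspect_table(files["core"])
    ms = auto_map(table.headers, core_schema)
    records = [apply_mapping(r, ms) for r in iter_rows(table)]
    ext_streams = {}
    ext_terms = {}
    if "extension" in files:
        ext_schema = get_schema("multimedia")
        etable = inspect_table(files["extension"])
        ems = auto_map(etable.headers, ext_schema)
        cid_col = detect_coreid_column(etable.headers, core_schema)
        pairs = [(r[cid_col], apply_mapping(r, ems).values)
                 for r in iter_rows(etable)]
        ext_streams[ext_schema.row_type] = pairs
        ext_terms[ext_schema.row_type] = [m.term for m in ems.mappings]
    descriptor = package_archive(
        records, ext_streams, metadata, out_path,
        core_row_type=core_schema.row_type,
        core_terms=[m.term for m in ms.mappings],
        extension_terms=ext_terms)
    return records, ext_streams, descriptor


def write_resource_config(tmp_path: Path, core_file: str,
                          name: str = "test-resource",
                          extension_file: str | None = None,
                          schedule: dict | None = None,
                          legacy_id: str | None = None) -> Path:
    doc = {
        "name": name,
        "organization": "Test Museum",
        "core": {"path": core_file, "type": "occurrence"},
        "metadata": {
            "title": "Synthetic occurrence dataset",
            "creators": [{"name": "A. Tester",
                          "organization": "Test Museum"}],
            "abstract": "Generated records.",
            "rights": "CC0",
        },
    }
    if extension_file:
        doc["extensions"] = [{"type": "multimedia", "path": extension_file}]
    if schedule:
        doc["schedule"] = schedule
    if legacy_id:
        doc["legacy_registry_id"] = legacy_id
    path = tmp_path / f"{name}.yml"
    path.write_text(yaml.safe_dump(doc), encoding="utf-8")
    return path
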