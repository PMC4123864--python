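"""Synthetic occurrence and checklist datasets with controlled error injection.

Every other module is testable offline against these generators: a seeded
:class:`FixtureSpec` produces delimited source files (a core table with
plausible Darwin Core columns, optionally an extension table keyed to the
core) together with a :class:`FixtureTruth` that records, by construction,
exactly which errors were injected where — the ground truth the validator
must recover.

Injection happens after clean generation, at positions drawn from the
seeded generator, and the rows touched by the different error kinds are
kept disjoint so the expected issue counts are exact, not approximate.
Realism of names and coordinates is cosmetic; the count contract is what
matters.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import UsageError
from .sources import Dialect, write_rows

#: The five noisy spellings of the United States used in the
#: country-field demonstration (plus their canonical code "US").
COUNTRY_VARIANTS = ("USA", "United State", "U.S.A.",
                    "United States of America", "US.")

_NAMES = (
    "Puma concolor", "Lynx rufus", "Canis latrans", "Ursus americanus",
    "Odocoileus virginianus", "Procyon lotor", "Sciurus carolinensis",
    "Turdus migratorius", "Cardinalis cardinalis", "Cyanocitta cristata",
    "Corvus brachyrhynchos", "Haliaeetus leucocephalus", "Falco peregrinus",
    "Ardea herodias", "Anas platyrhynchos", "Danaus plexippus",
    "Apis mellifera", "Bombus terrestris", "Quercus alba", "Acer saccharum",
    "Pinus ponderosa", "Sequoia sempervirens", "Taraxacum officinale",
    "Trifolium repens", "Rana temporaria", "Thamnophis sirtalis",
    "Chelonia mydas", "Salmo trutta", "Micropterus salmoides",
    "Gadus morhua",
)

_BASIS = ("PreservedSpecimen", "HumanObservation", "MachineObservation",
          "FossilSpecimen")

_COUNTRIES = ("US", "CA", "MX", "BR", "DE", "FR", "ES", "GB", "AU", "ZA")

CORE_HEADERS = {
    "occurrence": ("occurrenceID", "scientificName", "eventDate", "country",
                   "decimalLatitude", "decimalLongitude", "basisOfRecord"),
    "taxon": ("taxonID", "scientificName", "taxonRank", "kingdom",
              "family", "taxonomicStatus"),
}

EXTENSION_HEADERS = ("coreid", "identifier", "format", "title")


@dataclass(frozen=True)
class ErrorSpec:
    duplicate_ids: int = 0
    missing_ids: int = 0
    orphan_extension_rows: int = 0
    ragged_rows: int = 0
    noncanonical_country_values: int = 0


@dataclass(frozen=True)
class FixtureSpec:
    core_type: str = "occurrence"
    n_records: int = 50
    extension_mean_rows: float | None = None  # rows per core record
    errors: ErrorSpec = field(default_factory=ErrorSpec)
    seed: int = 0
    dialect: Dialect = field(default_factory=Dialect)


@dataclass
class FixtureTruth:
    """Ground truth recorded while the fixture was built."""

    record_count: int
    issue_counts: dict            # validator kind -> expected issue count
    star_cardinalities: dict      # core id -> expected joined extension rows
    extension_row_count: int = 0
    duplicate_rows: list = field(default_factory=list)
    missing_rows: list = field(default_factory=list)
    ragged_rows: list = field(default_factory=list)
    orphan_rows: list = field(default_factory=list)
    noncanonical_values: list = field(default_factory=list)


def _check_spec(spec: FixtureSpec) -> None:
    e = spec.errors
    for name in ("duplicate_ids", "missing_ids", "orphan_extension_rows",
                 "ragged_rows", "noncanonical_country_values"):
        if getattr(e, name) < 0:
            raise UsageError(f"error count {name} must be non-negative")
    if spec.n_records < 1:
        raise UsageError("n_records must be >= 1")
    # duplicates consume a victim row and a copy row; all injected row sets
    # are disjoint so the expected counts are exact
    needed = 2 * e.duplicate_ids + e.missing_ids + e.ragged_rows
    if needed > spec.n_records:
        raise UsageError(
            f"error spec needs {needed} distinct rows but the fixture has "
            f"only {spec.n_records}")
    if e.noncanonical_country_values > spec.n_records:
        raise UsageError("noncanonical_country_values exceeds n_records")
    if e.orphan_extension_rows and spec.extension_mean_rows is None:
        raise UsageError("orphan rows requested but the fixture has no "
                         "extension table")
    if e.noncanonical_country_values and spec.core_type != "occurrence":
        raise UsageError("country noise requires an occurrence fixture")


def _clean_core_row(rng: random.Random, core_type: str, i: int) -> list[str]:
    name = rng.choice(_NAMES)
    if core_type == "taxon":
        genus, _, _ = name.partition(" ")
        return [f"tax-{i + 1:06d}", name, "species", "Animalia",
                genus + "idae", rng.choice(("accepted", "synonym"))]
    date = (f"{rng.randint(2000, 2014)}-{rng.randint(1, 12):02d}-"
            f"{rng.randint(1, 28):02d}")
    return [f"occ-{i + 1:06d}", name, date, rng.choice(_COUNTRIES),
            f"{rng.uniform(-90, 90):.4f}", f"{rng.uniform(-180, 180):.4f}",
            rng.choice(_BASIS)]


def generate(spec: FixtureSpec, out_dir: str | Path) -> tuple[dict, FixtureTruth]:
    """Write the fixture's source files and return their ground truth.

    Returns ``(files, truth)`` where ``files`` maps ``"core"`` (and
    ``"extension"`` when requested) to the written paths.  The same spec
    and seed always produce byte-identical files.
    """
    _check_spec(spec)
    if spec.core_type not in CORE_HEADERS:
        raise UsageError(f"unknown core type {spec.core_type!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    e = spec.errors
    n = spec.n_records

    rows = [_clean_core_row(rng, spec.core_type, i) for i in range(n)]

    # choose disjoint row positions for each injected error kind
    pool = list(range(n))
    rng.shuffle(pool)
    victims = [pool.pop() for _ in range(e.duplicate_ids)]
    copies = [pool.pop() for _ in range(e.duplicate_ids)]
    missing = [pool.pop() for _ in range(e.missing_ids)]
    ragged = [pool.pop() for _ in range(e.ragged_rows)]

    for victim, copy_row in zip(victims, copies):
        rows[copy_row][0] = rows[victim][0]
    for r in missing:
        rows[r][0] = ""
    noisy_rows = rng.sample(range(n), e.noncanonical_country_values)
    noisy_values = []
    if spec.core_type == "occurrence":
        for j, r in enumerate(sorted(noisy_rows)):
            rows[r][3] = COUNTRY_VARIANTS[j % len(COUNTRY_VARIANTS)]
            noisy_values.append(rows[r][3])
    for r in ragged:
        rows[r] = rows[r][:-1]  # drop the final field; the id survives

    ext_path = None
    ext_rows: list[list[str]] = []
    cardinalities: dict[str, int] = {}
    orphan_positions: list[int] = []
    if spec.extension_mean_rows is not None:
        upper = max(0, int(round(2 * spec.extension_mean_rows)))
        for i in range(n):
            cid = rows[i][0]
            if cid == "":
                continue  # a record without an ID cannot anchor extension rows
            for k in range(rng.randint(0, upper)):
                ext_rows.append([
                    cid, f"http://example.org/media/{i + 1}/{k + 1}",
                    rng.choice(("image/jpeg", "image/png", "audio/wav")),
                    f"Media {k + 1} for record {i + 1}"])
        rng.shuffle(ext_rows)
        if e.orphan_extension_rows > len(ext_rows):
            raise UsageError(
                f"requested {e.orphan_extension_rows} orphan rows but the "
                f"extension has only {len(ext_rows)}")
        orphan_positions = rng.sample(range(len(ext_rows)),
                                      e.orphan_extension_rows)
        for j, p in enumerate(orphan_positions):
            ext_rows[p][0] = f"no-such-core-{j + 1}"
        # truth join cardinalities: duplicate core ids would make the join
        # undefined, so they are recorded only for unique ids
        core_ids = [r[0] for r in rows if r and r[0]]
        id_set = set(core_ids)
        cardinalities = {cid: 0 for cid in id_set}
        for row in ext_rows:
            if row[0] in id_set:
                cardinalities[row[0]] += 1

    ext_name = "multimedia" + _ext_suffix(spec.dialect)
    core_name = spec.core_type + _ext_suffix(spec.dialect)
    core_path = out_dir / core_name
    headers = CORE_HEADERS[spec.core_type]
    write_rows(core_path, [list(headers)] + rows, spec.dialect)
    files = {"core": str(core_path)}
    if spec.extension_mean_rows is not None:
        ext_path = out_dir / ext_name
        write_rows(ext_path, [list(EXTENSION_HEADERS)] + ext_rows,
                   spec.dialect)
        files["extension"] = str(ext_path)

    truth = FixtureTruth(
        record_count=n,
        issue_counts={
            "missing_id": e.missing_ids,
            "duplicate_id": 2 * e.duplicate_ids,
            "arity_mismatch": e.ragged_rows,
            "orphan_extension_row": e.orphan_extension_rows,
            "vocabulary_flag": len(set(noisy_values)),
        },
        star_cardinalities=cardinalities,
        extension_row_count=len(ext_rows),
        duplicate_rows=sorted(copies),
        missing_rows=sorted(missing),
        ragged_rows=sorted(ragged),
        orphan_rows=sorted(orphan_positions),
        noncanonical_values=noisy_values,
    )
    return files, truth


def _ext_suffix(dialect: Dialect) -> str:
    return ".tsv" if dialect.field_delimiter == "\t" else ".csv"


def country_noise_fixture(out_dir: str | Path,
                          canonical_rows: int = 10) -> str:
    """A small occurrence table demonstrating country-field noise.

    The country column holds ``canonical_rows`` canonical ``US`` values
    plus one row for each of the five classic variant spellings, so the
    vocabulary check flags exactly five distinct values and suggests "US"
    for each.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(321)
    rows = []
    i = 0
    for variant in COUNTRY_VARIANTS:
        i += 1
        rows.append([f"occ-{i:06d}", rng.choice(_NAMES), "2013-03-01",
                     variant, "39.7392", "-104.9903", "HumanObservation"])
    for _ in range(canonical_rows):
        i += 1
        rows.append([f"occ-{i:06d}", rng.choice(_NAMES), "2013-03-01",
                     "US", "39.7392", "-104.9903", "HumanObservation"])
    path = out_dir / "country_noise.csv"
    write_rows(path, [list(CORE_HEADERS["occurrence"])] + rows, Dialect())
    return str(path)
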