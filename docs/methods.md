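# Methods

This note documents the model behind `dwcapub`, the defaults that matter,
the numerical/structural choices made where the design was open, what the
synthetic data does and does not emulate, and known limitations.

## The data model

An archive is a star schema over delimited text. The **core** table holds
one record per row; its identifier column (`id`) carries the record's
stable identifier — `occurrenceID` for Occurrence Cores, `taxonID` for
Taxon Cores. **Extension** tables attach auxiliary rows (media,
measurements, …) many-to-one to core rows via a `coreid` column. The
structural descriptor `meta.xml` declares, per file: the row-type URI, the
text dialect (`fieldsTerminatedBy`, `fieldsEnclosedBy`,
`linesTerminatedBy`, `ignoreHeaderLines`, `encoding`), the position of the
id/coreid column, and one term binding per data column (with an optional
default substituted for empty fields). `eml.xml` carries the dataset
metadata.

Schemas (ordered term sets per row type) are loaded from definition files
bundled in `dwcapub/data` in the resource-registry XML style, so no
network access is ever needed. The bundled Occurrence (63 terms), Taxon
(32) and Simple Multimedia (14) subsets were transcribed once from the
public definitions; the exact membership is a fixture of this package.
Simple-name collisions across namespaces (e.g. `dwc:type` vs `dc:type`
style clashes) resolve deterministically to the first term in schema
order, with a logged warning.

## Reading delimited sources

The sniffer chooses the delimiter from {tab, comma, semicolon, pipe} over
the first 50 lines by the *most consistent modal field count*, preferring
multi-column readings: a few ragged rows therefore do not defeat the true
delimiter (they surface later as arity findings). A quote character is
assumed only when the file contains one. Encoding is UTF-8 unless a
byte-order mark says otherwise; undecodable bytes are an error naming the
byte offset rather than a silent fallback (Latin-1 is accepted only as an
explicit override). All sniffed values can be pinned by config.

The record tokenizer is symmetric with the writer: fields containing the
delimiter, the quote or a line break are quoted with embedded quotes
doubled, and the reader inverts exactly that, preserving line breaks
inside quoted fields byte-for-byte. It is implemented in this package
(with a fast split path for quote-free lines) because the reading contract
includes parse errors with line numbers for unterminated quoting, which
general-purpose CSV readers silently swallow at end of file; a test
cross-checks it against the stdlib reader on common input. Field
whitespace is never trimmed (data fidelity); header names are.

Ragged rows are deliberately *not* a read error: quality problems are
routed to validation reports, not repaired or rejected at ingest.

## Mapping

Auto-matching uses the same-name rule only: case-fold plus removal of
spaces and underscores, no edit distance, because fuzzy matching would
silently mis-map columns. Unmatched headers are listed, never guessed. A
term may additionally be bound to a constant (applied to every record) or
carry a default used when the bound field is empty. One source column may
feed several terms; binding one term twice is an error. Record IDs are
taken verbatim from the designated ID column — no trimming, exact
case-sensitive string identity throughout the toolkit, since identifiers
are opaque and normalization would mask exactly the publisher errors
validation exists to surface.

## Writing archives

Writer conventions (all stated explicitly in `meta.xml`, never left to
format defaults): tab-delimited, UTF-8, LF-terminated files, one header
line, the identifier duplicated into physical column 0 (`id`/`coreid`)
with term bindings from column 1, zip entry names equal to descriptor
locations with no internal directories, and zip member timestamps pinned
to a constant so identical inputs yield byte-identical archives. Tab and
newline dialect attributes are written in escaped form (`\t`, `\n`).
Archives are rectangular: a term absent from a record is an empty string.
On parse, absent optional descriptor attributes take the text-format
defaults (comma, double quote, LF, 0 header lines, UTF-8).

A metadata-only package contains `eml.xml` alone — no data files and no
`meta.xml` — and is flagged as such in the version history.

## The star join

`iter_star_records` makes one pass over the core building an ID index
(memory proportional to core row count, not total data), then streams
extensions through it, yielding one record per core row in file order with
extension rows grouped by row type in extension-file order. The join is
exact string equality. Extension rows whose `coreid` matches nothing are
not reader output — they are validator findings — and a duplicate core ID
aborts the join, which is unreachable on validated archives. Tests check
the join against an independent brute-force nested-loop oracle.

## Validation

- `missing_id` (empty/whitespace identifier) and `duplicate_id` are
  errors. A value occurring k ≥ 2 times yields k issues — every involved
  row, including the first — so reports are directly actionable.
- `arity_mismatch` (row width ≠ header width) is an error.
- An extension row with an unresolvable `coreid` is a warning (the row is
  unusable, the archive still coherent); an *empty* `coreid` is an error
  (the row is structurally meaningless).
- Vocabulary drift is advisory only: each distinct non-canonical value is
  flagged once with its row count, and a canonical form is suggested when
  a synonym rule matches (matching is case/punctuation/whitespace
  insensitive; canonical membership is exact, so `US.` is flagged even
  though it normalizes to a code). Data is never rewritten.

The verdict is `halt` iff any error-severity issue exists. All issues are
collected before the verdict is rendered (collect-then-halt), a usability
choice: a publisher sees the whole repair list at once. Duplicate
detection keeps a seen-set in memory — the contract is desk scale,
memory proportional to the distinct-ID count.

The shipped country vocabulary is the ISO 3166-1 alpha-2 code list with a
synonym table seeded with the five classic variant spellings of the United
States (`USA`, `United State`, `U.S.A.`, `United States of America`,
`US.`); it is a demonstration vocabulary, extensible via plain-text files.

## Publishing, versions, schedule

`publish` runs read → map → validate → package → record. On halt, nothing
is written. Versions are an immutable gapless sequence per resource
(`v1/, v2/, …` plus `history.json`), each holding the archive, the
validation report and a self-contained summary page; a metadata-only
change increments the same counter with a `metadata_only` flag. A pinned
timestamp makes a publish run fully reproducible. The scheduler computes
due-ness only (`--if-due`); there is no daemon — automation is a cron
invocation. Interval arithmetic: daily +1 d, weekly +7 d; monthly,
biannually (+6 calendar months — "bi-annually" read as twice a year, the
commoner publishing cadence) and annually advance by calendar months with
the day clamped to the target month's length (Jan 31 → Feb 28/29).

Registration emits a structured document (no network call): stable
identifier, title, organization, endpoint of the latest archive. The
identifier is minted deterministically (UUIDv5 of the resource name); a
configured legacy identifier from a former publishing protocol is reused
and marked migrated so an existing registry entry is maintained rather
than duplicated.

## Metadata

The modeled EML subset is the dataset-level profile a publishing tool
populates: title, creators, abstract, rights, keywords, geographic
coverage (description + bounding box, west ≤ east in [−180, 180],
south ≤ north in [−90, 90]), taxonomic coverage (rank/name pairs),
temporal coverage (ISO 8601 range), methods, citation, language. Unknown
elements inside `dataset` are preserved opaquely across a parse/write
cycle. Dublin Core records are accepted on read and mapped into the same
type; writing always emits EML, the richer format. The data-paper export
is portable structured text (Markdown headings) rather than binary RTF —
the contract is the sectioned manuscript skeleton, fixed at eleven
sections in fixed order (Title, Authors, Abstract, Keywords, Taxonomic /
Geographic / Temporal Coverage, Methods, Dataset Description, Rights,
References), with placeholders where metadata is missing.

## Synthetic data

The generator emulates the *structure* of publisher datasets — plausible
Darwin Core columns (seeded scientific names, dates, ISO country codes,
in-range coordinates), an optional multimedia extension keyed to the core,
four delimiter dialects — and injects a requested number of duplicate IDs,
missing IDs, orphan extension rows, ragged rows and non-canonical country
values at seeded positions, keeping the touched row sets disjoint so the
expected issue counts are exact by construction. The same spec and seed
produce byte-identical files. It does **not** model realistic sampling
distributions, geographic structure, taxonomic consistency or the messier
encodings of real exports; passing tests therefore demonstrate the
pipeline's structural correctness and count-exact error recovery, not
robustness to every artifact of real-world data.

Test and acceptance problem sizes — up to 1000 core × 1000 extension rows
per fixture, 100–200 fixtures per property, 50–100 randomized metadata
documents — are the package's chosen desk-scale envelope; all operations
are streaming or core-bounded in memory, so larger inputs differ only in
runtime.

## Known limitations

- No database sources, no multi-file cores, no gzip members, no remote
  archive fetching.
- No live registry calls, DOI minting, or web UI; the CLI and library are
  the interface.
- The meta.xml conformance check in the tests validates against a schema
  fixture authored from the emitted descriptor structure, not the
  normative published schema document.
- The country vocabulary is demonstrative; serious vocabulary cleaning
  (taxonomy, georeferences) is explicitly out of scope.
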