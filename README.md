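# dwcapub — a Darwin Core Archive publishing toolkit

`dwcapub` implements the dataset-publishing lifecycle for biodiversity
data as a Python library plus a `dwca` command line. It is aimed at
collection managers, ecologists and informaticians who hold occurrence
records or taxon checklists in ordinary delimited files and need to
publish them as standard, validated, versioned **Darwin Core Archives**
(DwC-A) — the star-schema package format consumed by aggregation networks
and archive readers.

## What it does

A Darwin Core Archive is a zip holding:

- one **core** data table — Occurrence Core (specimens/observations,
  identified by `occurrenceID`) or Taxon Core (checklist records,
  identified by `taxonID`);
- zero or more **extension** tables (e.g. Simple Multimedia) whose rows
  relate many-to-one to core rows through a `coreid` key, forming a star
  schema;
- `meta.xml`, the structural descriptor binding file columns to Darwin
  Core term URIs and declaring each file's text dialect;
- `eml.xml`, the dataset metadata (title, creators, rights, coverage,
  methods) in an Ecological Metadata Language subset.

The toolkit covers the classic publisher workflow: **inspect** a delimited
source (dialect sniffing), **map** its columns to Darwin Core terms
(columns whose names equal a term's name — after case folding and removal
of spaces/underscores — are matched automatically; nothing fuzzier is ever
guessed), enter **metadata**, **validate**, **publish** a versioned
archive with a summary page, and emit a **registry** document. Validation
enforces the halt rule: a missing or duplicated record identifier blocks
publication outright — no archive is produced and the existing version
history is untouched. Softer problems (unresolvable extension rows,
vocabulary drift such as the many spellings of "United States" in a
country field) are flagged with suggestions, never silently rewritten.
Dataset metadata can also be exported as a data-paper manuscript skeleton
with a fixed eleven-section structure.

A seeded fixture generator (`dwcapub.fixtures`) produces synthetic
occurrence/checklist datasets with controlled error injection and records
the ground truth, so the whole pipeline is testable offline.

## Worked example

```sh
$ dwca fixture --core occurrence -n 10 --seed 1 --out d/
core: d/occurrence.csv
{"missing_id": 0, "duplicate_id": 0, "arity_mismatch": 0, "orphan_extension_row": 0, "vocabulary_flag": 0}

$ cat resource.yml
name: demo
core: {path: d/occurrence.csv, type: occurrence}
metadata:
  title: Demo dataset
  creators: [{name: A. Tester}]
  rights: CC0

$ dwca publish --config resource.yml --store store --pinned-timestamp 2014-04-01T00:00:00
published version 1 (10 records) -> store/demo/v1/archive.zip

$ dwca validate store/demo/v1/archive.zip
verdict: pass

$ dwca versions demo --store store
v1	2014-04-01T00:00:00	10 records	store/demo/v1/archive.zip
```

The fixture line reports the generator's injected-error counts (all zero
here). `publish` reads the source, auto-maps its headers, validates record
IDs, row arity and extension integrity, and — only on a passing report —
writes `store/demo/v1/` with the archive, the validation report and a
self-contained HTML summary page, then appends version 1 to
`history.json`. Re-publishing creates `v2` and never touches `v1`; a
duplicate or missing `occurrenceID` instead prints the issue rows, exits
with status 1 and leaves the store byte-identical. With a duplicated ID
the same command prints, for every involved row:

```
duplicate_id	error	occurrence.csv	4	occ-000002	identifier 'occ-000002' occurs more than once
verdict: halt
```

Library use mirrors the CLI: `sniff_dialect` / `inspect_table`,
`auto_map` / `apply_mapping`, `package_archive` / `open_archive` /
`iter_star_records`, `check_record_ids` and friends, `publish`,
`write_eml` / `export_data_paper`.

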