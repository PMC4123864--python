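"""Archive codec: meta.xml round trip + schema conformance, packaging,
reading, and the star join checked against a brute-force oracle."""

import random
import zipfile

import pytest
from lxml import etree

from conftest import FIXTURE_DIR, build_archive_from_sources
from dwcapub.archive import (
    ArchiveDescriptor,
    ColumnBinding,
    FileDescriptor,
    iter_star_records,
    open_archive,
    package_archive,
    parse_meta_xml,
    write_meta_xml,
)
from dwcapub.errors import ArchiveError, DescriptorError, JoinError, PackagingError
from dwcapub.fixtures import ErrorSpec, FixtureSpec, generate
from dwcapub.sources import ARCHIVE_DIALECT, Dialect
from dwcapub.terms import Term, get_schema

OCC = get_schema("occurrence")
MM = get_schema("multimedia")


def _term(name: str) -> Term:
    return Term.from_qualified(f"http://rs.tdwg.org/dwc/terms/{name}")


def random_descriptor(rng: random.Random) -> ArchiveDescriptor:
    def fd(row_type, location, id_header):
        dialect = Dialect(
            field_delimiter=rng.choice(["\t", ",", ";", "|"]),
            quote_character=rng.choice(['"', None]),
            line_terminator=rng.choice(["\n", "\r\n"]),
            header_lines=rng.randint(0, 2))
        names = rng.sample(
            ["scientificName", "eventDate", "country", "locality",
             "recordedBy", "catalogNumber", "decimalLatitude"],
            k=rng.randint(1, 5))
        bindings = tuple(
            ColumnBinding(i + 1, _term(n),
                          default=rng.choice([None, "unknown"]))
            for i, n in enumerate(names))
        return FileDescriptor(location=location, row_type=row_type,
                              dialect=dialect, id_column=0, bindings=bindings)

    exts = tuple(fd(f"http://example.org/ext/{i}", f"ext{i}.txt", "coreid")
                 for i in range(rng.randint(0, 3)))
    return ArchiveDescriptor(
        core=fd(OCC.row_type, "occurrence.txt", "id"), extensions=exts)


class TestMetaXml:
    def test_core_only_document_structure(self):
        d = ArchiveDescriptor(core=FileDescriptor(
            location="occurrence.txt", row_type=OCC.row_type,
            dialect=ARCHIVE_DIALECT,
            bindings=(ColumnBinding(1, _term("scientificName")),)))
        root = etree.fromstring(write_meta_xml(d).encode())
        ns = "{http://rs.tdwg.org/dwc/text/}"
        assert len(root.findall(ns + "core")) == 1
        assert root.findall(ns + "extension") == []

    def test_tab_and_newline_attributes_are_escaped(self):
        d = ArchiveDescriptor(core=FileDescriptor(
            location="x.txt", row_type=OCC.row_type, dialect=ARCHIVE_DIALECT))
        text = write_meta_xml(d)
        el = etree.fromstring(text.encode()).find(
            "{http://rs.tdwg.org/dwc/text/}core")
        assert el.get("fieldsTerminatedBy") == "\\t"
        assert el.get("linesTerminatedBy") == "\\n"
        assert "\t" not in el.get("fieldsTerminatedBy")

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_randomized_descriptors(self, seed):
        d = random_descriptor(random.Random(seed))
        assert parse_meta_xml(write_meta_xml(d)) == d

    def test_absent_attributes_take_format_defaults(self):
        text = """<archive xmlns="http://rs.tdwg.org/dwc/text/">
          <core rowType="%s"><files><location>f.txt</location></files>
          <id index="0"/></core></archive>""" % OCC.row_type
        d = parse_meta_xml(text)
        assert d.core.dialect.header_lines == 0
        assert d.core.dialect.field_delimiter == ","
        assert d.metadata_location == "eml.xml"

    def test_extension_without_coreid_is_error(self):
        text = """<archive xmlns="http://rs.tdwg.org/dwc/text/">
          <core rowType="%s"><files><location>c.txt</location></files>
          <id index="0"/></core>
          <extension rowType="http://x/e"><files><location>e.txt</location>
          </files></extension></archive>""" % OCC.row_type
        with pytest.raises(DescriptorError, match="http://x/e"):
            parse_meta_xml(text)

    def test_missing_location_is_error(self):
        text = """<archive xmlns="http://rs.tdwg.org/dwc/text/">
          <core rowType="%s"><id index="0"/></core></archive>""" % OCC.row_type
        with pytest.raises(DescriptorError):
            parse_meta_xml(text)

    @pytest.mark.parametrize("seed", range(20))
    def test_validates_against_text_schema(self, seed):
        """Writer output conforms to the bundled descriptor XML schema."""
        xsd = etree.XMLSchema(
            etree.parse(str(FIXTURE_DIR / "dwc_text_schema_synthetic.xsd")))
        d = random_descriptor(random.Random(1000 + seed))
        doc = etree.fromstring(write_meta_xml(d).encode())
        xsd.assertValid(doc)

    def test_duplicate_locations_rejected(self):
        core = FileDescriptor(location="same.txt", row_type=OCC.row_type,
                              dialect=ARCHIVE_DIALECT)
        ext = FileDescriptor(location="same.txt", row_type="http://x/e",
                             dialect=ARCHIVE_DIALECT)
        with pytest.raises(DescriptorError):
            ArchiveDescriptor(core=core, extensions=(ext,))


class TestPackaging:
    def _records(self, n):
        t = _term("scientificName")
        return [(f"id{i}", {t: f"Species {i}"}) for i in range(n)]

    def test_core_only_zip_entry_and_line_counts(self, tmp_path, metadata):
        out = tmp_path / "a.zip"
        package_archive(self._records(10), {}, metadata, out,
                        core_row_type=OCC.row_type)
        with zipfile.ZipFile(out) as zf:
            names = set(zf.namelist())
            assert names == {"occurrence.txt", "meta.xml", "eml.xml"}
            lines = zf.read("occurrence.txt").decode().splitlines()
        assert len(lines) == 11  # header + 10 records

    def test_extension_adds_fourth_entry(self, tmp_path, metadata):
        out = tmp_path / "a.zip"
        t = _term("scientificName")
        mmid = MM.terms[2]
        package_archive([("c1", {t: "X"})],
                        {MM.row_type: [("c1", {mmid: "u1"}),
                                       ("c1", {mmid: "u2"})]},
                        metadata, out, core_row_type=OCC.row_type)
        with zipfile.ZipFile(out) as zf:
            assert len(zf.namelist()) == 4

    def test_metadata_only_package(self, tmp_path, metadata):
        out = tmp_path / "m.zip"
        d = package_archive([], {}, metadata, out,
                            core_row_type=OCC.row_type, metadata_only=True)
        assert d is None
        with zipfile.ZipFile(out) as zf:
            assert zf.namelist() == ["eml.xml"]

    def test_empty_core_without_flag_is_error(self, tmp_path, metadata):
        with pytest.raises(PackagingError):
            package_archive([], {}, metadata, tmp_path / "x.zip",
                            core_row_type=OCC.row_type)

    def test_empty_coreid_in_extension_is_error(self, tmp_path, metadata):
        t = _term("scientificName")
        with pytest.raises(PackagingError):
            package_archive([("c1", {t: "X"})],
                            {MM.row_type: [("", {MM.terms[2]: "u"})]},
                            metadata, tmp_path / "x.zip",
                            core_row_type=OCC.row_type)

    def test_identical_inputs_give_identical_bytes(self, tmp_path, metadata):
        a, b = tmp_path / "a.zip", tmp_path / "b.zip"
        for out in (a, b):
            package_archive(self._records(5), {}, metadata, out,
                            core_row_type=OCC.row_type)
        assert a.read_bytes() == b.read_bytes()


class TestOpenArchive:
    def test_round_trip_descriptor(self, tmp_path, metadata):
        out = tmp_path / "a.zip"
        t = _term("scientificName")
        d = package_archive([("c1", {t: "X"})], {}, metadata, out,
                            core_row_type=OCC.row_type)
        with open_archive(out) as a:
            assert a.descriptor == d
            assert a.eml_text() is not None

    def test_directory_layout_equivalent_to_zip(self, tmp_path, metadata):
        out = tmp_path / "a.zip"
        t = _term("scientificName")
        package_archive([("c1", {t: "X"})], {}, metadata, out,
                        core_row_type=OCC.row_type)
        unzipped = tmp_path / "unzipped"
        with zipfile.ZipFile(out) as zf:
            zf.extractall(unzipped)
        with open_archive(out) as za, open_archive(unzipped) as da:
            assert za.descriptor == da.descriptor
            assert (list(iter_star_records(za))
                    == list(iter_star_records(da)))

    def test_missing_meta_xml(self, tmp_path):
        out = tmp_path / "bad.zip"
        with zipfile.ZipFile(out, "w") as zf:
            zf.writestr("eml.xml", "<x/>")
        with pytest.raises(ArchiveError, match="meta.xml"):
            open_archive(out)

    def test_missing_referenced_file_named(self, tmp_path, metadata):
        out = tmp_path / "a.zip"
        t = _term("scientificName")
        package_archive([("c1", {t: "X"})], {}, metadata, out,
                        core_row_type=OCC.row_type)
        bad = tmp_path / "bad.zip"
        with zipfile.ZipFile(out) as src, zipfile.ZipFile(bad, "w") as dst:
            for name in src.namelist():
                if name != "occurrence.txt":
                    dst.writestr(name, src.read(name))
        with pytest.raises(ArchiveError, match="occurrence.txt"):
            open_archive(bad)


def brute_force_join(core_ids, ext_rows_by_type):
    """Independent nested-loop join oracle: for every core id, scan every
    extension row and collect matches in file order."""
    out = {}
    for cid in core_ids:
        out[cid] = {rt: [row for row in rows if row[0] == cid]
                    for rt, rows in ext_rows_by_type.items()}
    return out


class TestStarJoin:
    def test_example_cardinalities(self, tmp_path, metadata):
        t = _term("scientificName")
        mmid = MM.terms[2]
        core = [(cid, {t: "X"}) for cid in ("1", "2", "3")]
        exts = {MM.row_type: [(cid, {mmid: f"u{i}"})
                              for i, cid in enumerate(["1", "1", "2"])]}
        out = tmp_path / "a.zip"
        package_archive(core, exts, metadata, out, core_row_type=OCC.row_type)
        with open_archive(out) as a:
            stars = list(iter_star_records(a))
        counts = {s.core_id: sum(len(v) for v in s.extension_rows.values())
                  for s in stars}
        assert counts == {"1": 2, "2": 1, "3": 0}

    def test_no_extensions_empty_groups(self, tmp_path, metadata):
        t = _term("scientificName")
        out = tmp_path / "a.zip"
        package_archive([("1", {t: "X"})], {}, metadata, out,
                        core_row_type=OCC.row_type)
        with open_archive(out) as a:
            assert all(s.extension_rows == {} for s in iter_star_records(a))

    def test_duplicate_core_id_raises_join_error(self, tmp_path, metadata):
        t = _term("scientificName")
        out = tmp_path / "a.zip"
        package_archive([("1", {t: "X"}), ("1", {t: "Y"})], {}, metadata,
                        out, core_row_type=OCC.row_type)
        with open_archive(out) as a:
            with pytest.raises(JoinError, match="1"):
                list(iter_star_records(a))

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_nested_loop_oracle(self, seed, tmp_path, metadata):
        rng = random.Random(seed)
        n_core = rng.randint(1, 60)
        n_ext = rng.randint(0, 120)
        t = _term("scientificName")
        mmid = MM.terms[2]
        core_ids = [f"id{i}" for i in range(n_core)]
        core = [(cid, {t: "X"}) for cid in core_ids]
        # ~10% orphan coreids that must not be attached to any record
        ext_pairs = []
        for i in range(n_ext):
            cid = (f"orphan{i}" if rng.random() < 0.1
                   else rng.choice(core_ids))
            ext_pairs.append((cid, {mmid: f"u{i}"}))
        out = tmp_path / "a.zip"
        package_archive(core, {MM.row_type: ext_pairs}, metadata, out,
                        core_row_type=OCC.row_type)
        with open_archive(out) as a:
            stars = {s.core_id: s for s in iter_star_records(a)}
        oracle = brute_force_join(
            core_ids, {MM.row_type: [(cid, v[mmid]) for cid, v in ext_pairs]})
        for cid in core_ids:
            got = [row[mmid] for row in
                   stars[cid].extension_rows.get(MM.row_type, [])]
            want = [u for _, u in oracle[cid][MM.row_type]]
            assert got == want

    def test_conservation_of_extension_rows(self, tmp_path, metadata):
        spec = FixtureSpec(n_records=40, extension_mean_rows=1.0, seed=3,
                           errors=ErrorSpec(orphan_extension_rows=4))
        files, truth = generate(spec, tmp_path)
        out = tmp_path / "a.zip"
        _, _, _ = build_archive_from_sources(files, "occurrence", out,
                                             metadata)
        with open_archive(out) as a:
            total = sum(sum(len(v) for v in s.extension_rows.values())
                        for s in iter_star_records(a))
        assert total == truth.extension_row_count - 4
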