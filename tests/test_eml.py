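"""EML subset round trip, data-paper export, summary page."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lxml import etree

from dwcapub.archive import ArchiveDescriptor, FileDescriptor
from dwcapub.eml import (
    DATA_PAPER_SECTIONS,
    PLACEHOLDER,
    BoundingBox,
    Creator,
    DatasetStats,
    EmlMetadata,
    GeographicCoverage,
    TemporalCoverage,
    export_data_paper,
    parse_eml,
    render_summary_page,
    write_eml,
)
from dwcapub.errors import MetadataError
from dwcapub.publishing import PublishedVersion
from dwcapub.sources import ARCHIVE_DIALECT

MINIMAL = EmlMetadata(title="T", creators=(Creator(name="A"),))


def _version(n, year=2014, records=10):
    return PublishedVersion(
        version_number=n, timestamp=dt.datetime(year, 3, 1, 12, 0),
        archive_path=f"v{n}/archive.zip", record_count=records,
        metadata_only=False, validation_digest={"verdict": "pass"})


class TestWriteParse:
    def test_minimal_document(self):
        text = write_eml(MINIMAL)
        root = etree.fromstring(text.encode())
        ds = root.find("dataset")
        assert ds.find("title").text == "T"
        assert ds.find("creator/individualName/surName").text == "A"
        # absent optional fields are omitted, not emptied
        assert ds.find("abstract") is None
        assert ds.find("coverage") is None

    def test_round_trip_minimal(self):
        assert parse_eml(write_eml(MINIMAL)) == MINIMAL

    def test_bad_bounding_box_names_field(self):
        m = EmlMetadata(
            title="T", creators=(Creator(name="A"),),
            geographic_coverage=GeographicCoverage(
                "box", BoundingBox(west=10, east=-10, south=0, north=1)))
        with pytest.raises(MetadataError, match="geographic_coverage"):
            write_eml(m)

    def test_empty_title_rejected(self):
        with pytest.raises(MetadataError, match="title"):
            write_eml(EmlMetadata(title=" ", creators=(Creator(name="A"),)))

    def test_no_creator_rejected(self):
        with pytest.raises(MetadataError, match="creators"):
            write_eml(EmlMetadata(title="T", creators=()))

    def test_missing_title_on_parse(self):
        with pytest.raises(MetadataError, match="title"):
            parse_eml("<eml xmlns='eml://ecoinformatics.org/eml-2.1.1'>"
                      "<dataset/></eml>".replace("eml xmlns",
                                                 "eml:eml xmlns:eml")
                      .replace("</eml>", "</eml:eml>"))

    def test_foreign_elements_survive_rewrite(self):
        text = write_eml(MINIMAL).replace(
            "</dataset>",
            "<pubDate>2014-01-01</pubDate><custom>x</custom></dataset>")
        m = parse_eml(text)
        assert len(m.extras) == 2
        again = write_eml(m)
        assert "<pubDate>2014-01-01</pubDate>" in again
        assert "<custom>x</custom>" in again
        assert parse_eml(again) == m

    def test_dublin_core_accepted_on_read(self):
        dc = """<metadata xmlns:dc="http://purl.org/dc/elements/1.1/">
          <dc:title>DC dataset</dc:title>
          <dc:creator>B. Writer</dc:creator>
          <dc:rights>CC-BY</dc:rights>
        </metadata>"""
        m = parse_eml(dc)
        assert m.title == "DC dataset"
        assert m.creators[0].name == "B. Writer"
        assert m.rights == "CC-BY"


_texts = st.text(
    alphabet=st.characters(codec="utf-8", exclude_categories=("Cs", "Cc")),
    min_size=1, max_size=20).map(lambda s: s.strip()).filter(bool)
_creators = st.builds(
    Creator, name=_texts,
    organization=st.one_of(st.just(""), _texts),
    email=st.one_of(st.just(""), _texts))
_lon = st.floats(min_value=-180, max_value=180, allow_nan=False)
_lat = st.floats(min_value=-90, max_value=90, allow_nan=False)
_boxes = st.builds(
    lambda a, b, c, d: BoundingBox(west=min(a, b), east=max(a, b),
                                   south=min(c, d), north=max(c, d)),
    _lon, _lon, _lat, _lat)
_metadata = st.builds(
    EmlMetadata,
    title=_texts,
    creators=st.lists(_creators, min_size=1, max_size=3).map(tuple),
    abstract=st.one_of(st.just(""), _texts),
    rights=st.one_of(st.just(""), _texts),
    keywords=st.lists(_texts, max_size=3).map(tuple),
    geographic_coverage=st.one_of(
        st.none(),
        st.builds(GeographicCoverage, description=_texts,
                  bounding_box=st.one_of(st.none(), _boxes))),
    taxonomic_coverage=st.lists(
        st.tuples(st.sampled_from(["kingdom", "family", "genus"]), _texts),
        max_size=3).map(tuple),
    temporal_coverage=st.one_of(
        st.none(), st.builds(TemporalCoverage,
                             start=st.just("2001-01-01"),
                             end=st.just("2002-12-31"))),
    methods=st.one_of(st.just(""), _texts),
    citation=st.one_of(st.just(""), _texts),
    language=st.one_of(st.just(""), st.sampled_from(["en", "es", "da"])),
)


@settings(max_examples=100, deadline=None)
@given(m=_metadata)
def test_round_trip_is_identity_on_modeled_subset(m):
    assert parse_eml(write_eml(m)) == m


class TestDataPaper:
    def test_always_eleven_sections_in_fixed_order(self):
        draft = export_data_paper(MINIMAL)
        headings = [line[3:] for line in draft.splitlines()
                    if line.startswith("## ")]
        assert headings == list(DATA_PAPER_SECTIONS)

    def test_missing_methods_gets_placeholder(self):
        draft = export_data_paper(MINIMAL)
        section = draft.split("## Methods")[1].split("##")[0]
        assert PLACEHOLDER in section

    def test_stats_in_dataset_description(self):
        stats = DatasetStats(record_count=10,
                             core_row_type="http://x/Occurrence")
        draft = export_data_paper(MINIMAL, stats)
        section = draft.split("## Dataset Description")[1].split("##")[0]
        assert "10 records" in section
        assert "http://x/Occurrence" in section

    def test_full_metadata_populates_all_sections(self):
        m = EmlMetadata(
            title="Full", creators=(Creator(name="A", organization="Org"),),
            abstract="abs", rights="CC0", keywords=("k1", "k2"),
            geographic_coverage=GeographicCoverage(
                "desc", BoundingBox(-10, 10, -5, 5)),
            taxonomic_coverage=(("genus", "Puma"),),
            temporal_coverage=TemporalCoverage("2001", "2002"),
            methods="netting", citation="c")
        draft = export_data_paper(
            m, DatasetStats(record_count=3, core_row_type="rt"))
        assert PLACEHOLDER not in draft


class TestSummaryPage:
    def _descriptor(self):
        return ArchiveDescriptor(core=FileDescriptor(
            location="occurrence.txt",
            row_type="http://rs.tdwg.org/dwc/terms/Occurrence",
            dialect=ARCHIVE_DIALECT))

    def test_single_version_links_archive(self):
        page = render_summary_page(MINIMAL, self._descriptor(), [_version(1)])
        assert 'href="v1/archive.zip"' in page

    def test_versions_listed_newest_first(self):
        page = render_summary_page(
            MINIMAL, self._descriptor(),
            [_version(1, 2012), _version(2, 2013), _version(3, 2014)])
        body = page[page.index("Version history"):]
        assert (body.index("<td>3</td>") < body.index("<td>2</td>")
                < body.index("<td>1</td>"))

    def test_citation_fallback_composed(self):
        page = render_summary_page(MINIMAL, self._descriptor(),
                                   [_version(2, year=2014)])
        assert "A (2014). T. Version 2." in page

    def test_no_versions_is_error(self):
        with pytest.raises(MetadataError):
            render_summary_page(MINIMAL, self._descriptor(), [])

    def test_self_contained_well_formed_html(self):
        page = render_summary_page(MINIMAL, self._descriptor(), [_version(1)])
        assert "http-equiv" not in page
        assert 'src="http' not in page and "link rel" not in page
        etree.fromstring(page.encode(), etree.HTMLParser(recover=False))
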