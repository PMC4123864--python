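<?xml version="1.0" encoding="UTF-8"?>
<!-- Taxon Core (checklist) term subset bundled with dwcapub. -->
<extension xmlns="http://rs.gbif.org/extension/"
           title="Darwin Core Taxon"
           rowType="http://rs.tdwg.org/dwc/terms/Taxon">
  <property qualName="http://rs.tdwg.org/dwc/terms/taxonID"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/scientificNameID"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/acceptedNameUsageID"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/parentNameUsageID"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/scientificName"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/acceptedNameUsage"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/parentNameUsage"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/nameAccordingTo"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/namePublishedIn"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/namePublishedInYear"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/higherClassification"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/kingdom"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/phylum"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/class"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/order"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/family"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/genus"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/subgenus"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/specificEpithet"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/infraspecificEpithet"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/taxonRank"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/verbatimTaxonRank"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/scientificNameAuthorship"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/vernacularName"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/nomenclaturalCode"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/taxonomicStatus"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/nomenclaturalStatus"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/taxonRemarks"/>
  <property qualName="http://purl.org/dc/terms/modified"/>
  <property qualName="http://purl.org/dc/terms/language"/>
  <property qualName="http://purl.org/dc/terms/license"/>
  <property qualName="http://purl.org/dc/terms/references"/>
</extension>
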