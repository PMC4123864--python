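<?xml version="1.0" encoding="UTF-8"?>
<!-- Occurrence Core term subset bundled with dwcapub (transcribed once from
     the public core definition; membership is a fixture of this package). -->
<extension xmlns="http://rs.gbif.org/extension/"
           title="Darwin Core Occurrence"
           rowType="http://rs.tdwg.org/dwc/terms/Occurrence">
  <property qualName="http://rs.tdwg.org/dwc/terms/occurrenceID"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/basisOfRecord"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/institutionCode"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/collectionCode"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/catalogNumber"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/recordedBy"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/individualCount"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/sex"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/lifeStage"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/occurrenceStatus"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/preparations"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/associatedMedia"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/occurrenceRemarks"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/eventID"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/samplingProtocol"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/eventDate"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/year"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/month"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/day"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/habitat"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/fieldNumber"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/locationID"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/continent"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/waterBody"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/islandGroup"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/island"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/country"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/countryCode"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/stateProvince"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/county"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/locality"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/minimumElevationInMeters"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/maximumElevationInMeters"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/minimumDepthInMeters"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/maximumDepthInMeters"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/decimalLatitude"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/decimalLongitude"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/geodeticDatum"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/coordinateUncertaintyInMeters"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/georeferencedBy"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/identifiedBy"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/dateIdentified"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/identificationRemarks"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/taxonID"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/scientificName"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/acceptedNameUsage"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/kingdom"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/phylum"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/class"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/order"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/family"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/genus"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/specificEpithet"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/infraspecificEpithet"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/taxonRank"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/scientificNameAuthorship"/>
  <property qualName="http://rs.tdwg.org/dwc/terms/vernacularName"/>
  <property qualName="http://purl.org/dc/terms/type"/>
  <property qualName="http://purl.org/dc/terms/modified"/>
  <property qualName="http://purl.org/dc/terms/language"/>
  <property qualName="http://purl.org/dc/terms/license"/>
  <property qualName="http://purl.org/dc/terms/rightsHolder"/>
  <property qualName="http://purl.org/dc/terms/references"/>
</extension>
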