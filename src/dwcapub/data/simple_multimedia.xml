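<?xml version="1.0" encoding="UTF-8"?>
<!-- Simple Multimedia extension term subset bundled with dwcapub. -->
<extension xmlns="http://rs.gbif.org/extension/"
           title="Simple Multimedia"
           rowType="http://rs.gbif.org/terms/1.0/Multimedia">
  <property qualName="http://purl.org/dc/terms/type"/>
  <property qualName="http://purl.org/dc/terms/format"/>
  <property qualName="http://purl.org/dc/terms/identifier"/>
  <property qualName="http://purl.org/dc/terms/references"/>
  <property qualName="http://purl.org/dc/terms/title"/>
  <property qualName="http://purl.org/dc/terms/description"/>
  <property qualName="http://purl.org/dc/terms/created"/>
  <property qualName="http://purl.org/dc/terms/creator"/>
  <property qualName="http://purl.org/dc/terms/contributor"/>
  <property qualName="http://purl.org/dc/terms/publisher"/>
  <property qualName="http://purl.org/dc/terms/audience"/>
  <property qualName="http://purl.org/dc/terms/source"/>
  <property qualName="http://purl.org/dc/terms/license"/>
  <property qualName="http://purl.org/dc/terms/rightsHolder"/>
</extension>
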