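<?xml version="1.0" encoding="UTF-8"?>
<!-- Synthetic XML Schema for the archive structural descriptor (meta.xml),
     authored for this package's test suite from the descriptor structure
     the codec emits: an archive root in the Darwin Core text namespace
     holding one core element and any number of extension elements, each
     with dialect attributes, a files/location child, an id (core) or
     coreid (extension) element, and indexed field bindings.  It is a
     stand-in fixture, not the normative published schema. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:dwc="http://rs.tdwg.org/dwc/text/"
           targetNamespace="http://rs.tdwg.org/dwc/text/"
           elementFormDefault="qualified"
           attributeFormDefault="unqualified">

  <xs:complexType name="filesType">
    <xs:sequence>
      <xs:element name="location" type="xs:string" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="idType">
    <xs:attribute name="index" type="xs:nonNegativeInteger"/>
  </xs:complexType>

  <xs:complexType name="fieldType">
    <xs:attribute name="index" type="xs:nonNegativeInteger"/>
    <xs:attribute name="term" type="xs:anyURI" use="required"/>
    <xs:attribute name="default" type="xs:string"/>
    <xs:attribute name="vocabulary" type="xs:anyURI"/>
  </xs:complexType>

  <xs:attributeGroup name="fileAttributes">
    <xs:attribute name="rowType" type="xs:anyURI" use="required"/>
    <xs:attribute name="fieldsTerminatedBy" type="xs:string"/>
    <xs:attribute name="fieldsEnclosedBy" type="xs:string"/>
    <xs:attribute name="linesTerminatedBy" type="xs:string"/>
    <xs:attribute name="ignoreHeaderLines" type="xs:nonNegativeInteger"/>
    <xs:attribute name="encoding" type="xs:string"/>
    <xs:attribute name="dateFormat" type="xs:string"/>
  </xs:attributeGroup>

  <xs:complexType name="coreFileType">
    <xs:sequence>
      <xs:element name="files" type="dwc:filesType"/>
      <xs:element name="id" type="dwc:idType" minOccurs="0"/>
      <xs:element name="field" type="dwc:fieldType"
                  minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attributeGroup ref="dwc:fileAttributes"/>
  </xs:complexType>

  <xs:complexType name="extensionFileType">
    <xs:sequence>
      <xs:element name="files" type="dwc:filesType"/>
      <xs:element name="coreid" type="dwc:idType"/>
      <xs:element name="field" type="dwc:fieldType"
                  minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attributeGroup ref="dwc:fileAttributes"/>
  </xs:complexType>

  <xs:element name="archive">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="core" type="dwc:coreFileType"/>
        <xs:element name="extension" type="dwc:extensionFileType"
                    minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="metadata" type="xs:string"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
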