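# RDA FAIR data maturity recommendations and their implementation status
# for marine images under the iFDO standard and its infrastructure.
# Ranks: essential / important / useful (the RDA's own three tiers).
# Implementation strings are the published status wording; the literal
# strings "N/A for images" and "iFDO v2.0.0" mark rows that are not
# applicable to image data or deferred to a later standard version.
rows:
  - {id: RDA-F1-01M, rank: essential, description: "Metadata is identified by a persistent identifier", implementation: "URL:handle@ifdo"}
  - {id: RDA-F1-01D, rank: essential, description: "Data is identified by a persistent identifier", implementation: "URL:handle@data"}
  - {id: RDA-F1-02M, rank: essential, description: "Metadata is identified by a globally unique identifier", implementation: "image-set-uuid"}
  - {id: RDA-F1-02D, rank: essential, description: "Data is identified by a globally unique identifier", implementation: "image-set-uuid"}
  - {id: RDA-F2-01M, rank: essential, description: "Rich metadata is provided to allow discovery", implementation: "iFDO format"}
  - {id: RDA-F3-01M, rank: essential, description: "Metadata includes the identifier for the data", implementation: "URL:handle"}
  - {id: RDA-F4-01M, rank: essential, description: "Metadata is offered in a way to be harvested and indexed", implementation: "iFDO by https"}
  - {id: RDA-A1-01M, rank: important, description: "Metadata contains info to enable accessing the data", implementation: "URL:handle@data"}
  - {id: RDA-A1-02M, rank: essential, description: "Metadata can be accessed manually", implementation: "URL:handle"}
  - {id: RDA-A1-02D, rank: essential, description: "Data can be accessed manually", implementation: "URL:MAMS"}
  - {id: RDA-A1-03M, rank: essential, description: "Metadata identifier resolves to a metadata record", implementation: "URL:handle@ifdo"}
  - {id: RDA-A1-03D, rank: essential, description: "Data identifier resolves to a digital object", implementation: "URL:handle@data"}
  - {id: RDA-A1-04M, rank: essential, description: "Metadata is accessed through standardized protocol", implementation: "https"}
  - {id: RDA-A1-04D, rank: essential, description: "Data is accessible through standardized protocol", implementation: "https, nfs, ..."}
  - {id: RDA-A1-05D, rank: important, description: "Data can be accessed automatically", implementation: "MAMS-API"}
  - {id: RDA-A1.1-01M, rank: essential, description: "Metadata is accessible through a free protocol", implementation: "https"}
  - {id: RDA-A1.1-01D, rank: important, description: "Data is accessible through a free access protocol", implementation: "https"}
  - {id: RDA-A1.2-01D, rank: useful, description: "Data is accessible with authentication and authorization", implementation: "https"}
  - {id: RDA-A2-01M, rank: essential, description: "Metadata is guaranteed to remain available after data loss", implementation: "handle system"}
  - {id: RDA-I1-01M, rank: important, description: "Metadata uses knowledge representation in standard format", implementation: "iFDO format"}
  - {id: RDA-I1-01D, rank: important, description: "Data uses knowledge representation in standard format", implementation: "e.g. jpg, png, mov"}
  - {id: RDA-I1-02M, rank: important, description: "Metadata uses machine-understandable knowledge representation", implementation: "yaml"}
  - {id: RDA-I1-02D, rank: important, description: "Data uses machine-understandable knowledge representation", implementation: "e.g. jpg, png, mov"}
  - {id: RDA-I2-01M, rank: important, description: "Metadata uses FAIR-compliant vocabularies", implementation: "in preparation"}
  - {id: RDA-I2-01D, rank: useful, description: "Data uses FAIR-compliant vocabularies", implementation: "in preparation"}
  - {id: RDA-I3-01M, rank: important, description: "Metadata includes references to other metadata", implementation: "ORCID etc."}
  - {id: RDA-I3-01D, rank: useful, description: "Data includes references to other data", implementation: "image-uuid"}
  - {id: RDA-I3-02M, rank: useful, description: "Metadata includes references to other data", implementation: "image-set-uuid"}
  - {id: RDA-I3-02D, rank: useful, description: "Data includes qualified references to other data", implementation: "N/A for images"}
  - {id: RDA-I3-04M, rank: useful, description: "Metadata includes qualified references to other data", implementation: "N/A for images"}
  - {id: RDA-I3-03M, rank: important, description: "Metadata includes qualified references to other metadata", implementation: "iFDO v2.0.0"}
  - {id: RDA-R1-01M, rank: essential, description: "Plurality of accurate and relevant attributes are provided for reuse", implementation: "iFDO capture & content fields"}
  - {id: RDA-R1.1-01M, rank: essential, description: "Metadata includes information about the reuse license", implementation: "iFDO core fields"}
  - {id: RDA-R1.1-02M, rank: important, description: "Metadata refers to a standard reuse license", implementation: "iFDO core fields"}
  - {id: RDA-R1.1-03M, rank: important, description: "Metadata refers to a machine-understandable reuse license", implementation: "iFDO v2.0.0"}
  - {id: RDA-R1.2-02M, rank: useful, description: "Metadata includes cross-community provenance info", implementation: "iFDO v2.0.0"}
  - {id: RDA-R1.2-01M, rank: important, description: "Metadata includes community-specific provenance info", implementation: "iFDO capture & content fields"}
  - {id: RDA-R1.3-01M, rank: essential, description: "Metadata complies with a community standard", implementation: "iFDO file format"}
  - {id: RDA-R1.3-01D, rank: essential, description: "Data complies with a community standard", implementation: "e.g. jpg, png, mov"}
  - {id: RDA-R1.3-03M, rank: essential, description: "Metadata uses a machine-understandable standard", implementation: "yaml"}
  - {id: RDA-R1.3-02D, rank: useful, description: "Data uses a machine-understandable standard", implementation: "e.g. jpg, png, mov"}
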