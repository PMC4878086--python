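# Worked example configuration: the curated stem-cell retrieval thesaurus.
# 15 root MeSH descriptors, 5 free-text supplements (valuable terms that are
# not MeSH descriptors, rescuing recent articles with no MeSH indexing yet),
# and 3 noisy-hyponym exclusions (cell lines filed under progenitor cells
# but indexing routine cell-line literature).
roots:
  - Stem Cells
  - Stem Cell Transplantation
  - Nuclear Reprogramming
  - Hematopoiesis
  - Stem Cell Niche
  - Bone Marrow Transplantation
  - Adipogenesis
  - Cell Transdifferentiation
  - Stem Cell Research
  - Hematopoietic Stem Cell Mobilization
  - Nuclear Transfer Techniques
  - Cell Dedifferentiation
  - Stem Cell Factor
  - Blastocyst Inner Cell Mass
  - Tumor Stem Cell Assay
freetext:
  - stemness
  - stem cell
  - progenitor cell
  - ipsc
  - ips cell
exclusions:
  - HL-60 Cells
  - U937 Cells
  - K562 Cells
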