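# Example classified-thesaurus configuration: anatomy categories for
# stem-cell literature analysis.  Each category lists the MeSH descriptors
# whose exploded subtrees define membership; categories may overlap.
# Validate against a full MeSH vocabulary with meshkos.load_categories.
framework: anatomy
categories:
  Cardiovascular System:
    - Cardiovascular System
    - Cardiovascular Physiological Phenomena
    - Diagnostic Techniques, Cardiovascular
    - Cardiovascular Diseases
  Respiratory System:
    - Respiratory System
    - Respiratory Physiological Phenomena
    - Respiratory Tract Diseases
    - Carcinoma, Lewis Lung
    - Diagnostic Techniques, Respiratory System
  Digestive System:
    - Digestive System
    - Liver Regeneration
    - Digestive System and Oral Physiological Phenomena
    - Stomatognathic System
    - Digestive System Diseases
    - Diagnostic Techniques, Digestive System
    - Stomatognathic Diseases
    - Odontogenic Tumors
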