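# Substance-level headings (protein subunits, sequencing artifacts, small
# molecules): broad meaning, hard to place in a domain classification,
# excluded from candidate term sets.
Proteins
DNA
RNA
RNA, Messenger
Base Sequence
Amino Acid Sequence
Molecular Sequence Data
Sequence Analysis, DNA
Transcription Factors
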