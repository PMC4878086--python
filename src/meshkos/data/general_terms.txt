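# Check tags and very common indexing terms: too general to discriminate a
# research domain, excluded from candidate term sets.
Humans
Animals
Cell Line
Male
Female
Adult
Middle Aged
Aged
Child
Mice
Rats
Cells, Cultured
Time Factors
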