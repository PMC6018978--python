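>probe_1carg 51-nt saturation-assay probe with one central CArG-box (CCAAATAAGG); stored letter-for-letter as designed, read 5'->3' (the source's 3'/5' annotation refers to the complementary strand)
AATTCGAAATTTAATTATATTCCAAATAAGGAAAGTATGGAACGTTGAATT
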