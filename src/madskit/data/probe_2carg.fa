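>probe_2carg 151-nt EMSA probe with two CArG-boxes (CCAAATAAGG) 63 bp apart (six helical turns); AGAMOUS-intron-derived box
TCGAGGTCGGAAATTTAATTATATTCCAAATAAGGAAAGTATGGAACGTTCGACGGTATC
GATAAGCTTGATGAAATTTAATTATATTCCAAATAAGGAAAGTATGGAACGTTATCGAAT
TCCTGCAGCCCGGGGGATCCACTAGTTCTAG
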