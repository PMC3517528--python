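>Mar_synthetic_reference
CAGGGGTAGGCTCATGAATAACTGATCAATAAATAAGATAGATAAGACTATAATAGAGGTTGGCTGGATA
AGGAGAAGACCGCGAATCGTATGTGAACGTCCCTTTTTTGCAATCGGTGCTAATCATAGATCCTATAAAT
CAGACGGATATGTGAGAGTATTCTAACAATTCAAATATATTACTTAATAGGCACTGTGTAGTGCAATATG
GTTAACAACGATAATAAACAAATATCCCGCAATATAAAAGTTTAACTGGTTCCAGATAGGGTCCTTATTG
ACAAATTTTAACATTCTGGCTGAAGACAAATGGTGCAAGGCAACGATTTAAATTATTCCGAACGGACGGT
TTACTAGTCGTGTACTCTGCGAATTCTTAGAGTTAGATGCTCAGCAAATTAATTTGTCGGTTCGCCATTT
AGGTAAATGGTTAAGGCCGGTGTGATAATGAATCTAAACAATTATTATCCAACTTAAGAATGTACTGGAC
CTTGCACGAAGGAGGCAGAGATTTATGTACTTCGTGCTCACATCGGGAACTTCACCCTTACCTCTGTATT
TTTCAGGAGCGCTGTTTGCAACACCTGTATCAAGCTACTGCCTACCTCTG
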