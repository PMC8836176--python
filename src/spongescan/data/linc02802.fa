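>LINC02802 full-length transcript, as cloned into pcDNA3.1 (DNA notation)
GCGCAGGCGCCCAGAGGCGCACAGGAGACCTCAGGCCCAGACTCCACTCCCCAGCTGTGAAAGGACTGCT
GGCCAGACCCCCAAGCTAGCCCGCCAGGCCTCCATAGAGCTGCCCAGCATGGCTGCATCCAGTACCAAGA
GTTGGTGGGAGACGGGTGAGGTACAGGCTCAGTCTGCGGCCAAGACTCCGTCCTGCAAGACTCTTTGGCA
GTTGCACTGGGTACTGGCTGAGTTCTGGAAAACAGGAATGTGAGCAGAGTGCTGCAGATCTCCTTGTCAG
GAGCACCTAAGAACTGGCATGACTCTACACCCTCTCTCCTTCTGCAATGACCTCGTGTCAAGATGGCAGA
CCCGCAGAGATGAATGTGCCTGGATACCTGAGTCACCAGGTGGAGGAAACTCCCATTGACATGCATCACA
CTCCACATATGAAACCCTTCTTTTTCTGCACTGTCACTGGGGTTAGGGATTATTACTCACTGCAACTTAG
CCTAGCATTAAGTTGCTTGACTAATACAAGTTTCAATAAATGTCGCTTCATTTCCCATG
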