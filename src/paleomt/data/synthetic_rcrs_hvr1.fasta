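>synthetic_rcrs_hvr1 synthetic stand-in reference window, np 16056-16409
AGGGTCGCCCAGGAGCGTGCTTTCGGACTGTATTATTTACTCACCTTAAAAATTCTATCC
CTGTCTATACGTAGATGAGGGCAAAACTTAAGGGTTAATCGCATGGGATATTTGGTGCGT
GCGGTCTTCCCGTACCGGCATACATTTTCAGAGATCGGCGGAGCACTGGTGAAGTCAAGA
ACGCGTTTTCGTTGGGTCCGCTTTCTACTACCCGAATACACCGCGCTTAAATTCCGCCAG
GGATATCCTTATCCTATAGAACCGGAATTACAATGGCTTTCCTGGTGACGCTGTCCCCGC
TCAAACAATAAGTTGAAACGCTTGAGAGGCCTAATGCGCTGAGTTAACGTACGT
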