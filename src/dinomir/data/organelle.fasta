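>mito_1
GTTGCCACAGAGCCAGTGGACAGTGGCTTCGGTAGCCGGATGAAGTTACAACCCATATTTATGGCCCCAA
GGGCTGCCTCGACCTTGCGCAGCGACAGACTTTGGCTTACACAAACGTTACACGAGCTCCCTTAAAGCCA
TCCTGAAACA
>plastid_1
CCTTCGTTCCATCATCCCGTCGAATATTTTAGAGACTCCAGGCTAGCCAAACGTGGCGATTGATAGAAAA
AATGTGGGTAAACAATGGAAATAGAAGGAACATGGGCAGTTTTACGGAGAACGATAGACTGACGCTTTGC
TCAACGCAGC
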