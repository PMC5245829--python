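>rRNA_1
CAGTAGCTCACGATTCTTAGTAGTCTGCTGCGAGCCCTCCACGGCGTCGCAACACTATATGGCCAATGCC
ACATTTCATTGTGGTCTAGGAGACCGAACACTATGTTCGACTTTGCTATCTCATCGTTTCCTATAAGGTG
GGGGATCCCC
>rRNA_2
GATATTATCTTATTCTGGCACACGACTGATATTAAGGATAGACATTCGTATAAGTAGACTGGCACCACAG
GGGAGCATGGCGAGTAAAATCCCGTTATCGATTCGGCAAAATGCCTAAGAGCACGATAAACGTTGTCGTG
CAAATCGCCT
>rRNA_3
AAGAGCCCGTCGGAAAAGACAGTATCTGGTCTCGCGTCCGTCTTCGTCTCCCTCCGCTCCTTCATGTCCC
TGACAGGTGAGCGCTCGCCAGTCGTAATGAGACCACCGCTCAGGGGCACCACTTACAATTACGCCAGAGG
GTAGCGGCGC
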