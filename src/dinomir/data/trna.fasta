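>tRNA_1
ACACACGGGAAATAGTGGGAGTGTAAACAGCGTTGAACAAAGACTAGGCGCTACTTGTAGTATTTCCAGA
GCTGAGGTGGACGTTGGTCT
>tRNA_2
AATGAGCCCGTATCGAGCAGATGGAGTACTTTTCCGATATGAAGTCAACTTTAGACGACCGAGCAGTATG
TCCAGACAGGGCTCGCGATT
>tRNA_3
GGAGATCGCGACACGATAGGATTAATAGGAATTAATCACATTACCCCAGAGTACCCTATGTGCCCACGAT
AACCTTCGTACCTAATAAAG
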