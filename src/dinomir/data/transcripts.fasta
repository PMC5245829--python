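>LBP_like
GTAGATACAGGGTGATCTCGCTTATGCGAACATTGAGAACGCAGCATATCGAGGCTTCTAAATTACTCTT
GTTCGGCAGCATAGATTCGGGCAGCAGACATCGATGCGCGGGCAGCGCCGGCCCGCATGAGCTAATTAAT
TTCCCACCGGCAGGTATATCATTAGATACCAGCATGCACGTTCATGGTATGATAGTTTCCGCTTCACGTG
TGGCAAATCTTGACAGGGTGTTTCGCCATGACCTAGGCTCACCAGGTGTCACGGCCAAGGGCGCGCCACA
ATGAAATACGGCAAGTTGCCAACGCATTCTCGTCCCATTTTAGTCCGTTATACTAGACCATGAGACAGAA
AAACGCTAGTGCCTGGGAACTTGCTGCTGGAGCATGCCTTTACCGTAAACCAATCGGCTATCTGAGGTTA
TGGGTTATCTCTTTAGTTCATTGCCCGAATCGTAGAGCTCGAGTTGCTGGCCCCTACAGC
>transcript_2
AACACTCCGAGCAAGCACCTGCGAGACACTTCTAATCCCGACCTCATGAGTCACATAAGAAGGTGGCCCC
AAACTTATATGCCCGTTTGTTACGATGAACACCCACGATAAACCCATAGTCAATTGAGGTTCACGACCTG
GTAATACGTTGAATAGGGCATGAGCTCAGGCATCCCAAGGATCTAGTGGGGGCGCATATCATTAACCATC
CGGCCCCAAAGGCCCTAGTTCCATCGTATCACTTCCTATCCGCCGAAACGCCACGTGCAGCCTTAGCCAA
GTGGGAAGGCTTACCCAGTATATATGGTAGCGCAGCAACCCACTCTGATCCACCTGCCGTTGAGTCTATC
GAGCTAGGCGGATCACTAATAGCTCAGCTTAAAGTAGGCAAGCAAAGATT
>transcript_3
TGGGCTGCGCAGAGTACAACTGGAGGTAATGGGCCTCTTGGGAAAGGTGTCTGTCTTAAGCACGTTGTTG
AAGTGTGCGCCCTTACGAGCATTGCTCCGGGTCCAGTTATCCAGTATGACTGGTTCTGTGTTTCCGAGGA
TAGGCGACCACGCACGATACTTCTACACGAACGCTGAAACACATAGTAGACTGGGTATGGATATCAAGAA
GGGAACCCACATCCAGGATAGTTCCTCGAAAATTTCTTTCCTGGCAAGGGAACGGTAGATCCCTATGGGA
AAGATTCTAAAGCAAACGTTACCTTGAAGAACCTGGTATAGCACATAAGCTACGTTGCCGAGATGTGGAC
CGGGGAGAGGCAACAATGACTGACCCGCGGAACTTAGATAACTATGCCCGCAGACAGCGTATTGCACTAT
>transcript_4
GTTCTCCACACTCAACCTTCGCGCCCTCTTACACCGGGATTATTCATAGGTACGAGTACCAGGGTACAAT
GTGGCAAATAAAAAGGAGATTTACGCGTGCATTATGATAGACGGGATCTTAGCGGGCAAAGAAGGTTGTC
TTCTTTAGCTTACAACGTCCAGGGTGTAAAGCCCGCTGGGTCGCCCCGGACGAATGCGCGTGCTGCGTTG
ACGCTCCGAATAGAATGTAACACAGAGTACGTGTGATGCATAGTCATCCAAACGATCGTCCTCCGCGGTC
TGCGAAAATCTATCACGAACGATGGGTAGAACAGGTCTGCTGAACCAAGTCCGTACCAGCAGAACACCGT
ACGTTGGTAAACTTAACTTTGAGTATACACTATTCAAAGGCAAATTCCGGTGTATCAGCTAGTAAAGTGT
AGTGCCGGGGTTTCTTCAGG
>transcript_5
GCCTATTCCCCTCTGAGTTATGGTAGTAGGGGTGGGTAGGGCGCCAACGAAGTCGCACCTACGAACGGTA
CGGAGTCTTTGGTCTTATACGGACCCCCCGACTATGTAGCACTTCGCGTAGTCAGGGGTGCCACTGGGTG
ACATCTCGGGCATGCGCCCCATCAATTTGCCCCTTGGATTAACAACGTTAGCAACATTACGATTATATAC
CTCAAAAATTACTGGGATATTATTTACCACGGGGTATGCGTGATTCTTCTTACAAGAGTTGTGGTGTTTT
CGATCCTCTGCCGTGCGATCGAAGATCCGCGGATTAGCCAGCCTGTTCCCCAATAAACTAGTACCATTTA
CCTACAGCGTGCCGCGACCAGGAGACTACCACCGAGACCTCTGAAGGTGGAACTTAACGTTCTCACAGTA
GTTGAACCATACTGGAGCTGTGCACGGATGGCTAACTGTA
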