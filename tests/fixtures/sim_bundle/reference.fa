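>chrSim
CTGTATCCGTTATTGTTAACAGAATATTACGACTGAGGGGTACCATATTACGGAAGAGCTTCCGAAGGCT
CGTACTGGGATAATTGAAGGCTGCGAGATGCGAACCCTCTAGTTCGATAGCTTTCGTCAGAGTGTAAACA
GAGCAAGACGGGGCATGGATAATAGGGGAAGCACGCGGAGTCTAGACGTCTACGCTACTCGCAGCAGTAT
GTGACTTTGTTATTTGGGAATGGGTCACCGGCCGCGCTGTAAGTAGGTGGAGATGGGTGTCGTGCCATGG
TGCAATTGAGTTAATTACGTCGCACTTTTGTTTCCTTTGCCACGACCCCACGGAAACCCAGCGTCACCTG
TAGGCGATTGCCCACGACAACTCCAGAGAATCCCTAAGAATAGGAATTCAATATTGTCAATAACCATCAC
AATTTTCAGCATGGACGTTCTAAGAGCTGTCTGTCCCGAGGCGGGGAAGTTGTAAGCCCTATGGTTGATT
TAGGACAAAGAGATTCGATATTTACCTGCACTTGATTCCCGTTAACTCGTGCGATGACTTACCCTGGAAA
GACCTAGTGTATTAAGGGCCCACTGCCAGAACTTATGCGGGAGGATATCCCGCCTCAATTTGGTGTTTTG
TCACTAACACAAGGATCATGGCAGGAGTACAAAGGTGATAAGCCCACATCGAACACTCTCTTCAGCGAGC
TTCTGGAGAATCGTGGGTACATTCTTTAGAGTCCGAAGACTGCCAACACGGAGTATCCCGGGAACAAACA
ATCTCGCCTAGCTCGTGAAGTGAACATCTTCCGTACTCCACGACGCATAATAGTGGTGCTCTCGCTTAAT
ATGGGGCTAGCTGTGGTACAGTACATTAGAACTGCGGTGCACAACCAGGCCACTTACATCATCAAACCGG
GTTGGGAGGATTGAATGTCCCCTAATCATGTCGACAATGCGCCGGTCTGTTAAACAATTCTCCGAGCCTT
CGATTGATCACCCGCCCAAACCGATGTAAGTGTAACGAATTAAAAGGTCTAGCAACTGTCGTGTGTGCAC
TATCGCCTTTGAAGGGAAGTGTACGGCACGTGACACCCGTCACTATAGTTTCTATTGCATACTGTATTAT
AGTCCATACTAAACCTCTCACCATGGTCCCTTGGGGACGACAAACTGAGCCATATTGCGCATTTGGGATG
TCTCAACCAG
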