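>DAZL synthetic stand-in for the DAZL promoter amplicon (AC010139 79235-79514); 280 bp, 31 CpGs
TGCGTGAACCTCGACACATCAACACGGGGCTCGCCAACACCGGGGCCCGACCAACAGATTCGCAGTAGCGCAGAGCTACGCTCATTGCGGCAGCACGACTGTCGCATAGCACCCGCACTGAGCCGCCCAGCGGACCCACGCAGAGCCTCCGATAGGGCGACACACGCACAACATAGTCGGTGCGTGATTTGGTCACGTAGGCGAATGCCAAGGCGCATATACGACCATTCACGCTCCTGCGCAAAGGCCGCCTACCCCGGGACTCCCGGTACCCCACGCA
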