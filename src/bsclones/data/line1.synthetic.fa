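>LINE1 synthetic stand-in for the LINE-1 5'UTR amplicon (X58075 113-357); 244 bp, 19 CpGs
TTCGACAGGCATACAAAGCGTGGCCTCTTACGTCATGTCCAACGGCTGCACCATCGGCCATATAACCCAGCGTACAATCATTTACGCATCTGGTGGCGGGTAGCAGAGGCGGTATAGGCCAGACGCCAGTGGCGAGAAACATTCCCGACAGTAACATCTCGCCAGCTTCAGCGTAATCATTCACTGACGCAACCATTCGACCAGACCTTTACACGGTCAGCTTCCCGTGTCTAGACAGCGTATC
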