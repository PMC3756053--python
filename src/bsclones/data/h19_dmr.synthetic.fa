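>H19 synthetic stand-in for the H19-DMR amplicon (AF125183 7875-8096); 221 bp, 18 CpGs
TACAGCCGATGGCTGAGGCGAACTGGCTATCGAAACCAACTCACGAGCACAGGGCGTGACAGCACTGTCGGGCAAACCCGCTATCTACCCGATAACATATCTGCGAGCACTCTTCGGACACACTATGCACGGCTTCAGTTGCCGCATTCAATTCGCAAGTCCAACGTCCAGCTGGCCTCGCACATGGTATTCGCATGTTGTGCGCTATATCCAGCCGAGGT
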