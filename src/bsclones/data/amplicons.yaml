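# Default amplicon panel for bisulfite clone analysis of sperm DNA.
# Sequences are packaged synthetic stand-ins with the documented CpG
# architecture; accession coordinates and primers are metadata only.
amplicons:
  - name: H19
    accession: AF125183
    ref_start: 7875
    ref_end: 8096
    fasta: h19_dmr.synthetic.fa
    masked_cpgs: [7]          # C/T polymorphism; a T is ambiguous after conversion
    subwindows:
      CTCF6: [4, 8]           # CTCF-binding site 6, CpG ordinals 4-8 inclusive
    schemes: [H19_DMR, CTCF6]
    primers:
      forward: AGTATATGGGTATTTTTGGAGGTTTTT
      reverse: ATAAATATCCTATTCCCAAATAACCCC
  - name: DAZL
    accession: AC010139
    ref_start: 79235
    ref_end: 79514
    fasta: dazl_promoter.synthetic.fa
    masked_cpgs: []
    subwindows: {}
    schemes: [DAZL]
    primers:
      forward: RCCTTCCTAAAACTAAAACA
      reverse: GAAGAGAAAAGGAAAATTAAGAG
  - name: LINE1
    accession: X58075
    ref_start: 113
    ref_end: 357
    fasta: line1.synthetic.fa
    masked_cpgs: []
    subwindows: {}
    schemes: [LINE1]
    primers:
      forward: TTATTAGGGAGTGTTAGATAGTGGG
      reverse: CCTCTAAACCAAATATAAAATATAATCTC
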