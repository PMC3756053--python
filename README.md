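# bsclones

Bisulfite clone-sequencing methylation analysis for sperm-DNA amplicons:
the **H19-DMR** imprinting control region (18 CpGs, including CTCF-binding
site 6 at CpGs 4–8 and a masked C/T polymorphism at CpG 7), the **DAZL**
promoter (31 CpGs) and the **LINE-1** retrotransposon (19 CpGs) as a
global-methylation surrogate.

It is written for people who sequence cloned bisulfite-PCR products —
typically ~20 clones per patient and locus — and need to go from raw clone
FASTA files to per-CpG methylation calls, conversion quality control,
clone-category classification and group-level statistics, reproducibly and
in one pass.

## What it computes

Each sequenced clone reports one DNA molecule: after bisulfite treatment,
unmethylated cytosines read as T and 5-methylcytosines stay C. The pipeline

1. **aligns** each clone (either orientation) globally to the genomic
   reference under a bisulfite-aware score (reference C matched by clone C
   *or* T), and calls every CpG ordinal M/U/missing/masked;
2. **filters** clones by conversion QC: >95% of covered non-CpG cytosines
   converted (strict) and no unconverted C adjacent to a CpG;
3. **classifies** each passing clone — H19-DMR by unmethylated fraction f
   (complete methylation f=0 / mild f<0.5 / severe 0.5≤f<1 / complete
   unmethylation f=1), CTCF site 6 by unmethylated count of its 4
   informative CpGs (0 / 1–3 / 4), DAZL by methylated fraction g (0 /
   <0.2 / 0.2–0.8 / ≥0.8), and pools LINE-1 calls into methylated/total
   CpG counts;
4. **summarises** per patient (category percentages, per-CpG methylation
   fractions, text lollipop diagrams) and **compares** fertility groups
   (normozoospermia NZ, asthenozoospermia AZ, oligozoospermia OZ) by
   mean ± SD and one-way ANOVA on the per-patient percentages
   (F = t² for pairwise comparisons).

Because no real clone sets for these loci are publicly deposited, the
package ships a first-class simulator (`bsclones.simulate`) that generates
full cohorts — category mixtures per group, conversion failures,
over-conversion, sequencing errors, random clone orientation, the CpG 7
SNP, and LINE-1 per-copy CpG loss — together with a truth table, so every
stage is testable end to end. Packaged reference sequences are synthetic
stand-ins with the documented CpG architecture (see `docs/methods.md`);
supply your own amplicon FASTA via the config for real data.

## Worked example

Simulate the default three-group study design (20 patients × 20 clones per
group for H19 and DAZL, 6 patients per group for LINE-1) and analyse it:

```bash
bsclones simulate --seed 7 --out demo/sim
bsclones run --sample-sheet demo/sim/sample_sheet.tsv --out demo/out
```

`demo/out/line1_totals.tsv` — pooled LINE-1 methylation per group:

```
amplicon  group  n_patients  n_clones  total_cpg  methylated_cpg  pct_methylated
LINE1     NZ     6           116       1992       1591            79.869478
LINE1     AZ     6           111       1903       1412            74.198634
LINE1     OZ     6           111       1895       1522            80.316623
```

Each group's percentage is methylated CpGs over all called CpGs pooled
across that group's clones (clones contribute variable CpG counts because
LINE-1 copies differ); global methylation is high and similar across
groups, as expected for this control locus.

`demo/out/comparisons.tsv` — ANOVA on per-patient percentages of
completely methylated H19-DMR clones:

```
metric                            groups    F          p_value      stars  mean_NZ  mean_AZ  mean_OZ
pct_H19_DMR_complete_methylation  AZ+NZ+OZ  46.271376  1.15245e-12  **     82.78    76.73    50.50
pct_H19_DMR_complete_methylation  AZ+NZ      3.151837  8.38516e-02         82.78    76.73
pct_H19_DMR_complete_methylation  NZ+OZ     94.634054  7.30595e-12  **     82.78             50.50
```

The simulated OZ group, generated with a markedly lower
complete-methylation mixture, is flagged (**, p<0.01) against NZ and AZ,
while NZ vs AZ is not significant — the qualitative pattern the analysis
is designed to detect. Per-patient detail is in `patients.tsv`, per-clone
calls and QC in `clones.tsv`, and `lollipops/` holds one text panel per
patient (● methylated, ○ unmethylated, · missing, × masked — column 7 of
H19 is always ×, the polymorphic CpG).

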