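# Methods

## The measurement being modelled

Bisulfite clone sequencing reads DNA methylation one molecule at a time.
Genomic DNA is treated with sodium bisulfite, which deaminates unmethylated
cytosine to uracil (read as T after PCR) while 5-methylcytosine stays C; a
locus is PCR-amplified from the converted template, the product is cloned,
and ~20 colonies per sample are Sanger-sequenced. Each clone therefore
reports the methylation state of every CpG on one original molecule: C at a
reference CpG means methylated, T means unmethylated.

`bsclones` implements the downstream computation for three loci analysed in
human sperm:

* **H19-DMR** (18 CpGs in the amplicon) — the imprinting control region of
  the *H19/IGF2* locus. It is methylated on the paternal allele, so sperm
  clones are expected fully methylated; loss of methylation is the
  abnormality of interest. CpG 7 carries a C/T polymorphism and CpG
  ordinals 4–8 span CTCF-binding site 6.
* **DAZL promoter** (31 CpGs) — a germ-cell gene whose promoter is expected
  unmethylated in sperm; gain of methylation is the abnormality.
* **LINE-1** (19 CpGs on the consensus) — an abundant retrotransposon used
  as a surrogate for global genomic methylation. Amplification hits many
  genomic copies, so individual clones carry variable subsets of the 19
  consensus CpGs.

## Reference amplicons

Amplicon references are packaged FASTA records plus a YAML panel giving
masked CpG ordinals and named subwindows. Coordinates are 1-based and
inclusive throughout; a CpG site is identified by the position of its C,
and CpG *ordinals* count CpGs along the amplicon.

The packaged sequences are **synthetic stand-ins** (flagged in their
filenames and headers): they reproduce the documented architecture of each
amplicon — product size, exact CpG count, CpG spacing, an ample complement
of non-CpG cytosines — but are not the GenBank sequences, which this
package deliberately never fetches. Every algorithm here depends only on
that architecture, not on the particular bases between CpGs. Users with
the real amplicon sequences can supply them through the amplicon config.

Masking is structural: a masked ordinal (H19 CpG 7) is excluded from every
numerator and denominator regardless of the observed base, because after
bisulfite conversion a T at a C/T SNP is ambiguous between the T allele and
an unmethylated C. Allele-aware rescue is deliberately out of scope.

## Alignment and calling

Clones are globally aligned to the *genomic* reference under a
bisulfite-aware substitution rule: a reference C paired with clone C or T
scores as a match (+1), any other mismatch −1, affine gaps costing
|−2| + L·|−0.5| for length L. Both the clone and its reverse complement are
aligned and the better orientation kept (forward on an exact tie, with a
warning); cloning inserts either strand, so roughly half of real clones
arrive reversed. Ties among equal-scoring alignments resolve to the
aligner's deterministic first enumeration. All scores are configurable; the
defaults are this package's own choice since the wet-lab workflow delegated
alignment to interactive software.

Per CpG ordinal, the clone base paired with the reference CpG-C position
yields the call: C → methylated, T → unmethylated, gap or other base →
missing; masked ordinals are always masked. Missing calls are excluded from
numerator and denominator of every fraction — required for LINE-1, where
clones legitimately lack CpGs, and the safe behaviour for deletions
elsewhere. A clone whose best alignment covers <80% of the reference is
rejected as non-amplicon sequence (`NON_AMPLICON`); the threshold is ours
and config-overridable.

## Conversion quality control

Non-CpG cytosines have no biological methylation in sperm, so their
conversion measures bisulfite completeness clone by clone. Over reference
non-CpG cytosines covered by the alignment: clone T counts converted,
clone C unconverted. A clone passes QC only if

* conversion rate **strictly** exceeds 0.95 (a clone at exactly 95% fails), and
* no unconverted non-CpG C lies immediately 5′ or 3′ of either base of any
  CpG dinucleotide (incomplete conversion adjacent to a CpG undermines that
  CpG's call).

Clones failing QC are retained in `clones.tsv` with a machine-readable
reject reason but excluded from classification and statistics.

## Classification schemes

Let f be the unmethylated fraction and g the methylated fraction over
informative *called* CpGs.

| Scheme | Bins |
|---|---|
| H19_DMR | f=0 complete_methylation; 0<f<0.5 mild_hypomethylation; 0.5≤f<1 severe_hypomethylation; f=1 complete_unmethylation |
| CTCF6 (CpGs 4–8; 4 informative) | 0 unmethylated complete_methylation; 1–3 hypomethylation; 4 complete_unmethylation |
| DAZL | g=0 complete_unmethylation; 0<g<0.2 mild_hypermethylation; 0.2≤g<0.8 moderate_hypermethylation; g≥0.8 severe_hypermethylation |

The shared boundaries (0.5; 0.2 and 0.8) are closed on the more severe
side. With full-length clones these fractions are unreachable (no u/17
equals 0.5; no m/31 equals 0.2 or 0.8), so the convention matters only for
clones with missing CpGs; it is fixed here rather than configurable, and
tests pin it on truncated call vectors. CTCF6 uses absolute counts and
requires all four informative window CpGs called; a clone with a missing
window CpG is excluded from that scheme only. LINE-1 is not binned: calls
are pooled over clones into total/methylated CpG counts per patient and per
group.

## Statistics

The unit of analysis is the patient: category percentages are computed per
patient (100 × clones in bin / clones classified), then summarised as
mean ± sample SD (n−1) per group and compared by one-way fixed-effects
ANOVA on the per-patient percentages. F is computed from between/within
sums of squares with df (k−1, N−k) and p from the upper F tail; with two
groups this is identical to the pooled-variance t test (F = t²), which is
how pairwise comparisons are reported. If every group is internally
constant but means differ, F is reported +inf with p = 0 and flagged.
Significance marks follow the usual convention (* p<0.05, ** p<0.01); no
multiple-testing correction is applied, and none is claimed.

## Synthetic cohorts

`bsclones.simulate` emulates the data-generating process:

1. per clone, a category is drawn from the group's mixture, then a pattern
   uniform over the counts and placements compatible with that bin;
2. the genomic molecule is built (SNP allele at masked CpGs, drawn twice
   per patient as a germline genotype with T-allele frequency 0.3, one
   allele per haploid clone; LINE-1 CpGs independently ablated with
   probability 0.1 per clone, so called CpGs per clone average
   19 × 0.9 = 17.1);
3. in-silico bisulfite conversion per the pattern, then noise: failed
   conversion retains each non-CpG C with probability 0.01,
   over-conversion reads each methylated CpG as T with probability 0.01,
   sequencing substitutions hit any base at 0.001, and the clone is
   emitted on either strand with probability 0.5.

The error-rate defaults are ordinary values for a well-run bisulfite
experiment (conversion efficiency ≈99%, Sanger-grade reads); the
orientation rate reflects non-directional TA cloning. Default group
mixtures are parameterized from reported group-level category means for
fertile (NZ), asthenozoospermic (AZ) and oligozoospermic (OZ) men,
renormalized to sum to one; they are expectations used to shape simulated
cohorts, not any study's underlying per-patient data, which were never
released. Because category assignment is made on *observed* calls, nonzero
over-conversion steadily erodes the complete-methylation bin
(P(survive) = (1−r)^17 per clone), so simulated group means under noise sit
below the configured mixtures; with the error model zeroed the pipeline
recovers the configured mixtures exactly, clone for clone, and that
round-trip is the package's primary correctness check.

What the generator does not emulate: PCR and cloning bias (clone
resampling of the same template molecule), chromatograms and basecall
quality, indel sequencing errors, linked error hotspots, and real LINE-1
subfamily sequence divergence beyond CpG loss. Passing tests therefore
show the *computation* is right under a realistic error budget, not that
any biological conclusion transfers.

Determinism: one seed fixes everything; per-patient streams are derived
from (seed, amplicon, group index, patient index), so regenerating with
more patients leaves earlier patients' files byte-identical.

`line1_count_fixture` builds cohorts whose pooled per-group clone/CpG/
methylated-CpG totals equal a given count table exactly, by partitioning
the totals evenly across clones and randomizing only placements and
orientations; it exists so pooled-count reporting can be validated against
a published table to the digit.

## Problem sizes and numerics

The default simulated study is 3 groups × 20 patients × 20 clones for H19
and DAZL and 6 patients per group for LINE-1, matching the design the
analysis is meant for; full-cohort analysis runs in seconds. The
acceptance script uses 20 patients per group for all three amplicons in
its round-trip cohort and 1500 null replicates for the ANOVA type-I
calibration — sizes chosen so results are stable at the reported precision.
Percentages are exact rational arithmetic until formatting; ANOVA uses
float sums of squares (adequate at cohort scale); fraction denominators of
zero yield NaN per-CpG fractions, empty patients are flagged and excluded
from group statistics with a warning, and a clone covering no non-CpG
cytosines is assigned conversion rate 1.0 (nothing to convert).

## Known limitations

* Clone categories are taken at face value per molecule; no correction for
  conversion error is attempted when binning (mirroring standard practice).
* No allele phasing: the masked-SNP information is discarded, not used to
  separate parental alleles.
* ANOVA on percentages bounded at [0, 100] with small n is approximate;
  the type-I calibration shows it is near-nominal under the default
  design, but heavy-tailed or near-boundary metrics (rare bins) are less
  well behaved.
* The packaged references are synthetic; results on them validate the
  machinery, not locus-specific sequence effects (e.g. primer or repeat
  artefacts).
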