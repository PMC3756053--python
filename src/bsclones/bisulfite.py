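"""In-silico bisulfite conversion, clone alignment, per-CpG calling and QC.

Bisulfite treatment converts unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine stays C. A sequenced clone therefore
reports one molecule's methylation pattern: at each reference CpG the clone
base is C (methylated) or T (unmethylated). Alignment back to the genomic
reference must treat a clone T opposite a reference C as a match, since
conversion is expected at every unmethylated C.

Quality control follows the standard clone-validation rule: a clone is
accepted only if more than 95% of its covered non-CpG cytosines were
converted and none of the unconverted ones sits immediately adjacent to a
CpG dinucleotide (incomplete conversion next to a CpG can corrupt the call).
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import reverse_complement

from .amplicons import AmpliconSpec, InputError, _DNA

__all__ = [
    "Call",
    "AlignParams",
    "CloneAlignment",
    "ConversionStats",
    "bisulfite_convert",
    "orient_and_align",
    "call_states",
    "conversion_stats",
]

logger = logging.getLogger(__name__)


class Call(str, enum.Enum):
    """Per-CpG methylation call; one-letter codes used in TSV output."""

    METHYLATED = "M"
    UNMETHYLATED = "U"
    MISSING = "x"
    MASKED = "m"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AlignParams:
    """Scoring for the bisulfite-aware global alignment.

    A reference C paired with a clone C *or* T scores as a match; every
    other mismatch is penalised. Gaps are affine: a gap of length L costs
    ``gap_open + L * gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5
    min_coverage: float = 0.8


@dataclass
class CloneAlignment:
    """Oriented global alignment of one clone against a reference amplicon."""

    clone_id: str
    orientation: str  # "+" forward, "-" clone aligned as reverse complement
    score: float
    ref_to_clone: tuple[str | None, ...]  # per 1-based ref position (index 0 = pos 1)
    coverage: float  # fraction of reference positions paired with a clone base
    n_mismatches: int

    def base_at(self, position: int) -> str | None:
        """Clone base paired with 1-based reference ``position`` (None = gap)."""
        return self.ref_to_clone[position - 1]


@dataclass(frozen=True)
class ConversionStats:
    """Conversion completeness of one clone over covered non-CpG cytosines."""

    n_noncpg_c: int
    n_converted: int
    n_adjacent_unconverted: int
    conversion_rate: float
    qc_pass: bool


def bisulfite_convert(reference: str, methylated_positions: set[int] | frozenset[int]) -> str:
    """Convert ``reference`` in silico: every C outside ``methylated_positions``
    becomes T; methylated Cs and all other bases are unchanged.

    ``methylated_positions`` are 1-based and must point at Cs.
    """
    if not reference or not _DNA.match(reference):
        raise InputError("reference must be non-empty uppercase A/C/G/T/N")
    seq = list(reference)
    for p in methylated_positions:
        if not (1 <= p <= len(seq)) or seq[p - 1] != "C":
            raise InputError(f"methylated position {p} is not a C in the reference")
    keep = set(methylated_positions)
    for i, b in enumerate(seq):
        if b == "C" and (i + 1) not in keep:
            seq[i] = "T"
    return "".join(seq)


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                matrix[a, b] = 0.0
            elif a == b:
                matrix[a, b] = params.match
            else:
                matrix[a, b] = params.mismatch
    # bisulfite rule: reference C may be read as T at full match score
    matrix["C", "T"] = params.match
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    # biopython charges open+extend for the first gap base
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _align_one(aligner, ref: str, clone: str):
    aln = aligner.align(ref, clone)[0]  # first alignment: deterministic tie-break
    return aln.score, aln


def orient_and_align(
    clone: str,
    spec: AmpliconSpec,
    params: AlignParams | None = None,
    clone_id: str = "",
) -> CloneAlignment:
    """Globally align ``clone`` to the genomic reference in both orientations
    and return the higher-scoring one.

    The clone and its reverse complement are aligned under the
    bisulfite-aware scoring of :class:`AlignParams`; on an exact score tie
    the forward orientation is kept and a warning is logged.
    """
    if not clone or not _DNA.match(clone):
        raise InputError(f"clone {clone_id or '?'}: empty or non-DNA sequence")
    params = params or AlignParams()
    aligner = _make_aligner(params)
    ref = spec.sequence
    fwd_score, fwd = _align_one(aligner, ref, clone)
    rev_score, rev = _align_one(aligner, ref, reverse_complement(clone))
    if fwd_score == rev_score:
        logger.warning(
            "clone %s: forward/reverse alignment scores tie (%.1f); keeping forward",
            clone_id or "?",
            fwd_score,
        )
    if fwd_score >= rev_score:
        orientation, score, aln, oriented = "+", fwd_score, fwd, clone
    else:
        orientation, score, aln, oriented = "-", rev_score, rev, reverse_complement(clone)

    mapping: list[str | None] = [None] * len(ref)
    indices = aln.indices  # (2, columns); -1 marks a gap
    n_mismatch = 0
    for ri, ci in zip(indices[0], indices[1]):
        if ri < 0:
            continue
        if ci >= 0:
            base = oriented[ci]
            mapping[ri] = base
            refbase = ref[ri]
            if base != refbase and not (refbase == "C" and base == "T"):
                n_mismatch += 1
    covered = sum(1 for b in mapping if b is not None)
    return CloneAlignment(
        clone_id=clone_id,
        orientation=orientation,
        score=float(score),
        ref_to_clone=tuple(mapping),
        coverage=covered / len(ref),
        n_mismatches=n_mismatch,
    )


def call_states(alignment: CloneAlignment, spec: AmpliconSpec) -> tuple[Call, ...]:
    """Call each CpG ordinal from an oriented alignment.

    At the reference CpG-C position: clone C -> METHYLATED, clone T ->
    UNMETHYLATED, gap or any other base -> MISSING. Masked ordinals are
    always MASKED regardless of the observed base.
    """
    calls: list[Call] = []
    for ordinal, pos in enumerate(spec.cpg_positions, start=1):
        if ordinal in spec.masked_cpgs:
            calls.append(Call.MASKED)
            continue
        base = alignment.base_at(pos)
        if base == "C":
            calls.append(Call.METHYLATED)
        elif base == "T":
            calls.append(Call.UNMETHYLATED)
        else:
            calls.append(Call.MISSING)
    return tuple(calls)


def conversion_stats(
    alignment: CloneAlignment,
    spec: AmpliconSpec,
    min_conversion_rate: float = 0.95,
) -> ConversionStats:
    """Conversion QC over reference non-CpG cytosines covered by the clone.

    A covered non-CpG C read as T counts as converted; read as C it is
    unconverted. The clone passes QC only if the conversion rate strictly
    exceeds ``min_conversion_rate`` (equality fails) and no unconverted C
    lies immediately 5' or 3' of either base of any CpG dinucleotide.

    A clone covering zero non-CpG cytosines has an undefined rate and is
    reported with rate 1.0 (nothing to convert).
    """
    adjacent = spec.cpg_adjacent_positions()
    n_total = 0
    n_converted = 0
    n_adj_unconverted = 0
    for pos in spec.noncpg_c_positions():
        base = alignment.base_at(pos)
        if base is None:
            continue
        n_total += 1
        if base == "T":
            n_converted += 1
        elif base == "C" and pos in adjacent:
            n_adj_unconverted += 1
    rate = n_converted / n_total if n_total else 1.0
    return ConversionStats(
        n_noncpg_c=n_total,
        n_converted=n_converted,
        n_adjacent_unconverted=n_adj_unconverted,
        conversion_rate=rate,
        qc_pass=(rate > min_conversion_rate and n_adj_unconverted == 0),
    )
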