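"""Clone category classification and per-patient aggregation.

Three schemes are used, matching how sperm clone patterns are binned at
each locus:

``H19_DMR`` (expected fully methylated on the paternal allele) — by the
fraction f of informative CpGs that are unmethylated:
f = 0 complete_methylation; 0 < f < 0.5 mild_hypomethylation;
0.5 <= f < 1 severe_hypomethylation; f = 1 complete_unmethylation.

``CTCF6`` (CTCF-binding site 6, CpG ordinals 4-8 of the H19 amplicon, of
which 4 are informative) — by the absolute count of unmethylated CpGs:
0 complete_methylation; 1-3 hypomethylation; 4 complete_unmethylation.
A clone with any of the 4 informative window CpGs missing is excluded
from this scheme.

``DAZL`` (promoter expected unmethylated in germ cells) — by the fraction
g of informative CpGs that are methylated: g = 0 complete_unmethylation;
0 < g < 0.2 mild_hypermethylation; 0.2 <= g < 0.8 moderate_hypermethylation;
g >= 0.8 severe_hypermethylation.

Fractions always use informative *called* CpGs as denominator: MASKED and
MISSING CpGs are excluded from numerator and denominator alike. The shared
boundaries (0.5; 0.2 and 0.8) are left-closed on the more severe side; with
full-length clones (17 informative H19 CpGs, 31 DAZL CpGs) the boundary
fractions are unreachable, so the convention only matters for clones with
missing CpGs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .amplicons import AmpliconSpec, informative_cpgs
from .bisulfite import Call

__all__ = [
    "SCHEME_LABELS",
    "CloneCategory",
    "PatientSummary",
    "classify_h19",
    "classify_ctcf6",
    "classify_dazl",
    "classify",
    "summarize_patient",
    "aggregate_line1",
]

logger = logging.getLogger(__name__)

SCHEME_LABELS: dict[str, tuple[str, ...]] = {
    "H19_DMR": (
        "complete_methylation",
        "mild_hypomethylation",
        "severe_hypomethylation",
        "complete_unmethylation",
    ),
    "CTCF6": (
        "complete_methylation",
        "hypomethylation",
        "complete_unmethylation",
    ),
    "DAZL": (
        "complete_unmethylation",
        "mild_hypermethylation",
        "moderate_hypermethylation",
        "severe_hypermethylation",
    ),
}


@dataclass(frozen=True)
class CloneCategory:
    """Bin assignment of one clone under one scheme."""

    scheme: str
    label: str
    n_informative: int
    n_unmethylated: int
    n_methylated: int

    def __post_init__(self) -> None:
        assert self.n_unmethylated + self.n_methylated == self.n_informative


def _counts(calls: Sequence[Call], ordinals: Iterable[int] | None = None):
    """(n_unmethylated, n_methylated) over informative called CpGs.

    ``ordinals`` restricts to a 1-based CpG-ordinal subset; returns None in
    place of a count pair if any selected non-masked CpG is MISSING only
    when the caller asks (CTCF6 handles that itself).
    """
    idx = range(1, len(calls) + 1) if ordinals is None else ordinals
    n_u = n_m = n_missing = 0
    for o in idx:
        c = calls[o - 1]
        if c is Call.METHYLATED:
            n_m += 1
        elif c is Call.UNMETHYLATED:
            n_u += 1
        elif c is Call.MISSING:
            n_missing += 1
    return n_u, n_m, n_missing


def _h19_label(n_unmethylated: int, n_informative: int) -> str:
    f = n_unmethylated / n_informative
    if f == 0:
        return "complete_methylation"
    if f < 0.5:
        return "mild_hypomethylation"
    if f < 1:
        return "severe_hypomethylation"
    return "complete_unmethylation"


def _dazl_label(n_methylated: int, n_informative: int) -> str:
    g = n_methylated / n_informative
    if g == 0:
        return "complete_unmethylation"
    if g < 0.2:
        return "mild_hypermethylation"
    if g < 0.8:
        return "moderate_hypermethylation"
    return "severe_hypermethylation"


def classify_h19(calls: Sequence[Call]) -> CloneCategory | None:
    """Bin a clone by its unmethylated fraction over informative called CpGs.

    Returns None (clone excluded from the scheme) if no CpG was informative
    and called.
    """
    n_u, n_m, _ = _counts(calls)
    n_i = n_u + n_m
    if n_i == 0:
        logger.warning("H19_DMR: clone has no informative called CpGs; excluded")
        return None
    return CloneCategory("H19_DMR", _h19_label(n_u, n_i), n_i, n_u, n_m)


def classify_ctcf6(
    calls: Sequence[Call], window_ordinals: Sequence[int] = (4, 5, 6, 7, 8)
) -> CloneCategory | None:
    """Bin a clone at CTCF-binding site 6 by its count of unmethylated CpGs.

    All informative window CpGs (masked ordinals drop out of the call
    vector as MASKED) must be called; any MISSING one excludes the clone
    from this scheme.
    """
    n_u, n_m, n_missing = _counts(calls, window_ordinals)
    if n_missing:
        logger.warning("CTCF6: %d window CpG(s) missing; clone excluded", n_missing)
        return None
    n_i = n_u + n_m
    if n_u == 0:
        label = "complete_methylation"
    elif n_u < n_i:
        label = "hypomethylation"
    else:
        label = "complete_unmethylation"
    return CloneCategory("CTCF6", label, n_i, n_u, n_m)


def classify_dazl(calls: Sequence[Call]) -> CloneCategory | None:
    """Bin a clone by its methylated fraction over informative called CpGs."""
    n_u, n_m, _ = _counts(calls)
    n_i = n_u + n_m
    if n_i == 0:
        logger.warning("DAZL: clone has no informative called CpGs; excluded")
        return None
    return CloneCategory("DAZL", _dazl_label(n_m, n_i), n_i, n_u, n_m)


_CLASSIFIERS = {
    "H19_DMR": classify_h19,
    "DAZL": classify_dazl,
}


def classify(calls: Sequence[Call], scheme: str, spec: AmpliconSpec | None = None):
    """Dispatch to the scheme's classifier.

    For CTCF6 the window ordinals are taken from the amplicon's ``CTCF6``
    subwindow when a spec is given.
    """
    if scheme == "CTCF6":
        ordinals = spec.window_ordinals("CTCF6") if spec is not None else (4, 5, 6, 7, 8)
        return classify_ctcf6(calls, ordinals)
    try:
        return _CLASSIFIERS[scheme](calls)
    except KeyError:
        raise ValueError(f"unknown classification scheme {scheme!r}") from None


@dataclass
class PatientSummary:
    """Per-patient clone counts, category percentages and per-CpG fractions."""

    patient_id: str
    group: str
    amplicon: str
    n_clones_pass: int
    category_counts: dict[str, dict[str, int]]  # scheme -> label -> count
    category_percentages: dict[str, dict[str, float]]
    per_cpg_ordinals: tuple[int, ...]  # informative ordinals, in order
    per_cpg_methylation_fraction: tuple[float, ...]
    empty: bool = False


def summarize_patient(
    clones: Sequence[tuple[Sequence[Call], dict[str, CloneCategory | None]]],
    patient_id: str,
    group: str,
    spec: AmpliconSpec,
    schemes: Sequence[str] | None = None,
) -> PatientSummary:
    """Aggregate one patient's QC-passing clones.

    ``clones`` pairs each clone's call vector with its per-scheme category
    (None where the clone was excluded from a scheme). Category percentages
    are 100 * count / number of clones classified under that scheme; the
    per-CpG methylation fraction at each informative ordinal uses called
    clones only.
    """
    schemes = list(schemes if schemes is not None else spec.schemes)
    counts: dict[str, dict[str, int]] = {
        s: {label: 0 for label in SCHEME_LABELS.get(s, ())} for s in schemes
    }
    for _, cats in clones:
        for s in schemes:
            cat = cats.get(s)
            if cat is not None:
                counts[s][cat.label] += 1
    percentages: dict[str, dict[str, float]] = {}
    for s in schemes:
        total = sum(counts[s].values())
        percentages[s] = {
            label: (100.0 * c / total if total else 0.0)
            for label, c in counts[s].items()
        }
    ordinals = tuple(informative_cpgs(spec))
    fractions = []
    for o in ordinals:
        n_m = sum(1 for calls, _ in clones if calls[o - 1] is Call.METHYLATED)
        n_u = sum(1 for calls, _ in clones if calls[o - 1] is Call.UNMETHYLATED)
        fractions.append(n_m / (n_m + n_u) if (n_m + n_u) else float("nan"))
    empty = len(clones) == 0
    if empty:
        logger.warning(
            "patient %s / %s: zero QC-passing clones; summary flagged empty",
            patient_id,
            spec.name,
        )
    return PatientSummary(
        patient_id=patient_id,
        group=group,
        amplicon=spec.name,
        n_clones_pass=len(clones),
        category_counts=counts,
        category_percentages=percentages,
        per_cpg_ordinals=ordinals,
        per_cpg_methylation_fraction=tuple(fractions),
        empty=empty,
    )


def aggregate_line1(
    call_vectors: Sequence[Sequence[Call]],
) -> tuple[int, int, float]:
    """Pool per-CpG calls over clones: (total called CpGs, methylated, percent).

    LINE-1 clones come from many genomic copies whose CpG complements
    differ, so clones contribute variable numbers of called CpGs; only
    informative, non-missing calls are counted.
    """
    n_total = n_meth = 0
    for calls in call_vectors:
        for c in calls:
            if c is Call.METHYLATED:
                n_total += 1
                n_meth += 1
            elif c is Call.UNMETHYLATED:
                n_total += 1
    if n_total == 0:
        raise ValueError("no called CpGs to aggregate")
    return n_total, n_meth, 100.0 * n_meth / n_total
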