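"""Synthetic bisulfite-clone cohort generator.

No clone sequences from sperm bisulfite studies of these loci are publicly
deposited, so every pipeline stage is exercised on simulated cohorts that
carry the statistical structure the analysis assumes:

* per-group mixtures of clone categories (drawn per patient, then a
  concrete methylation pattern per clone, uniform over the patterns
  compatible with the category);
* an error model: failed bisulfite conversion (non-CpG C retained as C),
  over-conversion (a methylated CpG read as T), sequencing substitutions,
  and random clone orientation (TA cloning inserts either strand);
* a germline C/T polymorphism at masked CpGs (alleles drawn once per
  patient; each haploid clone carries one of the two);
* LINE-1 copy variation: each reference CpG is independently disrupted
  (ablated to a non-C base) per clone, so clones report variable CpG
  counts against the 19-CpG consensus.

Cohort generation is reproducible: a fixed seed yields byte-identical
files, and per-patient substreams are derived from (seed, amplicon, group
index, patient index) so extending a cohort never perturbs earlier
patients.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .amplicons import AmpliconSpec, ConfigError, load_amplicons
from .bisulfite import Call, bisulfite_convert
from .classify import SCHEME_LABELS, classify

__all__ = [
    "ErrorModel",
    "SnpModel",
    "Line1CopyModel",
    "GroupConfig",
    "SimulationConfig",
    "sample_pattern",
    "generate_clone",
    "generate_cohort",
    "generate_cohorts",
    "study_default_configs",
    "design_clone_counts",
    "line1_pattern_from_design",
    "truth_calls",
]

_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


@dataclass(frozen=True)
class ErrorModel:
    """Per-base error rates applied when emitting a clone sequence."""

    failed_conversion_rate: float = 0.01
    over_conversion_rate: float = 0.01
    sequencing_substitution_rate: float = 0.001
    reverse_orientation_probability: float = 0.5

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")


ZERO_ERROR = ErrorModel(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SnpModel:
    """Germline C/T polymorphism at masked CpGs (allele frequency of T)."""

    t_allele_frequency: float = 0.3


@dataclass(frozen=True)
class Line1CopyModel:
    """Per-clone, per-CpG probability that a genomic copy lacks the CpG."""

    cpg_disruption_probability: float = 0.1


@dataclass(frozen=True)
class GroupConfig:
    """One fertility group: cohort size and its category mixture.

    ``category_mixture`` gives probabilities over the scheme's bins
    (binned schemes); ``methylation_level`` gives the per-CpG Bernoulli
    methylation probability (LINE-1, which has no bins).
    """

    label: str
    n_patients: int
    clones_per_patient: int
    category_mixture: dict[str, float] | None = None
    methylation_level: float | None = None

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.clones_per_patient <= 0:
            raise ConfigError("cohort counts must be positive")
        if (self.category_mixture is None) == (self.methylation_level is None):
            raise ConfigError(
                f"group {self.label}: give exactly one of category_mixture "
                "or methylation_level"
            )
        if self.category_mixture is not None:
            total = sum(self.category_mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"group {self.label}: mixture sums to {total}, not 1"
                )


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one simulated cohort for one amplicon."""

    seed: int
    amplicon: str
    scheme: str  # "H19_DMR", "DAZL" or "LINE1"
    groups: tuple[GroupConfig, ...]
    error_model: ErrorModel = ErrorModel()
    snp_model: SnpModel = SnpModel()
    line1_copy_model: Line1CopyModel = Line1CopyModel()


def _feasible_counts(scheme: str, label: str, n_cpgs: int) -> list[int]:
    """Counts (unmethylated for hypo schemes, methylated for DAZL)
    compatible with a bin at a given informative CpG count."""
    n = n_cpgs
    if scheme in ("H19_DMR", "CTCF6"):
        if label == "complete_methylation":
            return [0]
        if label == "complete_unmethylation":
            return [n]
        if scheme == "CTCF6" and label == "hypomethylation":
            return list(range(1, n))
        if label == "mild_hypomethylation":
            return [u for u in range(1, n) if u / n < 0.5]
        if label == "severe_hypomethylation":
            return [u for u in range(1, n) if 0.5 <= u / n < 1]
    elif scheme == "DAZL":
        if label == "complete_unmethylation":
            return [0]
        if label == "mild_hypermethylation":
            return [m for m in range(1, n + 1) if m / n < 0.2]
        if label == "moderate_hypermethylation":
            return [m for m in range(1, n + 1) if 0.2 <= m / n < 0.8]
        if label == "severe_hypermethylation":
            return [m for m in range(1, n + 1) if m / n >= 0.8]
    raise ConfigError(f"unknown scheme/label {scheme!r}/{label!r}")


def sample_pattern(
    scheme: str, label: str, n_cpgs: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw a binary methylation pattern (1 = methylated) whose bin under
    ``scheme`` is ``label``: uniform over qualifying counts, then uniform
    over CpG placements."""
    counts = _feasible_counts(scheme, label, n_cpgs)
    if not counts:
        raise ConfigError(
            f"category {label!r} is infeasible with {n_cpgs} CpGs under {scheme}"
        )
    c = int(rng.choice(counts))
    pattern = np.ones(n_cpgs, dtype=np.int8)
    if scheme == "DAZL":  # c counts methylated CpGs
        pattern[:] = 0
        idx = rng.choice(n_cpgs, size=c, replace=False)
        pattern[idx] = 1
    else:  # c counts unmethylated CpGs
        idx = rng.choice(n_cpgs, size=c, replace=False)
        pattern[idx] = 0
    return pattern


@dataclass
class CloneRecord:
    """A simulated clone sequence plus its ground truth."""

    clone_id: str
    sequence: str
    orientation: str
    pattern: tuple[int, ...]  # over all CpG ordinals; -1 marks a disrupted CpG
    snp_allele: str
    disrupted_cpgs: tuple[int, ...]
    n_failed_conversions: int
    n_overconverted: int
    n_substitutions: int
    true_categories: dict[str, str] = field(default_factory=dict)


def truth_calls(
    spec: AmpliconSpec, pattern: Sequence[int], disrupted: Sequence[int] = ()
) -> tuple[Call, ...]:
    """The call vector a perfect pipeline would produce for a true pattern."""
    disrupted_set = set(disrupted)
    calls = []
    for ordinal in range(1, spec.n_cpgs + 1):
        if ordinal in spec.masked_cpgs:
            calls.append(Call.MASKED)
        elif ordinal in disrupted_set or pattern[ordinal - 1] < 0:
            calls.append(Call.MISSING)
        else:
            calls.append(Call.METHYLATED if pattern[ordinal - 1] else Call.UNMETHYLATED)
    return tuple(calls)


def generate_clone(
    spec: AmpliconSpec,
    pattern: Sequence[int],
    error_model: ErrorModel,
    rng: np.random.Generator,
    snp_allele: str = "C",
    disrupted_cpgs: Sequence[int] = (),
    clone_id: str = "clone",
) -> CloneRecord:
    """Emit one clone sequence for a true methylation ``pattern``.

    The genomic molecule is built first (SNP allele at masked CpGs, CpG
    disruptions), then bisulfite-converted according to the pattern, then
    corrupted: over-conversion flips methylated CpGs to T, failed
    conversion retains non-CpG Cs, sequencing substitutions hit any base,
    and the clone is reported on either strand. With all rates zero the
    output equals :func:`bisulfite_convert` of the reference.
    """
    if len(pattern) != spec.n_cpgs:
        raise ConfigError(
            f"pattern length {len(pattern)} != CpG count {spec.n_cpgs}"
        )
    seq = list(spec.sequence)
    disrupted = tuple(sorted(set(int(o) for o in disrupted_cpgs)))
    for o in disrupted:
        seq[spec.cpg_positions[o - 1] - 1] = "A"
    if snp_allele == "T":
        for o in spec.masked_cpgs:
            seq[spec.cpg_positions[o - 1] - 1] = "T"

    cpg_c = set(spec.cpg_positions)
    methylated: set[int] = set()
    n_over = 0
    for ordinal, p in enumerate(spec.cpg_positions, start=1):
        if seq[p - 1] != "C":
            continue  # disrupted or SNP-T: no cytosine to methylate
        if pattern[ordinal - 1] == 1:
            if error_model.over_conversion_rate and rng.random() < error_model.over_conversion_rate:
                n_over += 1
            else:
                methylated.add(p)

    n_failed = 0
    for i, b in enumerate(seq):
        if b != "C":
            continue
        p = i + 1
        if p in methylated:
            continue
        if p not in cpg_c and error_model.failed_conversion_rate and rng.random() < error_model.failed_conversion_rate:
            n_failed += 1  # retained unconverted C
        else:
            seq[i] = "T"

    n_subs = 0
    if error_model.sequencing_substitution_rate:
        others = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
        for i, b in enumerate(seq):
            if rng.random() < error_model.sequencing_substitution_rate:
                seq[i] = others[b][int(rng.integers(3))]
                n_subs += 1

    sequence = "".join(seq)
    orientation = "+"
    if error_model.reverse_orientation_probability and rng.random() < error_model.reverse_orientation_probability:
        sequence = _revcomp(sequence)
        orientation = "-"
    return CloneRecord(
        clone_id=clone_id,
        sequence=sequence,
        orientation=orientation,
        pattern=tuple(int(x) for x in pattern),
        snp_allele=snp_allele,
        disrupted_cpgs=disrupted,
        n_failed_conversions=n_failed,
        n_overconverted=n_over,
        n_substitutions=n_subs,
    )


def _patient_rng(seed: int, amplicon: str, group_index: int, patient_index: int):
    tag = zlib.crc32(amplicon.encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed & 0x7FFFFFFF, tag, group_index, patient_index])


def _embed_pattern(spec: AmpliconSpec, informative: Sequence[int], sub: np.ndarray) -> np.ndarray:
    """Expand a pattern over informative ordinals to the full CpG vector.

    Masked CpGs are set methylated: at an imprinted locus the polymorphic
    CpG's true state is irrelevant to every category, and after masking it
    never enters any statistic.
    """
    full = np.ones(spec.n_cpgs, dtype=np.int8)
    for o, v in zip(informative, sub):
        full[o - 1] = v
    return full


def _simulate_patient(
    config: SimulationConfig,
    group: GroupConfig,
    spec: AmpliconSpec,
    patient_id: str,
    rng: np.random.Generator,
) -> list[CloneRecord]:
    from .amplicons import informative_cpgs

    informative = informative_cpgs(spec)
    genotype = tuple(
        "T" if rng.random() < config.snp_model.t_allele_frequency else "C"
        for _ in range(2)
    ) if spec.masked_cpgs else ("C", "C")

    if group.category_mixture is not None:
        labels = list(group.category_mixture)
        probs = np.array([group.category_mixture[l] for l in labels], dtype=float)
        probs = probs / probs.sum()
    clones = []
    for i in range(group.clones_per_patient):
        clone_id = f"{patient_id}_{spec.name}_c{i+1:03d}"
        disrupted: tuple[int, ...] = ()
        if group.category_mixture is not None:
            label = labels[int(rng.choice(len(labels), p=probs))]
            sub = sample_pattern(config.scheme, label, len(informative), rng)
            pattern = _embed_pattern(spec, informative, sub)
        else:  # LINE-1 style: per-CpG Bernoulli + copy variation
            pattern = (rng.random(spec.n_cpgs) < group.methylation_level).astype(np.int8)
            p_dis = config.line1_copy_model.cpg_disruption_probability
            if p_dis:
                disrupted = tuple(
                    int(o)
                    for o in range(1, spec.n_cpgs + 1)
                    if rng.random() < p_dis
                )
        allele = genotype[int(rng.integers(2))]
        rec = generate_clone(
            spec,
            pattern,
            config.error_model,
            rng,
            snp_allele=allele,
            disrupted_cpgs=disrupted,
            clone_id=clone_id,
        )
        calls = truth_calls(spec, rec.pattern, rec.disrupted_cpgs)
        for scheme in spec.schemes:
            if scheme in SCHEME_LABELS:
                cat = classify(calls, scheme, spec)
                rec.true_categories[scheme] = cat.label if cat else "excluded"
        clones.append(rec)
    return clones


def generate_cohort(
    config: SimulationConfig,
    outdir: str | Path,
    specs: dict[str, AmpliconSpec] | None = None,
) -> tuple[list[dict], list[dict]]:
    """Write one amplicon's cohort under ``outdir``.

    Returns (sample-sheet rows, truth rows). FASTA files land in
    ``outdir/fasta/`` with one file per patient x amplicon; paths in the
    returned rows are relative to ``outdir``.
    """
    specs = specs or load_amplicons()
    try:
        spec = specs[config.amplicon]
    except KeyError:
        raise ConfigError(f"unknown amplicon {config.amplicon!r}") from None
    outdir = Path(outdir)
    (outdir / "fasta").mkdir(parents=True, exist_ok=True)
    sheet_rows: list[dict] = []
    truth_rows: list[dict] = []
    for gi, group in enumerate(config.groups):
        for pi in range(group.n_patients):
            patient_id = f"{group.label}{pi+1:02d}"
            rng = _patient_rng(config.seed, config.amplicon, gi, pi)
            clones = _simulate_patient(config, group, spec, patient_id, rng)
            rel = Path("fasta") / f"{patient_id}_{spec.name}.fa"
            with open(outdir / rel, "w", newline="\n") as fh:
                for rec in clones:
                    fh.write(f">{rec.clone_id}\n{rec.sequence}\n")
            sheet_rows.append(
                {
                    "sample_id": patient_id,
                    "group": group.label,
                    "amplicon": spec.name,
                    "fasta_path": rel.as_posix(),
                }
            )
            for rec in clones:
                row = {
                    "clone_id": rec.clone_id,
                    "sample_id": patient_id,
                    "group": group.label,
                    "amplicon": spec.name,
                    "true_orientation": rec.orientation,
                    "true_pattern": "".join(
                        "d" if (o + 1) in rec.disrupted_cpgs else str(rec.pattern[o])
                        for o in range(spec.n_cpgs)
                    ),
                    "snp_allele": rec.snp_allele,
                    "n_failed_conversions": rec.n_failed_conversions,
                    "n_overconverted": rec.n_overconverted,
                    "n_substitutions": rec.n_substitutions,
                }
                for scheme, label in rec.true_categories.items():
                    row[f"true_{scheme}"] = label
                truth_rows.append(row)
    return sheet_rows, truth_rows


def _write_tsv(path: Path, rows: list[dict]) -> None:
    cols: list[str] = []
    for r in rows:
        for k in r:
            if k not in cols:
                cols.append(k)
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r.get(k, "")) for k in cols) + "\n")


def generate_cohorts(
    configs: Sequence[SimulationConfig],
    outdir: str | Path,
    specs: dict[str, AmpliconSpec] | None = None,
) -> tuple[Path, Path]:
    """Generate several amplicons' cohorts into one directory with a merged
    sample sheet and truth table; returns (sample_sheet_path, truth_path)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sheet: list[dict] = []
    truth: list[dict] = []
    for cfg in configs:
        s, t = generate_cohort(cfg, outdir, specs=specs)
        sheet.extend(s)
        truth.extend(t)
    sheet_path = outdir / "sample_sheet.tsv"
    truth_path = outdir / "truth.tsv"
    _write_tsv(sheet_path, sheet)
    _write_tsv(truth_path, truth)
    return sheet_path, truth_path


def _norm(raw: dict[str, float]) -> dict[str, float]:
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


# Published per-group category means (percent) used to parameterize the
# default mixtures; they describe group-level expectations, not any
# patient's actual clone set.
H19_GROUP_MIXTURES = {
    "NZ": _norm({"complete_methylation": 94.53, "mild_hypomethylation": 5.47}),
    "AZ": _norm({"complete_methylation": 95.22, "mild_hypomethylation": 4.98}),
    "OZ": _norm(
        {
            "complete_methylation": 62.64,
            "mild_hypomethylation": 32.98,
            "severe_hypomethylation": 2.14,
            "complete_unmethylation": 2.25,
        }
    ),
}
DAZL_GROUP_MIXTURES = {
    "NZ": _norm({"complete_unmethylation": 79.89, "mild_hypermethylation": 12.0}),
    "AZ": _norm(
        {
            "complete_unmethylation": 62.8,
            "mild_hypermethylation": 27.76,
            "moderate_hypermethylation": 7.6,
            "severe_hypermethylation": 1.94,
        }
    ),
    "OZ": _norm(
        {
            "complete_unmethylation": 54.14,
            "mild_hypermethylation": 33.51,
            "moderate_hypermethylation": 9.68,
            "severe_hypermethylation": 2.7,
        }
    ),
}
LINE1_GROUP_LEVELS = {"NZ": 0.798, "AZ": 0.749, "OZ": 0.811}


def study_default_configs(
    seed: int,
    n_patients: int = 20,
    clones_per_patient: int = 20,
    error_model: ErrorModel | None = None,
    line1_n_patients: int = 6,
) -> list[SimulationConfig]:
    """The default study design: three groups (NZ fertile controls, AZ
    reduced motility, OZ low concentration) of 20 patients with ~20
    sequenced clones each for H19 and DAZL, and a 6-patient-per-group
    LINE-1 global-methylation panel."""
    em = error_model if error_model is not None else ErrorModel()
    h19 = SimulationConfig(
        seed=seed,
        amplicon="H19",
        scheme="H19_DMR",
        groups=tuple(
            GroupConfig(g, n_patients, clones_per_patient, category_mixture=m)
            for g, m in H19_GROUP_MIXTURES.items()
        ),
        error_model=em,
    )
    dazl = SimulationConfig(
        seed=seed,
        amplicon="DAZL",
        scheme="DAZL",
        groups=tuple(
            GroupConfig(g, n_patients, clones_per_patient, category_mixture=m)
            for g, m in DAZL_GROUP_MIXTURES.items()
        ),
        error_model=em,
    )
    line1 = SimulationConfig(
        seed=seed,
        amplicon="LINE1",
        scheme="LINE1",
        groups=tuple(
            GroupConfig(g, line1_n_patients, clones_per_patient, methylation_level=v)
            for g, v in LINE1_GROUP_LEVELS.items()
        ),
        error_model=em,
    )
    return [h19, dazl, line1]


def load_simulation_configs(
    path: str | Path, seed_override: int | None = None
) -> list[SimulationConfig]:
    """Read simulation configs from a YAML document.

    Layout: top-level ``seed`` plus a ``simulations`` list; each entry
    gives ``amplicon``, ``scheme``, ``groups`` (label, n_patients,
    clones_per_patient, and either category_mixture or methylation_level)
    and optional ``error_model`` / ``snp_model`` / ``line1_copy_model``
    overrides.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "simulations" not in doc:
        raise ConfigError(f"{path}: expected a mapping with a 'simulations' list")
    seed = int(doc.get("seed", 0)) if seed_override is None else seed_override
    configs = []
    for entry in doc["simulations"]:
        groups = tuple(
            GroupConfig(
                label=str(g["label"]),
                n_patients=int(g["n_patients"]),
                clones_per_patient=int(g["clones_per_patient"]),
                category_mixture=g.get("category_mixture"),
                methylation_level=g.get("methylation_level"),
            )
            for g in entry["groups"]
        )
        configs.append(
            SimulationConfig(
                seed=seed,
                amplicon=str(entry["amplicon"]),
                scheme=str(entry["scheme"]),
                groups=groups,
                error_model=ErrorModel(**(entry.get("error_model") or {})),
                snp_model=SnpModel(**(entry.get("snp_model") or {})),
                line1_copy_model=Line1CopyModel(**(entry.get("line1_copy_model") or {})),
            )
        )
    return configs


def design_clone_counts(
    n_clones: int, total_cpg: int, methylated_cpg: int, max_cpgs_per_clone: int
) -> list[tuple[int, int]]:
    """Partition pooled totals into per-clone (called CpGs, methylated CpGs).

    Both totals are spread as evenly as possible; used to build fixtures
    that reproduce published pooled count tables exactly.
    """
    if not 0 <= methylated_cpg <= total_cpg:
        raise ConfigError("methylated count exceeds total")
    if total_cpg > n_clones * max_cpgs_per_clone or total_cpg < n_clones:
        raise ConfigError("total CpG count incompatible with clone count")
    base, extra = divmod(total_cpg, n_clones)
    counts = [base + 1] * extra + [base] * (n_clones - extra)
    mbase, mextra = divmod(methylated_cpg, n_clones)
    meths = [mbase + 1] * mextra + [mbase] * (n_clones - mextra)
    # repair any clone where meth > count (possible at extreme skew)
    for i in range(n_clones):
        while meths[i] > counts[i]:
            j = next(k for k in range(n_clones) if meths[k] < counts[k])
            meths[i] -= 1
            meths[j] += 1
    assert sum(counts) == total_cpg and sum(meths) == methylated_cpg
    return list(zip(counts, meths))


def line1_count_fixture(
    groups: Sequence[tuple[str, int, int, int, int]],
    outdir: str | Path,
    seed: int,
    specs: dict[str, AmpliconSpec] | None = None,
    amplicon: str = "LINE1",
) -> Path:
    """Build a LINE-1 cohort whose pooled per-group counts are exact.

    ``groups`` rows are (label, n_patients, n_clones, total_cpg,
    methylated_cpg); the pooled totals of the generated cohort equal these
    numbers by construction (clone-level counts are partitioned evenly,
    CpG placements and orientations are randomized, no read errors are
    injected). Returns the sample-sheet path.
    """
    specs = specs or load_amplicons()
    spec = specs[amplicon]
    outdir = Path(outdir)
    (outdir / "fasta").mkdir(parents=True, exist_ok=True)
    orientation_model = ErrorModel(0.0, 0.0, 0.0, 0.5)
    sheet_rows: list[dict] = []
    for gi, (label, n_patients, n_clones, total_cpg, meth_cpg) in enumerate(groups):
        designs = design_clone_counts(n_clones, total_cpg, meth_cpg, spec.n_cpgs)
        per_patient: list[list[tuple[int, int]]] = [[] for _ in range(n_patients)]
        for i, d in enumerate(designs):
            per_patient[i % n_patients].append(d)
        for pi, patient_designs in enumerate(per_patient):
            patient_id = f"{label}{pi+1:02d}"
            rng = _patient_rng(seed, f"{amplicon}-fixture", gi, pi)
            rel = Path("fasta") / f"{patient_id}_{spec.name}.fa"
            with open(outdir / rel, "w", newline="\n") as fh:
                for ci, (n_called, n_meth) in enumerate(patient_designs):
                    pattern, disrupted = line1_pattern_from_design(
                        spec, n_called, n_meth, rng
                    )
                    rec = generate_clone(
                        spec,
                        pattern,
                        orientation_model,
                        rng,
                        disrupted_cpgs=disrupted,
                        clone_id=f"{patient_id}_{spec.name}_c{ci+1:03d}",
                    )
                    fh.write(f">{rec.clone_id}\n{rec.sequence}\n")
            sheet_rows.append(
                {
                    "sample_id": patient_id,
                    "group": label,
                    "amplicon": spec.name,
                    "fasta_path": rel.as_posix(),
                }
            )
    sheet_path = outdir / "sample_sheet.tsv"
    _write_tsv(sheet_path, sheet_rows)
    return sheet_path


def line1_pattern_from_design(
    spec: AmpliconSpec, n_called: int, n_methylated: int, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Pattern + disrupted ordinals realizing exactly ``n_called`` called
    CpGs of which ``n_methylated`` are methylated."""
    n = spec.n_cpgs
    if not 0 <= n_methylated <= n_called <= n:
        raise ConfigError("infeasible per-clone design")
    ordinals = rng.permutation(n) + 1
    disrupted = tuple(sorted(int(o) for o in ordinals[n_called:]))
    called = ordinals[:n_called]
    pattern = np.zeros(n, dtype=np.int8)
    pattern[called[:n_methylated] - 1] = 1
    return pattern, disrupted
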