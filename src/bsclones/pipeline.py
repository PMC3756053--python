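"""End-to-end pipeline: FASTA clones -> calls -> QC -> categories ->
per-patient summaries -> group comparisons, with a run manifest.

The pipeline is a pure function of its inputs and configuration: re-running
on identical inputs yields byte-identical outputs (rows are emitted in
sample-sheet order; group comparisons in a fixed metric order).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .amplicons import AmpliconSpec, ConfigError, InputError, informative_cpgs, load_amplicons
from .bisulfite import (
    AlignParams,
    Call,
    call_states,
    conversion_stats,
    orient_and_align,
)
from .classify import (
    SCHEME_LABELS,
    aggregate_line1,
    classify,
    summarize_patient,
)
from .report import render_lollipop
from .stats import one_way_anova, significance_stars

logger = logging.getLogger(__name__)

SAMPLE_SHEET_COLUMNS = ["sample_id", "group", "amplicon", "fasta_path"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the analysis.

    ``min_conversion_rate`` is a strict lower bound (a clone at exactly the
    threshold fails); ``min_coverage`` rejects clones whose best alignment
    covers too little of the reference to be amplicon-derived.
    """

    align: AlignParams = AlignParams()
    min_conversion_rate: float = 0.95
    min_coverage: float = 0.8
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        align = AlignParams(**doc.get("align", {}))
        kwargs = {k: v for k, v in doc.items() if k != "align"}
        return cls(align=align, **kwargs)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample sheet TSV.

    Required columns: sample_id, group, amplicon, fasta_path. Relative
    FASTA paths resolve against the sheet's own directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: sample sheet lacks column(s) {missing}")
    for i, row in df.iterrows():
        if row[SAMPLE_SHEET_COLUMNS].isna().any():
            raise InputError(f"{path}: row {i + 2} has empty required fields")
    df["fasta_path"] = [
        str(p if Path(p).is_absolute() else path.parent / p) for p in df["fasta_path"]
    ]
    return df


def _read_clones(fasta: Path) -> list[tuple[str, str]]:
    records = list(SeqIO.parse(str(fasta), "fasta"))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise InputError(f"{fasta}: duplicate clone ids")
    return [(r.id, str(r.seq).upper()) for r in records]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def process_clone(
    clone_id: str,
    sequence: str,
    spec: AmpliconSpec,
    config: PipelineConfig,
):
    """Align, call and QC one clone. Returns (row dict, calls or None).

    ``calls`` is None when the clone is rejected (reason code in the row):
    NON_AMPLICON for coverage failure, LOW_CONVERSION / ADJACENT_UNCONVERTED
    for the conversion filter.
    """
    aln = orient_and_align(sequence, spec, params=config.align, clone_id=clone_id)
    row = {
        "clone_id": clone_id,
        "orientation": aln.orientation,
        "alignment_score": aln.score,
        "coverage": round(aln.coverage, 4),
    }
    if aln.coverage < config.min_coverage:
        row.update(
            call_string="", n_noncpg_c=0, conversion_rate="", n_adjacent_unconverted=0,
            qc_pass=False, reject_reason="NON_AMPLICON",
        )
        return row, None
    calls = call_states(aln, spec)
    stats = conversion_stats(aln, spec, min_conversion_rate=config.min_conversion_rate)
    reason = ""
    if not stats.qc_pass:
        reason = (
            "ADJACENT_UNCONVERTED"
            if stats.n_adjacent_unconverted > 0
            else "LOW_CONVERSION"
        )
    row.update(
        call_string="".join(c.value for c in calls),
        n_noncpg_c=stats.n_noncpg_c,
        conversion_rate=round(stats.conversion_rate, 6),
        n_adjacent_unconverted=stats.n_adjacent_unconverted,
        qc_pass=stats.qc_pass,
        reject_reason=reason,
    )
    return row, calls if stats.qc_pass else None


def run_pipeline(
    sample_sheet: str | Path,
    outdir: str | Path,
    amplicon_config: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> Path:
    """Run align -> call -> QC -> classify -> summarize -> compare.

    Writes under ``outdir``: clones.tsv, patients.tsv, comparisons.tsv,
    line1_totals.tsv (when a pooled-count amplicon is present), lollipop
    text renderings, manifest.json and run.log. Returns ``outdir``.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "lollipops").mkdir(exist_ok=True)

    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("bsclones")
    root.addHandler(log_handler)
    try:
        return _run(Path(sample_sheet), outdir, amplicon_config, config)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _run(sheet_path: Path, outdir: Path, amplicon_config, config: PipelineConfig) -> Path:
    specs = load_amplicons(amplicon_config)
    sheet = read_sample_sheet(sheet_path)
    for amp in sheet["amplicon"].unique():
        if amp not in specs:
            raise ConfigError(f"sample sheet references unknown amplicon {amp!r}")

    clone_rows: list[dict] = []
    checksums: dict[str, str] = {}
    n_read = n_aligned = n_pass = 0
    # patient -> (spec, group, list of (calls, categories))
    patients: dict[tuple[str, str], dict] = {}

    for _, srow in sheet.iterrows():
        fasta = Path(srow["fasta_path"])
        if not fasta.exists():
            raise InputError(f"sample sheet references missing file: {fasta}")
        spec = specs[srow["amplicon"]]
        checksums[str(fasta)] = _sha256(fasta)
        clones = _read_clones(fasta)
        if not clones:
            logger.warning("%s: empty FASTA; sample skipped", fasta)
        key = (srow["sample_id"], spec.name)
        entry = patients.setdefault(
            key, {"spec": spec, "group": srow["group"], "clones": [], "rendered": []}
        )
        for clone_id, seq in clones:
            n_read += 1
            row, calls = process_clone(clone_id, seq, spec, config)
            row = {
                "clone_id": row.pop("clone_id"),
                "sample_id": srow["sample_id"],
                "group": srow["group"],
                "amplicon": spec.name,
                **row,
            }
            if row["reject_reason"] != "NON_AMPLICON":
                n_aligned += 1
                entry["rendered"].append((clone_id, call_states_from_row(row, spec)))
            if calls is not None:
                n_pass += 1
                categories = {}
                for scheme in spec.schemes:
                    if scheme in SCHEME_LABELS:
                        cat = classify(calls, scheme, spec)
                        categories[scheme] = cat
                        row[f"category_{scheme}"] = cat.label if cat else "excluded"
                entry["clones"].append((calls, categories))
            clone_rows.append(row)

    pd.DataFrame(clone_rows).to_csv(outdir / "clones.tsv", sep="\t", index=False)

    patient_rows: list[dict] = []
    summaries: list = []
    line1_rows: list[dict] = []
    for (patient_id, amp), entry in patients.items():
        spec = entry["spec"]
        summary = summarize_patient(
            entry["clones"], patient_id, entry["group"], spec
        )
        summaries.append(summary)
        prow = {
            "sample_id": patient_id,
            "group": summary.group,
            "amplicon": amp,
            "n_clones_pass": summary.n_clones_pass,
        }
        for scheme in spec.schemes:
            for label in SCHEME_LABELS.get(scheme, ()):
                prow[f"pct_{scheme}_{label}"] = round(
                    summary.category_percentages[scheme][label], 6
                )
        if "LINE1" in spec.schemes and summary.n_clones_pass:
            n_total, n_meth, pct = aggregate_line1([c for c, _ in entry["clones"]])
            prow["line1_total_cpg"] = n_total
            prow["line1_methylated_cpg"] = n_meth
            prow["line1_pct_methylated"] = round(pct, 6)
        prow["per_cpg_methylation"] = ",".join(
            f"{f:.4f}" for f in summary.per_cpg_methylation_fraction
        )
        patient_rows.append(prow)
        render = render_lollipop(
            entry["rendered"], spec, title=f"{patient_id} {amp}"
        )
        (outdir / "lollipops" / f"{patient_id}_{amp}.txt").write_text(render)
    pd.DataFrame(patient_rows).to_csv(outdir / "patients.tsv", sep="\t", index=False)

    comparison_rows = _compare_groups(patient_rows, specs, config)
    pd.DataFrame(comparison_rows).to_csv(outdir / "comparisons.tsv", sep="\t", index=False)

    # pooled LINE-1 style totals per group
    for amp, spec in specs.items():
        if "LINE1" not in spec.schemes:
            continue
        groups: dict[str, dict] = {}
        for (pid, a), entry in patients.items():
            if a != amp or not entry["clones"]:
                continue
            g = groups.setdefault(
                entry["group"], {"n_patients": 0, "n_clones": 0, "calls": []}
            )
            g["n_patients"] += 1
            g["n_clones"] += len(entry["clones"])
            g["calls"].extend(c for c, _ in entry["clones"])
        for glabel, g in groups.items():
            n_total, n_meth, pct = aggregate_line1(g["calls"])
            line1_rows.append(
                {
                    "amplicon": amp,
                    "group": glabel,
                    "n_patients": g["n_patients"],
                    "n_clones": g["n_clones"],
                    "total_cpg": n_total,
                    "methylated_cpg": n_meth,
                    "pct_methylated": round(pct, 6),
                }
            )
    if line1_rows:
        pd.DataFrame(line1_rows).to_csv(outdir / "line1_totals.tsv", sep="\t", index=False)

    manifest = {
        "tool": "bsclones",
        "version": __version__,
        "config": {
            "align": asdict(config.align),
            "min_conversion_rate": config.min_conversion_rate,
            "min_coverage": config.min_coverage,
            "alpha": config.alpha,
        },
        "inputs": {
            "sample_sheet": str(sheet_path),
            "sample_sheet_sha256": _sha256(sheet_path),
            "fasta_sha256": dict(sorted(checksums.items())),
        },
        "counts": {
            "clones_read": n_read,
            "clones_aligned": n_aligned,
            "clones_qc_pass": n_pass,
        },
    }
    with open(outdir / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def call_states_from_row(row: dict, spec: AmpliconSpec) -> tuple[Call, ...]:
    """Rehydrate a call vector from its one-letter TSV encoding."""
    return tuple(Call(ch) for ch in row["call_string"])


def _compare_groups(patient_rows: list[dict], specs, config: PipelineConfig) -> list[dict]:
    """One-way ANOVA per category metric: omnibus over all groups plus every
    pairwise comparison (a two-group ANOVA, equivalent to a pooled t test)."""
    df = pd.DataFrame(patient_rows)
    rows: list[dict] = []
    if df.empty:
        return rows
    metrics = [c for c in df.columns if c.startswith("pct_") or c == "line1_pct_methylated"]
    for amp in sorted(df["amplicon"].unique()):
        sub = df[(df["amplicon"] == amp) & (df["n_clones_pass"] > 0)]
        group_labels = sorted(sub["group"].unique())
        for metric in metrics:
            if sub[metric].isna().all():
                continue
            per_group = {
                g: sub.loc[sub["group"] == g, metric].dropna().tolist()
                for g in group_labels
            }
            per_group = {g: v for g, v in per_group.items() if len(v) >= 2}
            if len(per_group) < 2:
                continue
            sets = [tuple(per_group)] + list(combinations(sorted(per_group), 2))
            for labels in sets:
                if len(labels) < 2:
                    continue
                comp = one_way_anova(
                    [per_group[g] for g in labels],
                    labels=labels,
                    metric=f"{amp}:{metric}",
                    alpha=config.alpha,
                )
                row = {
                    "amplicon": amp,
                    "metric": metric,
                    "groups": "+".join(labels),
                    "F": round(comp.anova_F, 6) if comp.anova_F != float("inf") else "inf",
                    "df_between": comp.df_between,
                    "df_within": comp.df_within,
                    "p_value": f"{comp.p_value:.6g}",
                    "significant": comp.significant,
                    "stars": significance_stars(comp.p_value),
                }
                for i, g in enumerate(labels):
                    row[f"n_{g}"] = comp.group_n[i]
                    row[f"mean_{g}"] = round(comp.group_mean[i], 4)
                    row[f"sd_{g}"] = round(comp.group_sd[i], 4)
                rows.append(row)
    return rows
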