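"""Reference amplicon model.

An :class:`AmpliconSpec` describes one bisulfite-PCR amplicon on the genomic
(unconverted) top strand: its sequence, the ordered 1-based positions of the
C of every CpG dinucleotide, the set of CpG ordinals masked from
quantification (e.g. a C/T polymorphism, which after bisulfite conversion is
indistinguishable from an unmethylated CpG), and named sub-windows of CpG
ordinals such as a CTCF-binding site.

All coordinates exposed here are 1-based and inclusive; a CpG site is
identified by the position of its C. CpG ordinals count CpGs from 1 along
the amplicon.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml
from Bio import SeqIO

__all__ = [
    "AmpliconSpec",
    "ConfigError",
    "InputError",
    "find_cpg_sites",
    "informative_cpgs",
    "load_amplicons",
    "builtin_amplicon_config",
]

_DNA = re.compile(r"^[ACGTN]+$")


class InputError(ValueError):
    """Malformed user-supplied data (sequences, patterns)."""


class ConfigError(ValueError):
    """Inconsistent or unknown configuration."""


def find_cpg_sites(sequence: str) -> list[int]:
    """Return the 1-based positions of the C of every CpG dinucleotide.

    ``N`` never matches either base of a CpG. CpG dinucleotides cannot
    overlap, so a simple scan is exact.

    >>> find_cpg_sites("ACGACGT")
    [2, 5]
    """
    if not sequence or not _DNA.match(sequence):
        raise InputError("sequence must be non-empty uppercase A/C/G/T/N")
    return [m.start() + 1 for m in re.finditer("(?=CG)", sequence)]


@dataclass(frozen=True)
class AmpliconSpec:
    """One reference amplicon with its CpG index.

    Parameters
    ----------
    name : str
        Short locus identifier (e.g. ``"H19"``).
    sequence : str
        Uppercase genomic top-strand sequence of the amplicon.
    masked_cpgs : frozenset of int
        CpG ordinals excluded from every numerator and denominator. Masking
        is structural, never allele-aware.
    subwindows : mapping of str to (int, int)
        Named inclusive CpG-ordinal ranges (e.g. ``{"CTCF6": (4, 8)}``).
    schemes : tuple of str
        Classification schemes applicable to this amplicon.
    accession, ref_start, ref_end, primers
        Provenance metadata; never used computationally.
    """

    name: str
    sequence: str
    accession: str = ""
    ref_start: int | None = None
    ref_end: int | None = None
    masked_cpgs: frozenset[int] = frozenset()
    subwindows: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    schemes: tuple[str, ...] = ()
    primers: Mapping[str, str] = field(default_factory=dict)
    cpg_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not _DNA.match(self.sequence):
            raise InputError(f"{self.name}: sequence contains non-DNA characters")
        positions = tuple(find_cpg_sites(self.sequence))
        if self.cpg_positions:
            if tuple(self.cpg_positions) != positions:
                raise ConfigError(
                    f"{self.name}: declared CpG positions disagree with sequence"
                )
        else:
            object.__setattr__(self, "cpg_positions", positions)
        n = len(positions)
        bad = [o for o in self.masked_cpgs if not 1 <= o <= n]
        if bad:
            raise ConfigError(f"{self.name}: masked CpG ordinals {bad} outside 1..{n}")
        for wname, (lo, hi) in self.subwindows.items():
            if not (1 <= lo <= hi <= n):
                raise ConfigError(
                    f"{self.name}: subwindow {wname!r} range ({lo},{hi}) outside 1..{n}"
                )

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    def window_ordinals(self, window: str | None = None) -> list[int]:
        """All CpG ordinals in ``window`` (or the whole amplicon), masked or not."""
        if window is None:
            return list(range(1, self.n_cpgs + 1))
        try:
            lo, hi = self.subwindows[window]
        except KeyError:
            raise ConfigError(
                f"{self.name}: unknown subwindow {window!r}; "
                f"known: {sorted(self.subwindows)}"
            ) from None
        return list(range(lo, hi + 1))

    def noncpg_c_positions(self) -> list[int]:
        """1-based positions of cytosines outside any CpG (conversion-QC substrate)."""
        cpg = set(self.cpg_positions)
        return [
            i + 1
            for i, b in enumerate(self.sequence)
            if b == "C" and (i + 1) not in cpg
        ]

    def cpg_adjacent_positions(self) -> set[int]:
        """Reference positions immediately 5' or 3' of any CpG dinucleotide."""
        adj: set[int] = set()
        for p in self.cpg_positions:
            if p > 1:
                adj.add(p - 1)
            if p + 2 <= len(self.sequence):
                adj.add(p + 2)
        return adj


def informative_cpgs(spec: AmpliconSpec, window: str | None = None) -> list[int]:
    """CpG ordinals in ``window`` (default: whole amplicon) minus masked ordinals."""
    return [o for o in spec.window_ordinals(window) if o not in spec.masked_cpgs]


def builtin_amplicon_config() -> Path:
    """Path to the packaged default amplicon panel (H19 / DAZL / LINE1)."""
    return Path(str(resources.files("bsclones").joinpath("data/amplicons.yaml")))


def _read_single_fasta(path: Path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ConfigError(f"{path}: amplicon FASTA must hold exactly one record")
    return str(records[0].seq).upper()


def load_amplicons(config_path: str | Path | None = None) -> dict[str, AmpliconSpec]:
    """Load an amplicon panel from a YAML config (default: packaged panel).

    Each entry names the amplicon and provides either a ``fasta`` path
    (relative paths resolve against the config file) or an inline
    ``sequence``, plus masked CpG ordinals and named subwindows.
    """
    path = Path(config_path) if config_path is not None else builtin_amplicon_config()
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "amplicons" not in doc:
        raise ConfigError(f"{path}: expected a mapping with an 'amplicons' list")
    specs: dict[str, AmpliconSpec] = {}
    for entry in doc["amplicons"]:
        name = entry["name"]
        if name in specs:
            raise ConfigError(f"duplicate amplicon name {name!r}")
        if "sequence" in entry:
            seq = str(entry["sequence"]).upper()
        elif "fasta" in entry:
            fasta = Path(entry["fasta"])
            if not fasta.is_absolute():
                fasta = path.parent / fasta
            seq = _read_single_fasta(fasta)
        else:
            raise ConfigError(f"amplicon {name!r}: need 'fasta' or 'sequence'")
        subwindows = {
            str(k): (int(v[0]), int(v[1]))
            for k, v in (entry.get("subwindows") or {}).items()
        }
        specs[name] = AmpliconSpec(
            name=name,
            sequence=seq,
            accession=str(entry.get("accession", "")),
            ref_start=entry.get("ref_start"),
            ref_end=entry.get("ref_end"),
            masked_cpgs=frozenset(int(o) for o in entry.get("masked_cpgs") or ()),
            subwindows=subwindows,
            schemes=tuple(entry.get("schemes") or ()),
            primers=dict(entry.get("primers") or {}),
        )
    return specs
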