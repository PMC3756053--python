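"""Human-readable clone-pattern rendering (text lollipop diagrams)."""
from __future__ import annotations

from typing import Sequence

from .amplicons import AmpliconSpec
from .bisulfite import Call

__all__ = ["render_lollipop", "GLYPHS"]

# filled = methylated, open = unmethylated, dot = missing, cross = masked
GLYPHS = {
    Call.METHYLATED: "●",
    Call.UNMETHYLATED: "○",
    Call.MISSING: "·",
    Call.MASKED: "×",
}


def render_lollipop(
    clones: Sequence[tuple[str, Sequence[Call]]],
    spec: AmpliconSpec,
    title: str = "",
) -> str:
    """One row per clone, one column per CpG ordinal.

    Clones are ordered by descending methylated-CpG count, ties broken by
    clone id, so the rendering is deterministic. An empty clone list still
    yields the header.
    """
    lines = []
    header = title or spec.name
    lines.append(f"# {header} ({spec.n_cpgs} CpGs)")
    ruler = "".join(str(o % 10) for o in range(1, spec.n_cpgs + 1))
    width = max((len(cid) for cid, _ in clones), default=8)
    lines.append(f"{'CpG':<{width}}  {ruler}")
    def sort_key(item):
        cid, calls = item
        n_meth = sum(1 for c in calls if c is Call.METHYLATED)
        return (-n_meth, cid)
    for cid, calls in sorted(clones, key=sort_key):
        glyphs = "".join(GLYPHS[c] for c in calls)
        lines.append(f"{cid:<{width}}  {glyphs}")
    return "\n".join(lines) + "\n"
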