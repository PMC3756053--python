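"""Independent reference implementations used only to cross-check results.

The alignment oracle is a plain three-matrix (Gotoh) dynamic program,
written without any alignment library, under the same scoring convention
as the package: a gap of length L costs |gap_open| + L * |gap_extend|, and
a reference C may be read as clone T at full match score.
"""
import math

NEG = -math.inf


def bisulfite_score(ref_base: str, clone_base: str, match=1.0, mismatch=-1.0) -> float:
    if "N" in (ref_base, clone_base):
        return 0.0
    if ref_base == clone_base or (ref_base == "C" and clone_base == "T"):
        return match
    return mismatch


def gotoh_global_score(
    ref: str,
    clone: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> float:
    """Optimal global affine-gap alignment score of clone against ref."""
    first = gap_open + gap_extend  # cost of the first base of a gap
    n, m = len(ref), len(clone)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in clone row
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref row
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = first + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = first + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = bisulfite_score(ref[i - 1], clone[j - 1], match, mismatch)
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + first, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + first, Y[i][j - 1] + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])
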