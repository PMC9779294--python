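"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: alignment scores come
from exhaustive enumeration of all monotone alignments, interval overlaps
from a quadratic scan.
"""

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_global_score(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Optimal global affine-gap score by exhaustive enumeration.

    A gap of length k costs gap_open + k * gap_extend, matching the
    package's alignment convention. Exponential: only for short sequences.
    """
    best = float("-inf")
    la, lb = len(a), len(b)

    def rec(i: int, j: int, prev: str | None, score: float) -> None:
        nonlocal best
        if i == la and j == lb:
            if score > best:
                best = score
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, "M", score + _BLOSUM62[a[i], b[j]])
        if i < la:
            cost = gap_extend if prev == "X" else gap_open + gap_extend
            rec(i + 1, j, "X", score - cost)
        if j < lb:
            cost = gap_extend if prev == "Y" else gap_open + gap_extend
            rec(i, j + 1, "Y", score - cost)

    rec(0, 0, None, 0.0)
    return best


def quadratic_overlaps(frags_a, frags_b):
    """All pairwise (label_a, label_b) -> (overlap, jaccard) by direct scan.

    Fragments are (label, start, end) half-open.
    """
    out = {}
    for la, sa, ea in frags_a:
        for lb, sb, eb in frags_b:
            inter = max(0, min(ea, eb) - max(sa, sb))
            union = (ea - sa) + (eb - sb) - inter
            out[(la, lb)] = (inter, inter / union if union else 0.0)
    return out


def quadratic_containment(frags, features):
    """Per-fragment contained/partial feature relations by direct scan."""
    out = {}
    for lab, s, e in frags:
        hits = []
        for flab, fs, fe in sorted(features, key=lambda f: f[1]):
            inter = max(0, min(e, fe) - max(s, fs))
            if inter == 0:
                continue
            hits.append((flab, "contained" if fs >= s and fe <= e else "partial"))
        out[lab] = hits
    return out
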