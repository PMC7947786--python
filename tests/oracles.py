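"""Independent reference implementations used as test oracles.

These are deliberately plain (quadratic-space dynamic programmes, explicit
loops, union-find) and share no code with the package internals they check.
"""

from __future__ import annotations

import math

NEG = -1e9


def sw_score(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Smith-Waterman local alignment score, affine gaps (Gotoh states).

    A gap of length k costs gap_open + (k - 1) * gap_extend; ``score`` is a
    callable giving the substitution score of a residue pair.
    """
    la, lb = len(a), len(b)
    m = [[0.0] * (lb + 1) for _ in range(la + 1)]
    ix = [[NEG] * (lb + 1) for _ in range(la + 1)]
    iy = [[NEG] * (lb + 1) for _ in range(la + 1)]
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = score(a[i - 1], b[j - 1])
            m[i][j] = max(m[i - 1][j - 1], ix[i - 1][j - 1], iy[i - 1][j - 1], 0.0) + s
            ix[i][j] = max(m[i - 1][j] - gap_open, ix[i - 1][j] - gap_extend)
            iy[i][j] = max(m[i][j - 1] - gap_open, iy[i][j - 1] - gap_extend)
            best = max(best, m[i][j])
    return best


def nw_score(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Global (Needleman-Wunsch) alignment score with the same gap model."""
    la, lb = len(a), len(b)
    m = [[NEG] * (lb + 1) for _ in range(la + 1)]
    ix = [[NEG] * (lb + 1) for _ in range(la + 1)]
    iy = [[NEG] * (lb + 1) for _ in range(la + 1)]
    m[0][0] = 0.0
    for i in range(1, la + 1):
        ix[i][0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, lb + 1):
        iy[0][j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = score(a[i - 1], b[j - 1])
            m[i][j] = max(m[i - 1][j - 1], ix[i - 1][j - 1], iy[i - 1][j - 1]) + s
            ix[i][j] = max(m[i - 1][j] - gap_open, ix[i - 1][j] - gap_extend)
            iy[i][j] = max(m[i][j - 1] - gap_open, iy[i][j - 1] - gap_extend)
    return max(m[la][lb], ix[la][lb], iy[la][lb])


def union_find_components(nodes, edges) -> list[set]:
    """Connected components via union-find."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return list(groups.values())


def jsd_direct(p, q) -> float:
    """Jensen-Shannon divergence, base-2 logs, direct summation."""

    def h(v):
        return -sum(x * math.log2(x) for x in v if x > 0)

    mix = [(x + y) / 2.0 for x, y in zip(p, q)]
    return h(mix) - 0.5 * (h(p) + h(q))


def min_distance_exhaustive(coords, target_index, site_indices) -> float:
    """Minimum Euclidean distance from one point to a set, by full scan."""
    tx, ty, tz = coords[target_index]
    best = float("inf")
    for i in site_indices:
        x, y, z = coords[i]
        d = math.sqrt((x - tx) ** 2 + (y - ty) ** 2 + (z - tz) ** 2)
        best = min(best, d)
    return best


def apply_units_left_to_right(base: str, units) -> str:
    """Naive mutation application: ascending coordinates with explicit
    re-anchoring by the cumulative length change of preceding units."""
    seq = base
    offset = 0
    for unit in sorted(units, key=lambda u: u.span):
        if unit.kind == "insertion":
            pos = unit.start + offset
            seq = seq[:pos] + unit.replacement + seq[pos:]
            offset += len(unit.replacement)
        elif unit.kind == "substitution":
            pos = unit.start + offset
            seq = seq[: pos - 1] + unit.replacement + seq[pos:]
        elif unit.kind == "deletion":
            start, end = unit.start + offset, unit.end + offset
            seq = seq[: start - 1] + seq[end:]
            offset -= end - start + 1
        else:  # segment_swap
            start, end = unit.start + offset, unit.end + offset
            seq = seq[: start - 1] + unit.replacement + seq[end:]
            offset += len(unit.replacement) - (end - start + 1)
    return seq
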