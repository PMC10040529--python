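"""Independent reference implementations used only by the tests.

These were written against the documented definitions, not against the
package code, and deliberately use a different algorithmic shape so that
agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np

NEG_INF = float("-inf")


def gotoh_local_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Affine-gap Smith-Waterman score by explicit three-state DP.

    A gap of length L costs gap_open + L * gap_extend, matching the blastp
    11/1 convention.  Returns 0 when no positive-scoring local alignment
    exists.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), NEG_INF)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(
                H[i, j - 1] - gap_open - gap_extend, E[i, j - 1] - gap_extend
            )
            F[i, j] = max(
                H[i - 1, j] - gap_open - gap_extend, F[i - 1, j] - gap_extend
            )
            sub = H[i - 1, j - 1] + matrix[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, sub, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return int(best)


def union_find_components(ids: list[str], edges: list[tuple[str, str]]) -> list[frozenset]:
    """Brute-force connected components by repeated merging."""
    groups = {i: {i} for i in ids}
    for u, v in edges:
        gu, gv = None, None
        for root, members in groups.items():
            if u in members:
                gu = root
            if v in members:
                gv = root
        if gu != gv:
            groups[gu] |= groups.pop(gv)
    return [frozenset(m) for m in groups.values()]


def pearson_population(x, y) -> float:
    """Population-normalised Pearson correlation (divide by n, not n-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum() / n
    sx = np.sqrt(((x - mx) ** 2).sum() / n)
    sy = np.sqrt(((y - my) ** 2).sum() / n)
    return float(cov / (sx * sy))
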