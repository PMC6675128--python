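"""Naive full-matrix local-alignment oracle (Gotoh affine DP).

Independent of the package's aligner: no heuristics, no shared code; plain
Python dynamic programming. Scoring convention matches the pipeline's
contract: match/mismatch substitution scores, a gap of length L costs
gap_open + L * gap_extend, and any column involving N scores 0.
"""

from __future__ import annotations

NEG = float("-inf")


def local_affine(
    target: str,
    query: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> tuple[float, set[tuple[int, int]]]:
    """Best local score and the set of optimal (target_end, query_end) cells."""
    n, m = len(target), len(query)
    first = gap_open + gap_extend  # cost of the first base of a gap
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (deletion)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (insertion)
    best = 0.0
    for i in range(1, n + 1):
        ti = target[i - 1]
        for j in range(1, m + 1):
            qj = query[j - 1]
            E[i][j] = max(H[i - 1][j] + first, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + first, F[i][j - 1] + gap_extend)
            if ti == "N" or qj == "N":
                s = 0.0
            elif ti == qj:
                s = match
            else:
                s = mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    ends = {
        (i, j)
        for i in range(1, n + 1)
        for j in range(1, m + 1)
        if H[i][j] == best
    }
    return best, ends
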