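"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive (pure Python, quadratic/cubic) and
shares no code with the implementation under test.
"""

from __future__ import annotations

ACGT = set("ACGT")


def p_distance_oracle(a: str, b: str) -> tuple[float | None, int]:
    """Site-by-site enumeration of the uncorrected distance."""
    assert len(a) == len(b)
    n = 0
    mism = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in ACGT and y in ACGT:
            n += 1
            if x != y:
                mism += 1
    if n == 0:
        return None, 0
    return mism / n, n


def semiglobal_score_oracle(
    s: str,
    t: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 4.0,
    gap_extend: float = 1.0,
) -> float:
    """Affine-gap Gotoh DP with free end gaps; returns the optimal score.

    A gap of length k costs gap_open + k * gap_extend; terminal gaps in
    either sequence are free.  Ambiguity codes (non-ACGT) score 0 against
    anything.
    """
    NEG = float("-inf")

    def sub(x: str, y: str) -> float:
        if x in ACGT and y in ACGT:
            return match if x == y else mismatch
        return 0.0

    n, m = len(s), len(t)
    open_cost = gap_open + gap_extend
    # M: s[i] aligned to t[j]; X: gap in t (s consumed); Y: gap in s
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # free leading end gap in t
    for j in range(1, m + 1):
        Y[0][j] = 0.0  # free leading end gap in s
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + sub(s[i - 1], t[j - 1])
            X[i][j] = max(
                max(M[i - 1][j], Y[i - 1][j]) - open_cost,
                X[i - 1][j] - gap_extend,
            )
            Y[i][j] = max(
                max(M[i][j - 1], X[i][j - 1]) - open_cost,
                Y[i][j - 1] - gap_extend,
            )
    # free trailing end gaps: best over last row and column of any state
    best = max(M[n][m], X[n][m], Y[n][m])
    for i in range(n + 1):
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best


def local_score_oracle(
    s: str,
    t: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 4.0,
    gap_extend: float = 1.0,
) -> float:
    """Affine-gap Smith-Waterman DP; returns the optimal local score."""
    NEG = float("-inf")

    def sub(x: str, y: str) -> float:
        if x in ACGT and y in ACGT:
            return match if x == y else mismatch
        return 0.0

    n, m = len(s), len(t)
    open_cost = gap_open + gap_extend
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i][j] = max(
                0.0, max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            ) + sub(s[i - 1], t[j - 1])
            X[i][j] = max(
                max(M[i - 1][j], Y[i - 1][j]) - open_cost,
                X[i - 1][j] - gap_extend,
            )
            Y[i][j] = max(
                max(M[i][j - 1], X[i][j - 1]) - open_cost,
                Y[i][j - 1] - gap_extend,
            )
            best = max(best, M[i][j])
    return best


def best_region_oracle(counts_sp, counts_seq, window: int) -> tuple[int, int, int]:
    """Exhaustive window scan; returns (start, min_species, min_seqs)."""
    L = len(counts_sp)
    best = None
    for s in range(L - window + 1):
        key = (
            min(counts_sp[s : s + window]),
            min(counts_seq[s : s + window]),
        )
        if best is None or key > (best[1], best[2]):
            best = (s, key[0], key[1])
    assert best is not None
    return best


def single_linkage_oracle(d, t: float) -> list[frozenset[int]]:
    """Naive agglomeration: repeatedly merge groups linked by any pair <= t.

    ``d[i][j]`` may be None for undefined distances (never links).
    """
    n = len(d)
    groups = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                linked = any(
                    d[i][j] is not None and d[i][j] <= t
                    for i in groups[a]
                    for j in groups[b]
                )
                if linked:
                    groups[a] |= groups[b]
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    return [frozenset(g) for g in groups]
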